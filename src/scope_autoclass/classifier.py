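"""Domain assignment, confidence gating and hierarchy placement.

Given the top-ranked group of filtered hits on a query chain, each hit
seeds one predicted domain.  Each boundary of the hit's query extent is
treated independently:

* if the boundary lies inside an observed region and the nearest chain
  terminus or ATOM-record gap edge of that region is within
  ``extension_limit`` residues, the boundary is extended to it (the aim is
  to classify every observed residue; the small limit makes it unlikely the
  extension swallows another domain);
* a boundary falling outside the observed residues is clipped inward to the
  nearest observed residue;
* finally the predicted interval is intersected with the observed ranges,
  so predictions never contain unobserved residues.

A short unassigned observed region (at most ``extension_limit`` residues)
lying strictly between two predictions is appended to the preceding
prediction, so interior linkers do not block full coverage of the chain.

Predictions then pass through the high-confidence gate, a set of pure
predicates each contributing a reason code; a chain is accepted only when
no code fires.  Accepted predictions inherit their superfamily from the
target domain; family, protein and species are transferred only when the
alignment is strong enough (see :class:`~.core_model.Parameters`),
otherwise the prediction is attached to a reusable "automated matches"
fallback node at the first unreliable level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Tuple

from .core_model import (
    ChainKey,
    ChainRecord,
    Hierarchy,
    HierarchyNode,
    Parameters,
    ResidueRange,
    ranges_to_set,
    set_to_ranges,
)
from .errors import IntegrityError
from .seq_search import (
    AlignmentHit,
    DomainDatabase,
    HitGroup,
    filter_hits,
    group_and_rank,
    search,
)

AUTOMATED_MATCHES = "automated matches"

REASON_CODES = (
    "LOW_RESOLUTION",
    "RIBOSOMAL_OR_SYNTHETIC",
    "GENETIC_DOMAIN_HOMOLOG",
    "MULTIDOMAIN_SHAPE",
    "UNASSIGNED_REGION",
    "DUPLICATE_TARGET_DOMAIN",
    "TARGET_NOT_WHOLE_CHAIN",
    "NO_HITS",
)


@dataclass
class DomainPrediction:
    """An automatically assigned domain on a query chain."""

    query_chain_key: ChainKey
    ranges: List[ResidueRange]
    source_hit: AlignmentHit
    superfamily_sunid: Optional[int] = None
    family_sunid: Optional[int] = None
    protein_sunid: Optional[int] = None
    species_sunid: Optional[int] = None
    placement_mode: Optional[str] = None  # "matched" | "automated_matches"

    @property
    def start(self) -> int:
        return self.ranges[0].start

    @property
    def end(self) -> int:
        return self.ranges[-1].end

    @property
    def is_contiguous(self) -> bool:
        return len(self.ranges) == 1


@dataclass(frozen=True)
class EntryMeta:
    """Entry-level metadata relevant to gating (overrides the chain's own)."""

    resolution: Optional[float] = None
    description: str = ""


@dataclass(frozen=True)
class ConfidenceVerdict:
    chain_key: ChainKey
    accepted: bool
    reason_codes: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.accepted != (not self.reason_codes):
            raise ValueError("accepted flag inconsistent with reason codes")


# ---------------------------------------------------------------------------
# boundary assignment


def _adjust_start(start: int, observed: Sequence[ResidueRange], limit: int) -> Optional[int]:
    for r in observed:
        if start in r:
            return r.start if start - r.start <= limit else start
    # unobserved boundary: clip inward to the next observed residue
    for r in observed:
        if r.start > start:
            return r.start
    return None


def _adjust_end(end: int, observed: Sequence[ResidueRange], limit: int) -> Optional[int]:
    for r in observed:
        if end in r:
            return r.end if r.end - end <= limit else end
    for r in reversed(observed):
        if r.end < end:
            return r.end
    return None


def assign_domains(
    top_group: HitGroup,
    chain: ChainRecord,
    params: Optional[Parameters] = None,
) -> List[DomainPrediction]:
    """Turn the top hit group into sorted, non-overlapping predictions."""
    params = params or Parameters()
    if not top_group.hits:
        raise ValueError("empty hit group")
    observed = chain.observed_ranges
    if not observed:
        raise IntegrityError(f"chain {chain.key} has no observed residues")

    seeds: List[Tuple[int, int, AlignmentHit]] = []
    for hit in sorted(
        top_group.hits,
        key=lambda h: (h.query_range.start, h.query_range.end, h.target_sid),
    ):
        if hit.query_range.end > len(chain.seqres):
            raise IntegrityError(
                f"hit {hit.target_sid} extends past SEQRES of chain {chain.key}"
            )
        s = _adjust_start(hit.query_range.start, observed, params.extension_limit)
        e = _adjust_end(hit.query_range.end, observed, params.extension_limit)
        if s is None or e is None or s > e:
            continue  # hit entirely outside the observed residues
        seeds.append((s, e, hit))

    # enforce pairwise non-overlap, keeping earlier (left-most) predictions
    resolved: List[Tuple[int, int, AlignmentHit]] = []
    for s, e, hit in seeds:
        if resolved and s <= resolved[-1][1]:
            s = resolved[-1][1] + 1
            if s > e:
                continue
        resolved.append((s, e, hit))

    # interior-linker rule: a short unassigned observed stretch strictly
    # between two predictions joins the preceding prediction
    obs_set = ranges_to_set(observed)
    for i in range(len(resolved) - 1):
        s, e, hit = resolved[i]
        nxt_start = resolved[i + 1][0]
        between = [x for x in range(e + 1, nxt_start) if x in obs_set]
        if 0 < len(between) <= params.extension_limit:
            resolved[i] = (s, nxt_start - 1, hit)

    predictions = []
    for s, e, hit in resolved:
        ranges = set_to_ranges(x for x in range(s, e + 1) if x in obs_set)
        if not ranges:
            continue
        predictions.append(
            DomainPrediction(
                query_chain_key=chain.key, ranges=ranges, source_hit=hit
            )
        )
    return predictions


# ---------------------------------------------------------------------------
# high-confidence gate (each rule is a pure predicate; order-independent)


def _rule_low_resolution(ctx) -> bool:
    res = ctx.meta.resolution
    return res is not None and res >= ctx.params.resolution_cutoff


def _rule_ribosomal_or_synthetic(ctx) -> bool:
    if ctx.top_group is not None:
        for hit in ctx.top_group.hits:
            info = ctx.db.info(hit.target_sid)
            letter = info.sccs.split(".")[0] if info.sccs else ""
            if letter and letter > "g":
                return True
    desc = ctx.meta.description.lower()
    return any(k in desc for k in ctx.params.exclusion_keywords)


def _rule_genetic_homolog(ctx) -> bool:
    return any(ctx.db.info(h.target_sid).is_genetic for h in ctx.all_hits)


def _rule_single_whole_chain(ctx) -> bool:
    if len(ctx.predictions) != 1:
        return False
    return not ctx.db.info(ctx.predictions[0].source_hit.target_sid).whole_chain


def _rule_multidomain_shape(ctx) -> bool:
    preds = ctx.predictions
    if len(preds) < 2:
        return False
    target_chain = ctx.db.chain_seqres.get(ctx.top_group.target_chain_key)
    if target_chain is not None and ctx.chain.seqres == target_chain:
        return False  # 100% sequence identity with the target chain
    if len(preds) == 2 and all(p.is_contiguous for p in preds):
        return False
    return True


def _rule_unassigned_region(ctx) -> bool:
    assigned = set()
    for p in ctx.predictions:
        assigned |= ranges_to_set(p.ranges)
    leftover = ranges_to_set(ctx.chain.observed_ranges) - assigned
    return any(len(r) > ctx.params.unassigned_limit for r in set_to_ranges(leftover))


def _rule_duplicate_target(ctx) -> bool:
    sids = [p.source_hit.target_sid for p in ctx.predictions]
    return len(sids) != len(set(sids))


GATE_RULES: Tuple[Tuple[str, Callable], ...] = (
    ("LOW_RESOLUTION", _rule_low_resolution),
    ("RIBOSOMAL_OR_SYNTHETIC", _rule_ribosomal_or_synthetic),
    ("GENETIC_DOMAIN_HOMOLOG", _rule_genetic_homolog),
    ("TARGET_NOT_WHOLE_CHAIN", _rule_single_whole_chain),
    ("MULTIDOMAIN_SHAPE", _rule_multidomain_shape),
    ("UNASSIGNED_REGION", _rule_unassigned_region),
    ("DUPLICATE_TARGET_DOMAIN", _rule_duplicate_target),
)


@dataclass
class _GateContext:
    predictions: List[DomainPrediction]
    chain: ChainRecord
    meta: EntryMeta
    top_group: Optional[HitGroup]
    db: DomainDatabase
    params: Parameters
    all_hits: List[AlignmentHit]


def gate_confidence(
    predictions: List[DomainPrediction],
    chain: ChainRecord,
    top_group: Optional[HitGroup],
    domain_db: DomainDatabase,
    params: Optional[Parameters] = None,
    entry_meta: Optional[EntryMeta] = None,
    all_filtered_hits: Optional[List[AlignmentHit]] = None,
    rule_order: Optional[Sequence[Tuple[str, Callable]]] = None,
) -> ConfidenceVerdict:
    """Apply the high-confidence criteria and collect all firing codes.

    *all_filtered_hits* should be the complete filtered hit list across all
    groups (the genetic-homolog rule looks beyond the top group); it
    defaults to the top group's hits.  *rule_order* exists so tests can
    verify order independence.
    """
    params = params or Parameters()
    meta = entry_meta or EntryMeta(chain.resolution, chain.description)
    if not predictions:
        return ConfidenceVerdict(chain.key, False, frozenset({"NO_HITS"}))
    all_hits = all_filtered_hits
    if all_hits is None:
        all_hits = top_group.hits if top_group else []
    ctx = _GateContext(
        predictions=predictions,
        chain=chain,
        meta=meta,
        top_group=top_group,
        db=domain_db,
        params=params,
        all_hits=all_hits,
    )
    codes = frozenset(
        code for code, rule in (rule_order or GATE_RULES) if rule(ctx)
    )
    return ConfidenceVerdict(chain.key, not codes, codes)


# ---------------------------------------------------------------------------
# hierarchy placement


def _get_or_create_fallback(
    hierarchy: Hierarchy, parent_sunid: int, level: str
) -> int:
    """Reusable "automated matches" node under *parent_sunid* at *level*."""
    for child in hierarchy.children(parent_sunid):
        node = hierarchy.node(child)
        if node.level == level and node.description == AUTOMATED_MATCHES:
            return child
    parent = hierarchy.node(parent_sunid)
    sccs = parent.sccs + ".0" if level == "family" else parent.sccs
    node = HierarchyNode(
        sunid=hierarchy.next_sunid(),
        level=level,
        sccs=sccs,
        parent_sunid=parent_sunid,
        description=AUTOMATED_MATCHES,
    )
    hierarchy.add(node)
    return node.sunid


def place_in_hierarchy(
    prediction: DomainPrediction,
    hierarchy: Hierarchy,
    domain_db: DomainDatabase,
    params: Optional[Parameters] = None,
) -> DomainPrediction:
    """Fill the hierarchy placement of an accepted prediction.

    The superfamily is always inherited from the target domain.  Family,
    protein and species are inherited only when the alignment's percent
    identity clears the corresponding threshold (protein and species
    additionally require the hit to cover the full target); below the first
    unreliable level the prediction is attached to an "automated matches"
    fallback node, created on demand and reused across predictions.
    """
    params = params or Parameters()
    info = domain_db.info(prediction.source_hit.target_sid)
    if info.sunid not in hierarchy:
        raise IntegrityError(
            f"target domain {info.sid} (sunid {info.sunid}) not in hierarchy"
        )
    sf = hierarchy.get_ancestor(info.sunid, "superfamily")
    fam = hierarchy.get_ancestor(info.sunid, "family")
    prot = hierarchy.get_ancestor(info.sunid, "protein")
    spec = hierarchy.get_ancestor(info.sunid, "species")
    if sf is None or fam is None or prot is None or spec is None:
        raise IntegrityError(f"target domain {info.sid} lacks a full lineage")

    hit = prediction.source_hit
    full = hit.target_range.start == 1 and hit.target_range.end == info.length
    pct = hit.percent_identity
    fam_ok = pct >= params.family_identity
    prot_ok = full and pct >= params.protein_identity
    spec_ok = full and pct >= params.species_identity

    mode = "matched"
    if not fam_ok:
        fam = _get_or_create_fallback(hierarchy, sf, "family")
        prot = _get_or_create_fallback(hierarchy, fam, "protein")
        spec = _get_or_create_fallback(hierarchy, prot, "species")
        mode = "automated_matches"
    elif not prot_ok:
        prot = _get_or_create_fallback(hierarchy, fam, "protein")
        spec = _get_or_create_fallback(hierarchy, prot, "species")
        mode = "automated_matches"
    elif not spec_ok:
        spec = _get_or_create_fallback(hierarchy, prot, "species")
        mode = "automated_matches"

    return replace(
        prediction,
        superfamily_sunid=sf,
        family_sunid=fam,
        protein_sunid=prot,
        species_sunid=spec,
        placement_mode=mode,
    )


# ---------------------------------------------------------------------------
# end-to-end


def classify_chain(
    chain: ChainRecord,
    domain_db: DomainDatabase,
    hierarchy: Hierarchy,
    params: Optional[Parameters] = None,
    entry_meta: Optional[EntryMeta] = None,
) -> Tuple[List[DomainPrediction], ConfidenceVerdict]:
    """Search, filter, group, assign, gate and place one query chain."""
    params = params or Parameters()
    hits = search(chain.seqres, domain_db, params)
    filtered = filter_hits(hits, domain_db, params)
    non_genetic = [
        h for h in filtered if not domain_db.info(h.target_sid).is_genetic
    ]
    groups = group_and_rank(non_genetic, domain_db)
    if not groups:
        verdict = gate_confidence(
            [], chain, None, domain_db, params, entry_meta, filtered
        )
        return [], verdict
    top = groups[0]
    predictions = assign_domains(top, chain, params)
    verdict = gate_confidence(
        predictions, chain, top, domain_db, params, entry_meta, filtered
    )
    if verdict.accepted:
        predictions = [
            place_in_hierarchy(p, hierarchy, domain_db, params)
            for p in predictions
        ]
    return predictions, verdict


def dump_predictions_tsv(
    predictions: Sequence[DomainPrediction],
    verdicts: Dict[ChainKey, ConfidenceVerdict],
) -> str:
    """Deterministic TSV dump of predictions with their gate verdicts."""
    lines = [
        "chain\tranges\ttarget_sid\te_value\tsf\tfa\tdm\tsp\tmode\taccepted\treasons"
    ]
    for p in sorted(predictions, key=lambda p: (p.query_chain_key, p.start)):
        v = verdicts.get(p.query_chain_key)
        lines.append(
            "\t".join(
                [
                    f"{p.query_chain_key[0]}_{p.query_chain_key[1]}",
                    ",".join(str(r) for r in p.ranges),
                    p.source_hit.target_sid,
                    f"{p.source_hit.e_value:.3g}",
                    str(p.superfamily_sunid or "-"),
                    str(p.family_sunid or "-"),
                    str(p.protein_sunid or "-"),
                    str(p.species_sunid or "-"),
                    p.placement_mode or "-",
                    "-" if v is None else ("1" if v.accepted else "0"),
                    "-"
                    if v is None or not v.reason_codes
                    else ",".join(sorted(v.reason_codes)),
                ]
            )
        )
    return "\n".join(lines) + "\n"
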