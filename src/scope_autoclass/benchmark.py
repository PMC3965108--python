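"""Scoring predicted domains against curated domains.

A predicted domain counts as *correct* when it is placed in the curated
domain's superfamily and every corresponding segment boundary differs by no
more than the tolerance (10 residues by default).  Predictions are paired
with curated domains greedily by maximal residue overlap; unpaired entries
on either side become ``unmatched`` records.  Unequal segment counts in a
pair cannot be compared boundary-by-boundary and score as a boundary
mismatch with an infinite deviation.

Release-pair benchmarking classifies every chain present only in the newer
release against the older release's domain database and scores the accepted
predictions against the newer release's curated domains, mirroring how
consecutive classified releases validate an automated pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .core_model import (
    ChainKey,
    Hierarchy,
    Parameters,
    ResidueRange,
    ranges_to_set,
)
from .classifier import DomainPrediction, classify_chain
from .scop_io import ReleaseBundle
from .seq_search import DomainDatabase


@dataclass(frozen=True)
class CuratedDomain:
    """Ground-truth domain used as the comparison standard."""

    chain_key: ChainKey
    ranges: Tuple[ResidueRange, ...]
    superfamily_sunid: Optional[int]
    sid: str = ""


@dataclass
class BenchmarkRecord:
    chain_key: ChainKey
    predicted_ranges: Optional[Tuple[ResidueRange, ...]]
    curated_ranges: Optional[Tuple[ResidueRange, ...]]
    superfamily_match: bool
    max_boundary_dev: float  # max |start-start|, |end-end| over paired segments
    verdict: str  # correct | boundary_mismatch | superfamily_mismatch | unmatched


@dataclass
class BenchmarkSummary:
    n_predicted: int
    n_correct: int
    n_boundary_mismatch: int
    n_chains_attempted: int
    n_chains_classifiable: int
    percent_classifiable: Optional[float]
    error_rate_percent: Optional[float]

    @property
    def percent_classifiable_display(self) -> Optional[str]:
        if self.percent_classifiable is None:
            return None
        return format_percent(self.percent_classifiable)

    @property
    def error_rate_display(self) -> Optional[str]:
        if self.error_rate_percent is None:
            return None
        return format_percent(self.error_rate_percent)


# ---------------------------------------------------------------------------
# report formatting


def format_percent(value: float) -> str:
    """Render a percentage the way release reports print them.

    Values of at least 1% get one decimal place; smaller non-zero values
    are rounded to one significant figure (0.7534 -> "0.8%", 0.0774 ->
    "0.08%"), so tiny error rates keep a meaningful leading digit.
    """
    if value >= 1 or value == 0:
        return f"{value:.1f}%"
    decimals = -math.floor(math.log10(value))
    rounded = round(value, decimals)
    if rounded >= 1:  # rounding crossed the 1% threshold
        return f"{rounded:.1f}%"
    return f"{rounded:.{decimals}f}%"


def _group_thousands(n: int) -> str:
    return f"{n:,}".replace(",", " ")


def format_error_rate(n_errors: int, n_total: int) -> str:
    """E.g. ``format_error_rate(62, 80140) == "0.08% (62 of 80 140)"``."""
    if n_total == 0:
        return "n/a (0 of 0)"
    pct = format_percent(100.0 * n_errors / n_total)
    return f"{pct} ({_group_thousands(n_errors)} of {_group_thousands(n_total)})"


# ---------------------------------------------------------------------------
# pairing and comparison


def _overlap(a: Sequence[ResidueRange], b: Sequence[ResidueRange]) -> int:
    return len(ranges_to_set(a) & ranges_to_set(b))


def pair_domains(
    predicted: Sequence[DomainPrediction],
    curated: Sequence[CuratedDomain],
) -> Tuple[
    List[Tuple[DomainPrediction, CuratedDomain]],
    List[DomainPrediction],
    List[CuratedDomain],
]:
    """Greedy pairing by maximal residue overlap.

    Repeatedly pairs the (prediction, curated) couple with the largest
    overlap (ties broken by list position) until no overlapping couple
    remains; everything else is returned as leftovers.
    """
    pred_left = list(range(len(predicted)))
    cur_left = list(range(len(curated)))
    pairs: List[Tuple[DomainPrediction, CuratedDomain]] = []
    while pred_left and cur_left:
        best = None
        for i in pred_left:
            for j in cur_left:
                ov = _overlap(predicted[i].ranges, curated[j].ranges)
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, i, j)
        if best is None:
            break
        _, i, j = best
        pairs.append((predicted[i], curated[j]))
        pred_left.remove(i)
        cur_left.remove(j)
    return (
        pairs,
        [predicted[i] for i in pred_left],
        [curated[j] for j in cur_left],
    )


def compare_domains(
    pred: DomainPrediction,
    cur: CuratedDomain,
    hierarchy: Hierarchy,
    tolerance: int = 10,
) -> BenchmarkRecord:
    """Score one prediction against its paired curated domain."""
    sf_match = (
        pred.superfamily_sunid is not None
        and pred.superfamily_sunid == cur.superfamily_sunid
    )
    p_ranges, c_ranges = tuple(pred.ranges), tuple(cur.ranges)
    if len(p_ranges) != len(c_ranges):
        dev: float = math.inf
    else:
        dev = max(
            max(abs(p.start - c.start), abs(p.end - c.end))
            for p, c in zip(p_ranges, c_ranges)
        )
    if not sf_match:
        verdict = "superfamily_mismatch"
    elif dev > tolerance:
        verdict = "boundary_mismatch"
    else:
        verdict = "correct"
    return BenchmarkRecord(
        chain_key=pred.query_chain_key,
        predicted_ranges=p_ranges,
        curated_ranges=c_ranges,
        superfamily_match=sf_match,
        max_boundary_dev=dev,
        verdict=verdict,
    )


def _unmatched_record(chain_key, predicted=None, curated=None) -> BenchmarkRecord:
    return BenchmarkRecord(
        chain_key=chain_key,
        predicted_ranges=tuple(predicted.ranges) if predicted else None,
        curated_ranges=tuple(curated.ranges) if curated else None,
        superfamily_match=False,
        max_boundary_dev=math.inf,
        verdict="unmatched",
    )


def score_chain(
    predictions: Sequence[DomainPrediction],
    curated: Sequence[CuratedDomain],
    hierarchy: Hierarchy,
    tolerance: int = 10,
) -> List[BenchmarkRecord]:
    pairs, pred_left, cur_left = pair_domains(predictions, curated)
    records = [compare_domains(p, c, hierarchy, tolerance) for p, c in pairs]
    for p in pred_left:
        records.append(_unmatched_record(p.query_chain_key, predicted=p))
    for c in cur_left:
        records.append(_unmatched_record(c.chain_key, curated=c))
    records.sort(
        key=lambda r: (
            r.chain_key,
            r.predicted_ranges[0].start if r.predicted_ranges else 10**9,
        )
    )
    return records


def summarize(
    records: Sequence[BenchmarkRecord],
    attempted_chains: Iterable[ChainKey],
) -> BenchmarkSummary:
    """Release-level counts and percentages over one benchmark run."""
    attempted = set(attempted_chains)
    predicted = [r for r in records if r.predicted_ranges is not None]
    classifiable = {r.chain_key for r in predicted}
    n_pred = len(predicted)
    n_bm = sum(1 for r in predicted if r.verdict == "boundary_mismatch")
    return BenchmarkSummary(
        n_predicted=n_pred,
        n_correct=sum(1 for r in predicted if r.verdict == "correct"),
        n_boundary_mismatch=n_bm,
        n_chains_attempted=len(attempted),
        n_chains_classifiable=len(classifiable & attempted)
        if attempted
        else len(classifiable),
        percent_classifiable=(
            100.0 * len(classifiable & attempted) / len(attempted)
            if attempted
            else None
        ),
        error_rate_percent=(100.0 * n_bm / n_pred) if n_pred else None,
    )


# ---------------------------------------------------------------------------
# release-pair benchmarking


def curated_domains_for_chain(
    bundle: ReleaseBundle, chain_key: ChainKey
) -> List[CuratedDomain]:
    out = []
    for dom in bundle.domains_on_chain(chain_key):
        sf = bundle.hierarchy.get_ancestor(dom.sunid, "superfamily")
        out.append(
            CuratedDomain(
                chain_key=chain_key,
                ranges=tuple(dom.ranges),
                superfamily_sunid=sf,
                sid=dom.sid,
            )
        )
    return out


def benchmark_release_pair(
    old_release: ReleaseBundle,
    new_release: ReleaseBundle,
    params: Optional[Parameters] = None,
) -> Tuple[List[BenchmarkRecord], BenchmarkSummary]:
    """Classify chains new in *new_release* with *old_release*'s database
    and score them against the newer release's curated domains.

    The two releases must share an identifier space: superfamily sunids in
    the new release refer to the same nodes as in the old one.
    """
    import copy
    import warnings

    params = params or Parameters()
    new_chains = sorted(set(new_release.chains) - set(old_release.chains))
    if not new_chains:
        warnings.warn("no chains are unique to the newer release; empty run")
        return [], summarize([], [])
    db = DomainDatabase.from_bundle(old_release)
    hierarchy = copy.deepcopy(old_release.hierarchy)  # placement may add nodes
    records: List[BenchmarkRecord] = []
    for key in new_chains:
        chain = new_release.chains[key]
        predictions, verdict = classify_chain(chain, db, hierarchy, params)
        if not verdict.accepted:
            continue
        curated = curated_domains_for_chain(new_release, key)
        records.extend(
            score_chain(
                predictions, curated, hierarchy, params.benchmark_tolerance
            )
        )
    return records, summarize(records, new_chains)


# ---------------------------------------------------------------------------
# release diffing


@dataclass(frozen=True)
class ChangeRecord:
    sunid: int
    sid: str
    change_type: str  # added | removed | moved | re-bounded
    detail: str


def diff_releases(a: ReleaseBundle, b: ReleaseBundle) -> List[ChangeRecord]:
    """Per-sunid change history between two releases."""
    changes: List[ChangeRecord] = []
    sids_a = {d.sunid: d for d in a.domains.values()}
    sids_b = {d.sunid: d for d in b.domains.values()}
    for sunid in sorted(set(a.hierarchy.nodes) | set(b.hierarchy.nodes)):
        in_a, in_b = sunid in a.hierarchy, sunid in b.hierarchy
        sid = ""
        if in_a:
            sid = a.hierarchy.node(sunid).sid
        if in_b and not sid:
            sid = b.hierarchy.node(sunid).sid
        if in_a and not in_b:
            changes.append(ChangeRecord(sunid, sid, "removed", ""))
            continue
        if in_b and not in_a:
            changes.append(ChangeRecord(sunid, sid, "added", ""))
            continue
        na, nb = a.hierarchy.node(sunid), b.hierarchy.node(sunid)
        if na.parent_sunid != nb.parent_sunid:
            changes.append(
                ChangeRecord(
                    sunid, sid, "moved", f"{na.parent_sunid}->{nb.parent_sunid}"
                )
            )
        da, db_ = sids_a.get(sunid), sids_b.get(sunid)
        if da is not None and db_ is not None:
            ra = ",".join(f"{s.chain_id}:{s.range}" for s in da.segments)
            rb = ",".join(f"{s.chain_id}:{s.range}" for s in db_.segments)
            if ra != rb:
                changes.append(
                    ChangeRecord(sunid, sid, "re-bounded", f"{ra}->{rb}")
                )
    return changes


def format_history(changes: Sequence[ChangeRecord]) -> str:
    """Change history, one tab-separated line per changed sunid."""
    lines = ["# sunid\tsid\tchange\tdetail"]
    for c in changes:
        lines.append(f"{c.sunid}\t{c.sid or '-'}\t{c.change_type}\t{c.detail or '-'}")
    return "\n".join(lines) + "\n"


def format_report(
    records: Sequence[BenchmarkRecord], summary: BenchmarkSummary
) -> str:
    """Benchmark report: per-record TSV followed by a summary block."""
    lines = ["chain\tpredicted\tcurated\tsf_match\tmax_dev\tverdict"]
    for r in records:
        pred = (
            ",".join(map(str, r.predicted_ranges)) if r.predicted_ranges else "-"
        )
        cur = ",".join(map(str, r.curated_ranges)) if r.curated_ranges else "-"
        dev = "inf" if math.isinf(r.max_boundary_dev) else str(int(r.max_boundary_dev))
        lines.append(
            f"{r.chain_key[0]}_{r.chain_key[1]}\t{pred}\t{cur}\t"
            f"{int(r.superfamily_match)}\t{dev}\t{r.verdict}"
        )
    lines.append("")
    lines.append(f"# predicted domains: {summary.n_predicted}")
    lines.append(f"# correct: {summary.n_correct}")
    lines.append(f"# boundary mismatches: {summary.n_boundary_mismatch}")
    lines.append(f"# chains attempted: {summary.n_chains_attempted}")
    lines.append(f"# chains classifiable: {summary.n_chains_classifiable}")
    lines.append(
        "# percent classifiable: "
        + (summary.percent_classifiable_display or "n/a")
    )
    lines.append(
        "# error rate: "
        + format_error_rate(summary.n_boundary_mismatch, summary.n_predicted)
    )
    return "\n".join(lines) + "\n"
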