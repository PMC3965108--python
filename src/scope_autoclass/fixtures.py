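"""Synthetic releases and query chains for testing every pipeline stage.

Generated sequences are i.i.d. draws over the 20-residue alphabet; the
members of a family are point-mutated copies of a family ancestor.  At the
lengths used here (>= 80 residues) this guarantees that within-family
alignments are overwhelmingly significant (E far below 1e-4) while
cross-family alignments are chance-level, so search, filtering and ranking
behave as on real data.  The generator makes no claim of structural
plausibility and models substitutions only (no indels).

The worked-example fixture reproduces a published non-trivial case: a
554-residue query chain with residues 2-547 observed, two filtered hits
covering query residues 2-224 and 226-544 to the two domains of one
classified reference chain, and curated domains 2-223 and 224-547.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .benchmark import CuratedDomain
from .core_model import (
    ChainRecord,
    Hierarchy,
    HierarchyNode,
    Parameters,
    ResidueRange,
    Segment,
)
from .core_model import DomainDefinition
from .scop_io import ReleaseBundle
from .seq_search import DomainDatabase, HitGroup, filter_hits, group_and_rank, search

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: divergence between members of one synthetic family (substitutions/site)
WITHIN_FAMILY_MUTATION_RATE = 0.05


@dataclass
class FixtureSpec:
    """Knobs of the synthetic-release generator."""

    seed: int = 0
    n_superfamilies: int = 3
    domains_per_family: int = 2
    chain_length_range: Tuple[int, int] = (120, 300)
    mutation_rate: float = 0.05  # for derived queries
    gap_spec: Tuple[Tuple[int, int], ...] = ()  # (position, length) unobserved
    multidomain_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_superfamilies, self.domains_per_family) < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.chain_length_range[0] < 80:
            raise ValueError("chain lengths below 80 make homology ambiguous")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point-mutate *seq* at *rate* substitutions/site (always to a
    different residue)."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_release(spec: FixtureSpec) -> ReleaseBundle:
    """Build a consistent synthetic release, deterministic per seed.

    Layout: one class (``a``), one fold/superfamily/family per superfamily
    index, ``domains_per_family`` domains per family, each with its own
    protein and species node.  A ``multidomain_fraction`` of the chains
    carry two domains (from different families) joined by a 5-residue
    linker; the rest are single-domain whole chains.
    """
    rng = np.random.default_rng(spec.seed)
    hierarchy = Hierarchy()
    next_id = [1]

    def new_node(**kw) -> HierarchyNode:
        node = HierarchyNode(sunid=next_id[0], **kw)
        next_id[0] += 1
        hierarchy.add(node)
        return node

    cls = new_node(level="class", sccs="a", description="synthetic alpha class")
    dom_specs = []  # (family node, sequence)
    for i in range(spec.n_superfamilies):
        fold = new_node(
            level="fold",
            sccs=f"a.{i + 1}",
            parent_sunid=cls.sunid,
            description=f"synthetic fold {i + 1}",
        )
        sf = new_node(
            level="superfamily",
            sccs=f"a.{i + 1}.1",
            parent_sunid=fold.sunid,
            description=f"synthetic superfamily {i + 1}",
        )
        fam = new_node(
            level="family",
            sccs=f"a.{i + 1}.1.1",
            parent_sunid=sf.sunid,
            description=f"synthetic family {i + 1}",
        )
        length = int(rng.integers(spec.chain_length_range[0], spec.chain_length_range[1] + 1))
        ancestor = _random_seq(rng, length)
        for j in range(spec.domains_per_family):
            seq = ancestor if j == 0 else mutate(
                ancestor, WITHIN_FAMILY_MUTATION_RATE, rng
            )
            dom_specs.append((fam, seq))

    n_domains = len(dom_specs)
    n_pairs = int(spec.multidomain_fraction * n_domains / 2)
    # interleave so paired domains come from different families where possible
    order = sorted(range(n_domains), key=lambda k: (k % spec.domains_per_family, k))

    bundle = ReleaseBundle(hierarchy=hierarchy, version_label=f"synthetic-{spec.seed}")
    chain_no = 0

    def add_chain(members: List[Tuple[HierarchyNode, str]]) -> None:
        nonlocal chain_no
        chain_no += 1
        pdb_id = f"{chain_no:04d}"
        linker = _random_seq(rng, 5)
        seq_parts: List[str] = []
        offsets: List[Tuple[int, int]] = []
        pos = 1
        for idx, (_, seq) in enumerate(members):
            if idx > 0:
                seq_parts.append(linker)
                pos += len(linker)
            seq_parts.append(seq)
            offsets.append((pos, pos + len(seq) - 1))
            pos += len(seq)
        seqres = "".join(seq_parts)
        bundle.chains[(pdb_id, "A")] = ChainRecord(
            pdb_id=pdb_id,
            chain_id="A",
            seqres=seqres,
            observed_ranges=[ResidueRange(1, len(seqres))],
            resolution=1.50,
            description=f"synthetic protein {chain_no}",
        )
        for idx, ((fam, seq), (s, e)) in enumerate(zip(members, offsets)):
            prot = new_node(
                level="protein",
                sccs=fam.sccs,
                parent_sunid=fam.sunid,
                description=f"synthetic protein {chain_no}.{idx + 1}",
            )
            sp = new_node(
                level="species",
                sccs=fam.sccs,
                parent_sunid=prot.sunid,
                description="synthetic organism",
            )
            sid = f"d{pdb_id}a{idx + 1}"
            dom_node = new_node(
                level="domain",
                sccs=fam.sccs,
                sid=sid,
                parent_sunid=sp.sunid,
                description=f"{pdb_id} A:{s}-{e}",
            )
            bundle.domains[sid] = DomainDefinition(
                sid=sid,
                sunid=dom_node.sunid,
                segments=[Segment("A", ResidueRange(s, e))],
                sequence=seq,
            )

    i = 0
    for _ in range(n_pairs):
        add_chain([dom_specs[order[i]], dom_specs[order[i + 1]]])
        i += 2
    while i < n_domains:
        add_chain([dom_specs[order[i]]])
        i += 1

    bundle.validate()
    return bundle


@dataclass
class DerivedQuery:
    """A mutated copy of a release chain plus its ground truth."""

    chain: ChainRecord
    truth: List[CuratedDomain]
    source_chain_key: Tuple[str, str]


def derive_query(
    bundle: ReleaseBundle,
    chain_key: Tuple[str, str],
    mutation_rate: float,
    gap_spec: Sequence[Tuple[int, int]] = (),
    seed: int = 0,
    pdb_id: Optional[str] = None,
) -> DerivedQuery:
    """Emulate a newly released chain homologous to a classified one.

    The source chain's SEQRES is point-mutated at *mutation_rate*;
    *gap_spec* marks (position, length) stretches as unobserved.  Ground
    truth carries the source domains' boundaries (intersected with the
    observed residues) and superfamilies, for benchmarking.
    """
    source = bundle.chains[chain_key]
    rng = np.random.default_rng(seed)
    seq = mutate(source.seqres, mutation_rate, rng)

    observed = set(range(1, len(seq) + 1))
    for pos, length in gap_spec:
        if pos < 1 or pos + length - 1 > len(seq):
            raise ValueError(f"gap ({pos},{length}) outside chain of length {len(seq)}")
        observed -= set(range(pos, pos + length))
    from .core_model import set_to_ranges

    observed_ranges = set_to_ranges(observed)
    qid = pdb_id or f"q{chain_key[0][-3:]}"
    chain = ChainRecord(
        pdb_id=qid,
        chain_id=source.chain_id,
        seqres=seq,
        observed_ranges=observed_ranges,
        resolution=source.resolution,
        description=f"synthetic query from {chain_key[0]}",
    )
    truth = []
    for dom in bundle.domains_on_chain(chain_key):
        vis = [
            r
            for rr in dom.ranges
            for r in [
                ResidueRange(s, e)
                for s, e in _clip_to_observed(rr, observed)
            ]
        ]
        if not vis:
            continue  # the gap removed this domain entirely
        sf = bundle.hierarchy.get_ancestor(dom.sunid, "superfamily")
        truth.append(
            CuratedDomain(
                chain_key=chain.key,
                ranges=tuple(vis),
                superfamily_sunid=sf,
                sid=dom.sid,
            )
        )
    return DerivedQuery(chain=chain, truth=truth, source_chain_key=chain_key)


def _clip_to_observed(r: ResidueRange, observed: set) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for i in range(r.start, r.end + 1):
        if i in observed:
            if out and i == out[-1][1] + 1:
                out[-1] = (out[-1][0], i)
            else:
                out.append((i, i))
    return out


def extend_release(
    old: ReleaseBundle,
    queries: Sequence[DerivedQuery],
    boundary_shift: int = 0,
) -> ReleaseBundle:
    """Build a successor release: *old* plus the query chains as curated
    entries, placed under their source domains' species nodes.

    *boundary_shift* perturbs each curated domain's start by +shift
    (clamped within the domain), emulating curation disagreement in linker
    regions -- useful for exercising the benchmark tolerance.
    """
    import copy

    new = ReleaseBundle(
        hierarchy=copy.deepcopy(old.hierarchy),
        domains=dict(old.domains),
        chains=dict(old.chains),
        version_label=old.version_label + "+queries",
    )
    for q in queries:
        new.chains[q.chain.key] = q.chain
        for k, cur in enumerate(q.truth):
            src = old.domains[cur.sid]
            sp = new.hierarchy.get_ancestor(src.sunid, "species")
            sccs = new.hierarchy.node(src.sunid).sccs
            ranges = list(cur.ranges)
            if boundary_shift and len(ranges[0]) > abs(boundary_shift) + 1:
                r0 = ranges[0]
                ranges[0] = ResidueRange(r0.start + boundary_shift, r0.end)
            sid = f"d{q.chain.pdb_id}{q.chain.chain_id.lower()}{k + 1}"
            node = HierarchyNode(
                sunid=new.hierarchy.next_sunid(),
                level="domain",
                sccs=sccs,
                sid=sid,
                parent_sunid=sp,
                description=f"{q.chain.pdb_id} curated",
            )
            new.hierarchy.add(node)
            seq = "".join(
                q.chain.seqres[r.start - 1 : r.end] for r in ranges
            )
            new.domains[sid] = DomainDefinition(
                sid=sid,
                sunid=node.sunid,
                segments=[Segment(q.chain.chain_id, r) for r in ranges],
                sequence=seq,
            )
    new.validate()
    return new


# ---------------------------------------------------------------------------
# the worked example


@dataclass
class WorkedExample:
    """The two-domain worked example with everything needed end to end."""

    chain: ChainRecord
    hit_group: HitGroup
    curated: List[CuratedDomain]
    release: ReleaseBundle
    database: DomainDatabase
    all_filtered_hits: List


def fig2_fixture(seed: int = 20040427) -> WorkedExample:
    """Reconstruct the published two-domain worked example.

    The query chain has 554 residues of which 2-547 are observed.  Its
    residues 2-224 and 226-544 are exact copies of the two classified
    domains of a 554-residue reference chain (observed 4-19, 48-66 and
    90-544); all other query positions are independent random residues, so
    the search backend recovers exactly the two printed hits.  Curated
    domains for the query are 2-223 and 224-547.
    """
    rng = np.random.default_rng(seed)
    ref_seq = _random_seq(rng, 554)
    dom1_seq = ref_seq[1:224]  # reference residues 2-224, length 223
    dom2_seq = ref_seq[225:544]  # reference residues 226-544, length 319

    query = list(_random_seq(rng, 554))
    query[1:224] = dom1_seq
    query[225:544] = dom2_seq
    # force the non-homologous positions to differ from the reference
    for i in (0, 224, *range(544, 554)):
        if query[i] == ref_seq[i]:
            query[i] = AMINO_ACIDS.replace(ref_seq[i], "")[
                rng.integers(len(AMINO_ACIDS) - 1)
            ]
    query_seq = "".join(query)

    hierarchy = Hierarchy()
    nid = iter(range(1, 100))

    def node(**kw):
        n = HierarchyNode(sunid=next(nid), **kw)
        hierarchy.add(n)
        return n

    cls = node(level="class", sccs="c", description="alpha and beta proteins")
    lineage = {}
    for k in (1, 2):
        fold = node(level="fold", sccs=f"c.{k}", parent_sunid=cls.sunid)
        sf = node(level="superfamily", sccs=f"c.{k}.1", parent_sunid=fold.sunid)
        fam = node(level="family", sccs=f"c.{k}.1.1", parent_sunid=sf.sunid)
        prot = node(level="protein", sccs=fam.sccs, parent_sunid=fam.sunid)
        sp = node(level="species", sccs=fam.sccs, parent_sunid=prot.sunid)
        lineage[k] = (sf, sp, fam)

    release = ReleaseBundle(hierarchy=hierarchy, version_label="worked-example")
    release.chains[("1ek1", "A")] = ChainRecord(
        pdb_id="1ek1",
        chain_id="A",
        seqres=ref_seq,
        observed_ranges=[
            ResidueRange(4, 19),
            ResidueRange(48, 66),
            ResidueRange(90, 544),
        ],
        resolution=2.30,
        description="hydroxyacyl-CoA dehydrogenase-like reference",
    )
    for k, (seg, seq) in enumerate(
        [(ResidueRange(2, 224), dom1_seq), (ResidueRange(226, 544), dom2_seq)], 1
    ):
        sid = f"d1ek1a{k}"
        dn = node(
            level="domain",
            sccs=lineage[k][2].sccs,
            sid=sid,
            parent_sunid=lineage[k][1].sunid,
            description=f"1ek1 A:{seg}",
        )
        release.domains[sid] = DomainDefinition(
            sid=sid, sunid=dn.sunid, segments=[Segment("A", seg)], sequence=seq
        )
    release.validate()

    chain = ChainRecord(
        pdb_id="1vj5",
        chain_id="A",
        seqres=query_seq,
        observed_ranges=[ResidueRange(2, 547)],
        resolution=1.95,
        description="conserved hypothetical protein",
    )

    db = DomainDatabase.from_bundle(release)
    params = Parameters()
    hits = search(chain.seqres, db, params)
    filtered = filter_hits(hits, db, params)
    groups = group_and_rank(filtered, db)
    if not groups:
        raise RuntimeError("worked-example fixture produced no hit group")
    curated = [
        CuratedDomain(
            chain_key=chain.key,
            ranges=(ResidueRange(2, 223),),
            superfamily_sunid=lineage[1][0].sunid,
            sid="d1vj5a1",
        ),
        CuratedDomain(
            chain_key=chain.key,
            ranges=(ResidueRange(224, 547),),
            superfamily_sunid=lineage[2][0].sunid,
            sid="d1vj5a2",
        ),
    ]
    return WorkedExample(
        chain=chain,
        hit_group=groups[0],
        curated=curated,
        release=release,
        database=db,
        all_filtered_hits=filtered,
    )
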