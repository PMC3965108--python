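"""Core data model for a SCOP-style domain classification.

The classification is a seven-level hierarchy (class, fold, superfamily,
family, protein, species, domain) whose nodes carry stable integer
identifiers (*sunid*), concise dotted classification strings (*sccs*, e.g.
``b.1.1.1``) and, at the domain level, seven-character stable domain
identifiers (*sid*, e.g. ``d1vj5a1``).

All residue coordinates in this package are 1-based inclusive indices into a
chain's SEQRES (deposited) sequence.  Author residue numbering, insertion
codes and heteroatoms are an I/O concern and never enter the core model.
Observed residues -- those resolved in the ATOM records of a structure --
are represented as a sorted list of non-overlapping :class:`ResidueRange`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import IntegrityError, UnknownIdentifierError

#: The seven hierarchy levels in root-to-leaf order.
LEVELS: Tuple[str, ...] = (
    "class",
    "fold",
    "superfamily",
    "family",
    "protein",
    "species",
    "domain",
)

LEVEL_INDEX: Mapping[str, int] = {name: i for i, name in enumerate(LEVELS)}

#: sccs class letters a-g denote the seven "true" structural classes; letters
#: beyond g mark non-true classes (e.g. ribosomal or synthetic constructs).
TRUE_CLASS_LETTERS = frozenset("abcdefg")


@dataclass(frozen=True, order=True)
class ResidueRange:
    """A contiguous 1-based inclusive interval of SEQRES indices."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue range {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end

    def overlaps(self, other: "ResidueRange") -> bool:
        return self.start <= other.end and other.start <= self.end

    def intersect(self, other: "ResidueRange") -> Optional["ResidueRange"]:
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return ResidueRange(lo, hi) if lo <= hi else None

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "ResidueRange":
        """Parse ``"2-547"`` (or a single index ``"5"``) into a range."""
        if "-" in text:
            a, b = text.split("-", 1)
            return cls(int(a), int(b))
        return cls(int(text), int(text))


def merge_ranges(ranges: Iterable[ResidueRange]) -> List[ResidueRange]:
    """Merge overlapping or adjacent ranges into a sorted disjoint list."""
    out: List[ResidueRange] = []
    for r in sorted(ranges, key=lambda r: (r.start, r.end)):
        if out and r.start <= out[-1].end + 1:
            if r.end > out[-1].end:
                out[-1] = ResidueRange(out[-1].start, r.end)
        else:
            out.append(r)
    return out


def range_union_size(ranges: Iterable[ResidueRange]) -> int:
    """Number of distinct residue indices covered by the union of *ranges*."""
    return sum(len(r) for r in merge_ranges(ranges))


def ranges_to_set(ranges: Iterable[ResidueRange]) -> frozenset:
    return frozenset(i for r in ranges for i in range(r.start, r.end + 1))


def set_to_ranges(indices: Iterable[int]) -> List[ResidueRange]:
    """Collapse a set of residue indices into sorted contiguous ranges."""
    out: List[ResidueRange] = []
    for i in sorted(set(indices)):
        if out and i == out[-1].end + 1:
            out[-1] = ResidueRange(out[-1].start, i)
        else:
            out.append(ResidueRange(i, i))
    return out


@dataclass
class HierarchyNode:
    """One node of the classification hierarchy.

    ``sccs`` is the dotted classification string; nodes at protein level and
    below inherit their family's sccs.  ``sid`` is set only for domain-level
    leaves.
    """

    sunid: int
    level: str
    sccs: str = ""
    sid: str = ""
    parent_sunid: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVEL_INDEX:
            raise ValueError(f"unknown hierarchy level {self.level!r}")

    @property
    def class_letter(self) -> str:
        return self.sccs.split(".")[0] if self.sccs else ""

    @property
    def is_true_class(self) -> bool:
        return self.class_letter in TRUE_CLASS_LETTERS


class Hierarchy:
    """Container for hierarchy nodes with parent/child navigation.

    Nodes are keyed by sunid.  Child lists are maintained incrementally and
    returned sorted for deterministic traversal.
    """

    def __init__(self, nodes: Iterable[HierarchyNode] = ()) -> None:
        self.nodes: Dict[int, HierarchyNode] = {}
        self._children: Dict[int, List[int]] = {}
        for node in nodes:
            self.add(node)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, sunid: int) -> bool:
        return sunid in self.nodes

    def __iter__(self):
        return iter(sorted(self.nodes))

    def add(self, node: HierarchyNode) -> HierarchyNode:
        if node.sunid in self.nodes:
            raise IntegrityError(f"duplicate sunid {node.sunid}")
        self.nodes[node.sunid] = node
        if node.parent_sunid is not None:
            self._children.setdefault(node.parent_sunid, []).append(node.sunid)
        return node

    def node(self, sunid: int) -> HierarchyNode:
        try:
            return self.nodes[sunid]
        except KeyError:
            raise UnknownIdentifierError(f"unknown sunid {sunid}") from None

    def children(self, sunid: int) -> List[int]:
        return sorted(self._children.get(sunid, []))

    def roots(self) -> List[int]:
        return sorted(s for s, n in self.nodes.items() if n.parent_sunid is None)

    def next_sunid(self) -> int:
        return max(self.nodes, default=0) + 1

    def get_ancestor(self, sunid: int, level: str) -> Optional[int]:
        """Sunid of the unique ancestor of *sunid* at *level* (self counts).

        Returns ``None`` when the node lies above the requested level.
        Raises :class:`UnknownIdentifierError` for an unknown sunid and
        ``ValueError`` for an unknown level name.
        """
        if level not in LEVEL_INDEX:
            raise ValueError(f"unknown hierarchy level {level!r}")
        node = self.node(sunid)
        target = LEVEL_INDEX[level]
        while LEVEL_INDEX[node.level] > target:
            if node.parent_sunid is None:
                return None
            node = self.node(node.parent_sunid)
        return node.sunid if LEVEL_INDEX[node.level] == target else None

    def validate(self) -> None:
        """Check tree structure: parent links exist and levels step by one."""
        for node in self.nodes.values():
            if node.parent_sunid is None:
                if node.level != "class":
                    raise IntegrityError(
                        f"root node {node.sunid} has level {node.level!r}, expected class"
                    )
                continue
            if node.parent_sunid not in self.nodes:
                raise IntegrityError(
                    f"node {node.sunid} references missing parent {node.parent_sunid}"
                )
            parent = self.nodes[node.parent_sunid]
            if LEVEL_INDEX[node.level] != LEVEL_INDEX[parent.level] + 1:
                raise IntegrityError(
                    f"node {node.sunid} ({node.level}) is not one level below "
                    f"parent {parent.sunid} ({parent.level})"
                )
            if parent.sccs and node.sccs and not node.sccs.startswith(parent.sccs):
                raise IntegrityError(
                    f"sccs {node.sccs!r} of node {node.sunid} does not extend "
                    f"parent sccs {parent.sccs!r}"
                )


def get_ancestor(hierarchy: Hierarchy, sunid: int, level: str) -> Optional[int]:
    """Module-level convenience wrapper around :meth:`Hierarchy.get_ancestor`."""
    return hierarchy.get_ancestor(sunid, level)


@dataclass(frozen=True)
class Segment:
    """One chain-anchored piece of a domain definition."""

    chain_id: str
    range: ResidueRange


@dataclass
class DomainDefinition:
    """A classified domain: where it lives on its chain(s) and its sequence.

    ``segments`` are sorted by (chain_id, start) and non-overlapping within a
    chain; ``sequence`` is the SEQRES-based amino-acid string concatenated
    over the segments.  A domain spanning more than one chain is a *genetic
    domain*; such domains are flagged and never used as prediction targets.
    """

    sid: str
    sunid: int
    segments: List[Segment]
    sequence: str

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.chain_id, s.range.start)
        )
        by_chain: Dict[str, List[ResidueRange]] = {}
        for seg in self.segments:
            by_chain.setdefault(seg.chain_id, []).append(seg.range)
        for chain, rs in by_chain.items():
            for a, b in zip(rs, rs[1:]):
                if a.overlaps(b):
                    raise IntegrityError(
                        f"domain {self.sid}: overlapping segments on chain {chain}"
                    )
        total = sum(len(s.range) for s in self.segments)
        if self.sequence and total != len(self.sequence):
            raise IntegrityError(
                f"domain {self.sid}: sequence length {len(self.sequence)} != "
                f"total segment length {total}"
            )

    @property
    def chain_id(self) -> str:
        return self.segments[0].chain_id

    @property
    def ranges(self) -> List[ResidueRange]:
        return [s.range for s in self.segments]

    @property
    def is_genetic(self) -> bool:
        return len({s.chain_id for s in self.segments}) > 1

    @property
    def total_length(self) -> int:
        return sum(len(s.range) for s in self.segments)


ChainKey = Tuple[str, str]  # (pdb_id, chain_id)


@dataclass
class ChainRecord:
    """A query or reference chain with its deposited sequence and metadata.

    ``observed_ranges`` is the union of residues present in the ATOM records,
    expressed in SEQRES index space.  ``resolution`` is in angstroms, or
    ``None`` for non-crystallographic entries.
    """

    pdb_id: str
    chain_id: str
    seqres: str
    observed_ranges: List[ResidueRange] = field(default_factory=list)
    resolution: Optional[float] = None
    description: str = ""
    author_numbering: Optional[Dict[int, str]] = None

    def __post_init__(self) -> None:
        self.observed_ranges = sorted(
            self.observed_ranges, key=lambda r: (r.start, r.end)
        )
        prev_end = 0
        for r in self.observed_ranges:
            if r.start <= prev_end:
                raise IntegrityError(
                    f"chain {self.key}: observed ranges overlap or unsorted"
                )
            if r.end > len(self.seqres):
                raise IntegrityError(
                    f"chain {self.key}: observed range {r} outside SEQRES "
                    f"(length {len(self.seqres)})"
                )
            prev_end = r.end

    @property
    def key(self) -> ChainKey:
        return (self.pdb_id, self.chain_id)

    @property
    def n_observed(self) -> int:
        return range_union_size(self.observed_ranges)


@dataclass
class Parameters:
    """Tunable thresholds of the classification pipeline.

    The first six mirror the published procedure: hits must be at least as
    significant as ``e_max``; an alignment must cover the target domain to
    within ``target_end_slack`` residues of each end; a domain boundary is
    extended to a chain terminus or ATOM-record gap at most
    ``extension_limit`` residues away; an observed region longer than
    ``unassigned_limit`` residues left out of every domain blocks high
    confidence; predicted and curated boundaries agree when they differ by at
    most ``benchmark_tolerance`` residues; and entries at
    ``resolution_cutoff`` angstroms or worse are excluded from the
    high-confidence set.

    The remaining fields parameterise the sub-superfamily placement
    heuristics and the ribosomal/synthetic keyword screen.
    """

    e_max: float = 1e-4
    target_end_slack: int = 10
    extension_limit: int = 10
    unassigned_limit: int = 10
    benchmark_tolerance: int = 10
    resolution_cutoff: float = 3.0
    # sub-superfamily placement heuristics (percent identity over aligned columns)
    species_identity: float = 100.0
    protein_identity: float = 90.0
    family_identity: float = 70.0
    # entry-description keywords flagging ribosomal/synthetic chains
    exclusion_keywords: Tuple[str, ...] = ("ribosom", "synthetic construct")
    # hits with E-value above this are never reported by the search backend
    e_report: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "e_max",
            "target_end_slack",
            "extension_limit",
            "unassigned_limit",
            "benchmark_tolerance",
            "resolution_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")
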