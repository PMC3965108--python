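"""Local-alignment search of query chains against the classified-domain set.

The default backend performs affine-gap Smith-Waterman local alignment
(BLOSUM62; gap cost 12 for the first gapped position, 1 per additional
position) via ``Bio.Align.PairwiseAligner`` and converts raw scores to
expectation values with the Karlin-Altschul formula

    E = K * m * n * exp(-lambda * S)

where ``m`` is the query length, ``n`` the summed length of the database
and (lambda, K) are pinned to gapped-BLOSUM62-style constants.  The backend
is deliberately simple: it does not claim to reproduce any particular BLAST
build's statistics, only its qualitative behaviour -- homologous pairs at
domain-scale lengths score many hundreds of bits and pass any practical
threshold, while chance similarities between unrelated sequences do not.

Secondary hits to the same target (e.g. an internally duplicated query) are
found by masking the aligned query region with ``X`` and re-aligning, up to
a small number of rounds.

Hit filtering keeps alignments that are at least as significant as the
E-value threshold *and* cover most of the target domain, defined as missing
at most ``target_end_slack`` residues from each end of the target sequence.
Surviving hits are grouped by the PDB chain their target domains belong to,
and groups are ranked by the total number of distinct query residues they
cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .core_model import (
    ChainKey,
    Parameters,
    ResidueRange,
    range_union_size,
    ranges_to_set,
)
from .errors import IntegrityError, UnknownIdentifierError
from .scop_io import ReleaseBundle, _read_fasta, _wrap

# Karlin-Altschul parameters for gapped BLOSUM62-style scoring.
KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = -12  # cost of the first position of a gap
GAP_EXTEND = -1

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(str(_BLOSUM62.alphabet))

MAX_HITS_PER_TARGET = 4


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _sanitize(seq: str) -> str:
    """Uppercase and map residues outside the scoring alphabet to X."""
    seq = seq.upper()
    if all(c in _ALPHABET for c in seq):
        return seq
    return "".join(c if c in _ALPHABET else "X" for c in seq)


def e_value(score: float, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a query chain against a classified domain."""

    query_range: ResidueRange
    target_sid: str
    target_range: ResidueRange  # 1-based over the domain's concatenated sequence
    e_value: float
    percent_identity: float
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("negative E-value")
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("percent identity outside [0, 100]")


@dataclass
class HitGroup:
    """All filtered hits whose targets live on one classified PDB chain."""

    target_chain_key: ChainKey
    hits: List[AlignmentHit]
    coverage: int  # distinct query residues covered by the group's hits

    @property
    def best_e_value(self) -> float:
        return min(h.e_value for h in self.hits)


@dataclass(frozen=True)
class DomainInfo:
    """Index entry for one searchable domain."""

    sid: str
    sunid: int
    length: int
    chain_key: ChainKey
    sccs: str
    is_genetic: bool
    whole_chain: bool  # domain covers every observed residue of its chain


class DomainDatabase:
    """Sequence database over a release's domains, plus the chain SEQRES set.

    Genetic (multi-chain) domains are indexed and searched -- homology to
    them must be detectable for confidence gating -- but they are excluded
    from the exported searchable FASTA and never used as prediction targets.
    """

    def __init__(
        self,
        entries: Dict[str, DomainInfo],
        sequences: Dict[str, str],
        chain_seqres: Dict[ChainKey, str],
    ) -> None:
        self.entries = entries
        self.sequences = sequences
        self.chain_seqres = chain_seqres
        self.total_length = sum(len(s) for s in sequences.values())

    def __contains__(self, sid: str) -> bool:
        return sid in self.entries

    def info(self, sid: str) -> DomainInfo:
        try:
            return self.entries[sid]
        except KeyError:
            raise UnknownIdentifierError(f"unknown target sid {sid!r}") from None

    @classmethod
    def from_bundle(cls, bundle: ReleaseBundle) -> "DomainDatabase":
        entries: Dict[str, DomainInfo] = {}
        sequences: Dict[str, str] = {}
        for dom in bundle.domains.values():
            if not dom.sequence:
                continue
            pdb_id = dom.sid[1:5]
            chain_key = (pdb_id, dom.chain_id)
            chain = bundle.chains.get(chain_key)
            whole = False
            if chain is not None and not dom.is_genetic:
                dom_set = ranges_to_set(dom.ranges)
                obs_set = ranges_to_set(chain.observed_ranges)
                whole = obs_set <= dom_set and bool(obs_set)
            node = bundle.hierarchy.node(dom.sunid)
            entries[dom.sid] = DomainInfo(
                sid=dom.sid,
                sunid=dom.sunid,
                length=dom.total_length,
                chain_key=chain_key,
                sccs=node.sccs,
                is_genetic=dom.is_genetic,
                whole_chain=whole,
            )
            sequences[dom.sid] = _sanitize(dom.sequence)
        chain_seqres = {k: c.seqres for k, c in bundle.chains.items()}
        return cls(entries, sequences, chain_seqres)

    # -- on-disk form used by the CLI ------------------------------------

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = ["# scope-autoclass domain index"]
        for sid in sorted(self.entries):
            e = self.entries[sid]
            lines.append(
                "\t".join(
                    [
                        sid,
                        str(e.sunid),
                        str(e.length),
                        e.chain_key[0],
                        e.chain_key[1],
                        e.sccs or "-",
                        "1" if e.is_genetic else "0",
                        "1" if e.whole_chain else "0",
                    ]
                )
            )
        (out / "index.tsv").write_text("\n".join(lines) + "\n")
        with open(out / "sequences.fa", "w") as fh:
            for sid in sorted(self.sequences):
                fh.write(f">{sid}\n{_wrap(self.sequences[sid])}\n")
        with open(out / "chain_seqres.fa", "w") as fh:
            for key in sorted(self.chain_seqres):
                fh.write(f">{key[0]}_{key[1]}\n{_wrap(self.chain_seqres[key])}\n")

    @classmethod
    def load(cls, db_dir) -> "DomainDatabase":
        d = Path(db_dir)
        entries: Dict[str, DomainInfo] = {}
        for line in (d / "index.tsv").read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            sid, sunid, length, pdb, chain, sccs, genetic, whole = line.split("\t")
            entries[sid] = DomainInfo(
                sid=sid,
                sunid=int(sunid),
                length=int(length),
                chain_key=(pdb, chain),
                sccs="" if sccs == "-" else sccs,
                is_genetic=genetic == "1",
                whole_chain=whole == "1",
            )
        sequences = {h.split()[0]: s for h, s in _read_fasta(d / "sequences.fa")}
        chain_seqres = {}
        for h, s in _read_fasta(d / "chain_seqres.fa"):
            pdb, chain = h.split()[0].split("_", 1)
            chain_seqres[(pdb, chain)] = s
        return cls(entries, sequences, chain_seqres)


def _alignment_extents(alignment) -> Tuple[ResidueRange, ResidueRange]:
    qb, tb = alignment.aligned
    q = ResidueRange(int(qb[0][0]) + 1, int(qb[-1][1]))
    t = ResidueRange(int(tb[0][0]) + 1, int(tb[-1][1]))
    return q, t


def _percent_identity(alignment) -> float:
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / columns if columns else 0.0


def search(
    query_seqres: str,
    domain_db: DomainDatabase,
    params: Optional[Parameters] = None,
) -> List[AlignmentHit]:
    """Align *query_seqres* against every indexed domain sequence.

    Returns every local alignment with expectation value at or below
    ``params.e_report`` (default 10), at most :data:`MAX_HITS_PER_TARGET`
    per target via query masking.  Deterministic: targets are scanned in
    sid order and the aligner's first optimal trace is taken.
    """
    if not query_seqres:
        raise ValueError("empty query sequence")
    params = params or Parameters()
    query = _sanitize(query_seqres)
    aligner = make_aligner()
    hits: List[AlignmentHit] = []
    for sid in sorted(domain_db.sequences):
        target = domain_db.sequences[sid]
        if not target:
            continue
        masked = query
        for _ in range(MAX_HITS_PER_TARGET):
            alignments = aligner.align(masked, target)
            try:
                best = alignments[0]
            except IndexError:  # no positive-scoring local alignment
                break
            if best.score <= 0:
                break
            ev = e_value(best.score, len(query), domain_db.total_length)
            if ev > params.e_report:
                break
            q_range, t_range = _alignment_extents(best)
            hits.append(
                AlignmentHit(
                    query_range=q_range,
                    target_sid=sid,
                    target_range=t_range,
                    e_value=ev,
                    percent_identity=round(_percent_identity(best), 2),
                    score=float(best.score),
                )
            )
            masked = (
                masked[: q_range.start - 1]
                + "X" * len(q_range)
                + masked[q_range.end :]
            )
    hits.sort(key=lambda h: (h.target_sid, h.query_range.start, h.query_range.end))
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    domain_db: DomainDatabase,
    params: Parameters,
) -> List[AlignmentHit]:
    """Keep hits at least as significant as ``e_max`` that cover most of the
    target domain (missing at most ``target_end_slack`` residues per end)."""
    kept = []
    for hit in hits:
        target_len = domain_db.info(hit.target_sid).length
        if hit.e_value > params.e_max:
            continue
        if hit.target_range.start > 1 + params.target_end_slack:
            continue
        if hit.target_range.end < target_len - params.target_end_slack:
            continue
        kept.append(hit)
    return kept


def group_and_rank(
    hits: Iterable[AlignmentHit],
    domain_db: DomainDatabase,
) -> List[HitGroup]:
    """Group filtered hits by target PDB chain and rank by query coverage.

    Coverage is the size of the *union* of query residues over a group's
    hits, so overlapping hits are not double-counted.  Ties break on the
    group's best (smallest) E-value, then lexicographically on the chain
    key, which keeps the ranking deterministic.
    """
    by_chain: Dict[ChainKey, List[AlignmentHit]] = {}
    for hit in hits:
        key = domain_db.info(hit.target_sid).chain_key
        by_chain.setdefault(key, []).append(hit)
    groups = [
        HitGroup(
            target_chain_key=key,
            hits=sorted(hs, key=lambda h: (h.query_range.start, h.target_sid)),
            coverage=range_union_size([h.query_range for h in hs]),
        )
        for key, hs in by_chain.items()
    ]
    groups.sort(key=lambda g: (-g.coverage, g.best_e_value, g.target_chain_key))
    return groups


def dump_hits_tsv(query_key: ChainKey, hits: Iterable[AlignmentHit]) -> str:
    """Tabular hit dump (one line per hit)."""
    lines = [
        "query\ttarget_sid\tq_start\tq_end\tt_start\tt_end\te_value\tpct_id"
    ]
    for h in hits:
        lines.append(
            f"{query_key[0]}_{query_key[1]}\t{h.target_sid}\t"
            f"{h.query_range.start}\t{h.query_range.end}\t"
            f"{h.target_range.start}\t{h.target_range.end}\t"
            f"{h.e_value:.3g}\t{h.percent_identity:.2f}"
        )
    return "\n".join(lines) + "\n"
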