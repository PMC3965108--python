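"""Reading and writing SCOP-compatible release files.

A release is exchanged as a set of plain-text files:

``dir.des``
    Node descriptions, tab-separated: ``sunid  level-code  sccs  sid
    description`` with level codes ``cl, cf, sf, fa, dm, sp, px`` for class,
    fold, superfamily, family, protein, species and domain.
``dir.hie``
    Tree edges: ``sunid  parent_sunid  comma-list-of-children`` (``-`` for
    no parent / no children).
``dir.cla``
    Domain classifications: ``sid  pdb_id  region  sccs  sunid
    cl=..,cf=..,sf=..,fa=..,dm=..,sp=..,px=..``.
``domains.fa`` / ``genetic.fa``
    ASTRAL-style SEQRES-based domain sequences; genetic (multi-chain)
    domains live in the auxiliary file and are excluded from the searchable
    set.  Headers: ``>sid pdb_id region (sccs)``.
``chains.fa``
    Chain SEQRES sequences with entry metadata encoded as ``key=value``
    tokens in the header: ``>pdbid_chain observed=2-547 resolution=1.80
    description=...``.

All files are UTF-8 with LF line endings and a single ``#`` header line
carrying the version label.  The writer orders records by sunid (chains by
key), so write∘read∘write is byte-stable.

Region strings follow the grammar ``chain:start-end`` with comma-joined
segments (``A:2-224,A:226-544``; a genetic domain mixes chains).  The
reader additionally accepts the whole-chain shorthand ``chain:`` and ``-``
for chainless entries; the writer always emits explicit ranges.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core_model import (
    ChainKey,
    ChainRecord,
    DomainDefinition,
    Hierarchy,
    HierarchyNode,
    LEVELS,
    ResidueRange,
    Segment,
)
from .errors import IntegrityError, ParseError

LEVEL_CODES = {
    "class": "cl",
    "fold": "cf",
    "superfamily": "sf",
    "family": "fa",
    "protein": "dm",
    "species": "sp",
    "domain": "px",
}
CODE_LEVELS = {v: k for k, v in LEVEL_CODES.items()}

FASTA_WIDTH = 60


@dataclass
class ReleaseBundle:
    """A complete classified release held in memory."""

    hierarchy: Hierarchy
    domains: Dict[str, DomainDefinition] = field(default_factory=dict)
    chains: Dict[ChainKey, ChainRecord] = field(default_factory=dict)
    version_label: str = "fixture-0"

    def validate(self) -> None:
        self.hierarchy.validate()
        for dom in self.domains.values():
            if dom.sunid not in self.hierarchy:
                raise IntegrityError(
                    f"domain {dom.sid} references unknown sunid {dom.sunid}"
                )
            if self.hierarchy.node(dom.sunid).level != "domain":
                raise IntegrityError(
                    f"domain {dom.sid} sunid {dom.sunid} is not a domain-level node"
                )
        referenced = {
            seg.chain_id for d in self.domains.values() for seg in d.segments
        }
        chain_ids = {c for (_, c) in self.chains}
        missing = referenced - chain_ids
        if missing:
            raise IntegrityError(
                f"domains reference chains absent from release: {sorted(missing)}"
            )

    def domains_on_chain(self, key: ChainKey) -> List[DomainDefinition]:
        pdb_id, chain_id = key
        out = []
        for dom in self.domains.values():
            dom_pdb = _pdb_of_sid(dom.sid)
            if dom_pdb == pdb_id and any(
                s.chain_id == chain_id for s in dom.segments
            ):
                out.append(dom)
        return sorted(out, key=lambda d: d.ranges[0].start)


def _pdb_of_sid(sid: str) -> str:
    # sid layout: 'd' + 4-char pdb id + chain letter + domain counter
    return sid[1:5]


# ---------------------------------------------------------------------------
# region strings


def format_region(segments: Sequence[Segment]) -> str:
    return ",".join(f"{s.chain_id}:{s.range}" for s in segments)


def parse_region(
    text: str,
    chain_lengths: Optional[Dict[str, int]] = None,
) -> List[Segment]:
    """Parse a cla region string into segments.

    ``chain:`` (whole chain) needs *chain_lengths* to resolve; ``-`` yields
    a single chainless segment and is not produced by this package's writer.
    """
    segments: List[Segment] = []
    for part in text.split(","):
        part = part.strip()
        if part == "-":
            raise ValueError("chainless region strings are not supported")
        if ":" not in part:
            raise ValueError(f"bad region segment {part!r}")
        chain, _, rng = part.partition(":")
        if rng:
            segments.append(Segment(chain, ResidueRange.parse(rng)))
        else:
            if not chain_lengths or chain not in chain_lengths:
                raise ValueError(
                    f"whole-chain region {part!r} needs the chain length"
                )
            segments.append(Segment(chain, ResidueRange(1, chain_lengths[chain])))
    return segments


# ---------------------------------------------------------------------------
# writing


def _wrap(seq: str) -> str:
    return "\n".join(
        seq[i : i + FASTA_WIDTH] for i in range(0, len(seq), FASTA_WIDTH)
    )


def _des_lines(bundle: ReleaseBundle) -> Iterable[str]:
    yield f"# dir.des {bundle.version_label}"
    for sunid in bundle.hierarchy:
        n = bundle.hierarchy.node(sunid)
        yield "\t".join(
            [
                str(n.sunid),
                LEVEL_CODES[n.level],
                n.sccs or "-",
                n.sid or "-",
                n.description or "-",
            ]
        )


def _hie_lines(bundle: ReleaseBundle) -> Iterable[str]:
    yield f"# dir.hie {bundle.version_label}"
    for sunid in bundle.hierarchy:
        n = bundle.hierarchy.node(sunid)
        kids = bundle.hierarchy.children(sunid)
        yield "\t".join(
            [
                str(sunid),
                "-" if n.parent_sunid is None else str(n.parent_sunid),
                ",".join(map(str, kids)) if kids else "-",
            ]
        )


def _cla_lines(bundle: ReleaseBundle) -> Iterable[str]:
    yield f"# dir.cla {bundle.version_label}"
    for dom in sorted(bundle.domains.values(), key=lambda d: d.sunid):
        lineage = []
        for level in LEVELS:
            anc = bundle.hierarchy.get_ancestor(dom.sunid, level)
            lineage.append(f"{LEVEL_CODES[level]}={anc}")
        node = bundle.hierarchy.node(dom.sunid)
        yield "\t".join(
            [
                dom.sid,
                _pdb_of_sid(dom.sid),
                format_region(dom.segments),
                node.sccs or "-",
                str(dom.sunid),
                ",".join(lineage),
            ]
        )


def _domain_fasta(bundle: ReleaseBundle, genetic: bool) -> str:
    buf = io.StringIO()
    for dom in sorted(bundle.domains.values(), key=lambda d: d.sunid):
        if dom.is_genetic != genetic:
            continue
        if not dom.sequence:
            continue
        node = bundle.hierarchy.node(dom.sunid)
        buf.write(
            f">{dom.sid} {_pdb_of_sid(dom.sid)} "
            f"{format_region(dom.segments)} ({node.sccs or '-'})\n"
        )
        buf.write(_wrap(dom.sequence) + "\n")
    return buf.getvalue()


def write_domain_fasta(bundle: ReleaseBundle) -> str:
    """FASTA text of the searchable (non-genetic) domain sequence set."""
    return _domain_fasta(bundle, genetic=False)


def _chain_fasta(bundle: ReleaseBundle) -> str:
    buf = io.StringIO()
    for key in sorted(bundle.chains):
        ch = bundle.chains[key]
        obs = ",".join(str(r) for r in ch.observed_ranges) or "-"
        res = "NA" if ch.resolution is None else f"{ch.resolution:.2f}"
        buf.write(
            f">{ch.pdb_id}_{ch.chain_id} observed={obs} resolution={res} "
            f"description={ch.description}\n"
        )
        buf.write(_wrap(ch.seqres) + "\n")
    return buf.getvalue()


def write_release(bundle: ReleaseBundle, out_dir) -> Dict[str, Path]:
    """Write a bundle to *out_dir* as the canonical file set.

    Returns a mapping from logical file name to path.  Output ordering is
    deterministic (by sunid / chain key) regardless of insertion order.
    """
    bundle.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "des": out / "dir.des",
        "hie": out / "dir.hie",
        "cla": out / "dir.cla",
        "domains": out / "domains.fa",
        "genetic": out / "genetic.fa",
        "chains": out / "chains.fa",
    }
    files["des"].write_text("\n".join(_des_lines(bundle)) + "\n")
    files["hie"].write_text("\n".join(_hie_lines(bundle)) + "\n")
    files["cla"].write_text("\n".join(_cla_lines(bundle)) + "\n")
    files["domains"].write_text(write_domain_fasta(bundle))
    files["genetic"].write_text(_domain_fasta(bundle, genetic=True))
    files["chains"].write_text(_chain_fasta(bundle))
    return files


# ---------------------------------------------------------------------------
# reading


def _data_lines(path) -> Iterable[Tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _header_label(path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        parts = first.split(maxsplit=2)
        if len(parts) >= 3:
            return parts[2]
    return ""


def read_hierarchy(des_path, hie_path) -> Tuple[Hierarchy, str]:
    """Parse dir.des + dir.hie into a :class:`Hierarchy`."""
    descriptions: Dict[int, Tuple[str, str, str, str]] = {}
    for lineno, line in _data_lines(des_path):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError(des_path, lineno, f"expected 5 fields, got {len(fields)}")
        sunid_s, code, sccs, sid, desc = fields
        if code not in CODE_LEVELS:
            raise ParseError(des_path, lineno, f"unknown level code {code!r}")
        try:
            sunid = int(sunid_s)
        except ValueError:
            raise ParseError(des_path, lineno, f"bad sunid {sunid_s!r}") from None
        descriptions[sunid] = (
            CODE_LEVELS[code],
            "" if sccs == "-" else sccs,
            "" if sid == "-" else sid,
            "" if desc == "-" else desc,
        )

    parents: Dict[int, Optional[int]] = {}
    for lineno, line in _data_lines(hie_path):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(hie_path, lineno, f"expected 3 fields, got {len(fields)}")
        try:
            sunid = int(fields[0])
            parent = None if fields[1] == "-" else int(fields[1])
        except ValueError:
            raise ParseError(hie_path, lineno, "bad sunid field") from None
        if sunid not in descriptions:
            raise IntegrityError(
                f"{hie_path}: sunid {sunid} (line {lineno}) missing from dir.des"
            )
        if parent is not None and parent not in descriptions:
            raise IntegrityError(
                f"{hie_path}: parent sunid {parent} (line {lineno}) missing from dir.des"
            )
        parents[sunid] = parent

    hierarchy = Hierarchy()
    for sunid in sorted(descriptions):
        level, sccs, sid, desc = descriptions[sunid]
        if sunid not in parents:
            raise IntegrityError(f"sunid {sunid} present in dir.des but not dir.hie")
        hierarchy.add(
            HierarchyNode(
                sunid=sunid,
                level=level,
                sccs=sccs,
                sid=sid,
                parent_sunid=parents[sunid],
                description=desc,
            )
        )
    hierarchy.validate()
    return hierarchy, _header_label(des_path)


def _read_fasta(path) -> List[Tuple[str, str]]:
    """Minimal ordered FASTA reader returning (header, sequence) pairs."""
    records: List[Tuple[str, str]] = []
    header: Optional[str] = None
    chunks: List[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def _parse_chain_header(header: str, path) -> dict:
    name, _, rest = header.partition(" ")
    if "_" not in name:
        raise ParseError(path, 0, f"bad chain record name {name!r}")
    pdb_id, chain_id = name.split("_", 1)
    observed: List[ResidueRange] = []
    resolution: Optional[float] = None
    description = ""
    tokens = rest.split(" ")
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.startswith("observed="):
            val = tok[len("observed=") :]
            if val != "-":
                observed = [ResidueRange.parse(p) for p in val.split(",")]
        elif tok.startswith("resolution="):
            val = tok[len("resolution=") :]
            resolution = None if val == "NA" else float(val)
        elif tok.startswith("description="):
            description = " ".join([tok[len("description=") :]] + tokens[i + 1 :])
            break
        i += 1
    return dict(
        pdb_id=pdb_id,
        chain_id=chain_id,
        observed_ranges=observed,
        resolution=resolution,
        description=description,
    )


def read_release(des_path, hie_path, cla_path, fasta_paths) -> ReleaseBundle:
    """Assemble a :class:`ReleaseBundle` from parseable files plus FASTA.

    *fasta_paths* is a sequence of FASTA files; chain files are recognised
    by the ``observed=`` metadata token in their headers, the rest are
    domain sequence files (searchable and genetic alike).
    """
    hierarchy, label = read_hierarchy(des_path, hie_path)

    chains: Dict[ChainKey, ChainRecord] = {}
    domain_seqs: Dict[str, str] = {}
    for path in fasta_paths:
        for header, seq in _read_fasta(path):
            if "observed=" in header:
                rec = ChainRecord(seqres=seq, **_parse_chain_header(header, path))
                chains[rec.key] = rec
            else:
                sid = header.split()[0]
                domain_seqs[sid] = seq

    domains: Dict[str, DomainDefinition] = {}
    for lineno, line in _data_lines(cla_path):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(cla_path, lineno, f"expected 6 fields, got {len(fields)}")
        sid, pdb_id, region, sccs, sunid_s, _lineage = fields
        try:
            sunid = int(sunid_s)
        except ValueError:
            raise ParseError(cla_path, lineno, f"bad sunid {sunid_s!r}") from None
        if sunid not in hierarchy:
            raise IntegrityError(
                f"{cla_path}: line {lineno}: sunid {sunid} not in hierarchy"
            )
        lengths = {
            c: len(chains[(pdb_id, c)].seqres)
            for (p, c) in chains
            if p == pdb_id
        }
        try:
            segments = parse_region(region, lengths)
        except ValueError as exc:
            raise ParseError(cla_path, lineno, str(exc)) from None
        domains[sid] = DomainDefinition(
            sid=sid,
            sunid=sunid,
            segments=segments,
            sequence=domain_seqs.get(sid, ""),
        )

    bundle = ReleaseBundle(
        hierarchy=hierarchy,
        domains=domains,
        chains=chains,
        version_label=label or "unknown",
    )
    bundle.validate()
    return bundle


def read_release_dir(release_dir) -> ReleaseBundle:
    """Read a release from a directory laid out by :func:`write_release`."""
    d = Path(release_dir)
    fastas = [
        p
        for p in (d / "domains.fa", d / "genetic.fa", d / "chains.fa")
        if p.exists()
    ]
    return read_release(d / "dir.des", d / "dir.hie", d / "dir.cla", fastas)
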