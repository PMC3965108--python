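# Methods

This note records what the pipeline computes, the assumptions behind
each stage, the default parameters and why they have those values, what
the synthetic fixtures do and do not emulate, and the design decisions
that were left open by the problem statement and resolved here.

## Model of the data

A *release* is a hierarchy of nodes (class → fold → superfamily →
family → protein → species → domain), a set of domain definitions, and a
set of chain records. Identifiers follow SCOP conventions: integer
`sunid`s, 7-character `sid`s (`d` + PDB id + chain letter + domain
ordinal), and dotted `sccs` strings whose components are prefixes down
the lineage (`c.1`, `c.1.1`, `c.1.1.1`). True structural classes use
letters `a`–`g`; letters beyond `g` mark non-structural categories
(e.g. synthetic constructs), which the gate excludes.

All residue coordinates are 1-based inclusive SEQRES positions.
A chain's *observed* residues (those resolved in the structure) are a
sorted list of disjoint ranges; everything downstream — boundary
assignment, unassigned-region detection, benchmarking — operates on the
observed set, because curators only draw boundaries through residues
that exist in the model.

## Pipeline assumptions

- **Homology transfer is valid.** The pipeline only classifies chains
  with strong local-alignment hits to already-classified domains; it
  never proposes new folds or superfamilies. Chains without qualifying
  hits are counted as attempted-but-unclassifiable.
- **Near-full-domain hits imply shared architecture.** The filter
  demands the alignment reach within `target_end_slack` residues of
  both ends of the target domain, so a hit represents "this whole
  domain occurs here", not a shared fragment.
- **One source chain explains the query.** Hits are grouped by the
  chain their targets live on and the single best-covering group is
  used, mirroring the curator practice of copying one template's
  decomposition rather than mixing templates.
- **Boundary uncertainty is small and local.** Curated boundaries are
  themselves somewhat arbitrary in linkers, so extensions, linker
  absorption and the benchmark tolerance all use the same 10-residue
  scale.

## Parameters (defaults and rationale)

| Parameter | Default | Rationale |
|---|---|---|
| `e_max` | 1e-4 | Inclusive significance cutoff for transferring a classification; conservative for BLOSUM62 local alignments of domain length. |
| `target_end_slack` | 10 | A hit must cover the target domain to within this many residues per end; allows frayed termini without admitting fragment hits. |
| `extension_limit` | 10 | Predicted ends within this distance of a terminus or gap edge are extended to it, matching curator treatment of short unresolved tails. |
| `unassigned_limit` | 10 | An observed run longer than this outside every prediction suggests a missed domain and blocks the high-confidence gate. |
| `benchmark_tolerance` | 10 | Max per-boundary deviation for a prediction to count as correct; same scale as the boundary-uncertainty assumption above. |
| `resolution_cutoff` | 3.0 Å | Entries at or above this resolution are gated out; low-resolution models have unreliable residue-level boundaries. Entries with no stated resolution (e.g. NMR) are exempt. |
| `species_identity` | 100% | Species is inherited only for an identical, fully covering match. |
| `protein_identity` | 90% | Protein-level inheritance still requires full target coverage. |
| `family_identity` | 70% | Below this the domain goes to an "automated matches" fallback under the superfamily (see D3 below). |
| `exclusion_keywords` | "ribosom", "synthetic construct" | Case-insensitive description substrings gating out entries whose domain decomposition needs manual judgement. |
| `e_report` | 10 | Loose reporting threshold for raw (pre-filter) hit listings. |

Alignment scoring: BLOSUM62, gap open 12, gap extend 1; Karlin–Altschul
`E = K·m·n·exp(−λS)` with λ = 0.267, K = 0.041 (standard values for
these scoring parameters). `m` is the query length, `n` the total
database length. E-values are computed analytically, not by simulation,
so they are deterministic and backend-independent.

Secondary hits to the same target are found by masking earlier hit
regions of the query with `X` (scored as mismatch everywhere) and
re-aligning, up to 4 rounds per target. This finds internal repeats
without a full suboptimal-alignment enumeration.

## Confidence gate

Eight reason codes, each a pure predicate of the prediction set, the
chain, the top hit group, the database, and (two codes) the entry
metadata or the full filtered hit list:

`NO_HITS`, `LOW_RESOLUTION`, `RIBOSOMAL_OR_SYNTHETIC`,
`GENETIC_DOMAIN_HOMOLOG`, `TARGET_NOT_WHOLE_CHAIN`,
`MULTIDOMAIN_SHAPE`, `UNASSIGNED_REGION`, `DUPLICATE_TARGET_DOMAIN`.

Because the predicates are independent and side-effect free, the set of
codes (and hence the verdict) does not depend on evaluation order; the
test suite shuffles the rule order to enforce this. Acceptance is
exactly "no codes fired".

## Synthetic fixtures

The generator builds releases with one class, one fold/superfamily/
family lineage per superfamily, and families populated by a seed
sequence plus point-mutated siblings (5% default within-family rate,
substitutions always change the residue). Chains are single-domain by
default; a configurable fraction are two-domain chains joined by a
5-residue linker. Derived queries mutate a reference chain's SEQRES at
a given rate, optionally punch unobserved gaps, and carry the clipped
reference decomposition as ground truth.

What this emulates: sequence divergence within families, multi-domain
decomposition, unobserved regions, release growth (derived queries
appended as newly curated chains, with optional boundary perturbation).
What it does not emulate: real substitution processes (mutations are
uniform over the 19 alternatives), indel evolution, structural
divergence without sequence divergence (remote homologs below ~30%
identity), genetic-domain biology, or realistic resolution/description
metadata beyond what the gate needs.

The worked-example fixture is constructed so that the real alignment
backend — not canned numbers — reproduces the headline hits: the query
carries exact copies of two reference domain sequences at positions
2–224 and 226–544, with residues 1, 225 and 545–554 forced to differ so
the local alignments cannot extend past the domain copies, and observed
residues 2–547 so the second prediction's extension target is 547.

## Numerical choices

- Percent identity is `100 · identities / alignment columns` (gaps
  count as columns), rounded to two decimals.
- Percent displays: values ≥1% (and exact zero) get one decimal;
  values below 1% get one significant figure, re-checked after rounding
  (so 0.07736% → `0.08%`, 0.7534% → `0.8%`). Counts in rate strings are
  thousands-grouped with spaces: `0.08% (62 of 80 140)`.
- A segment-count mismatch between prediction and curated domain is an
  infinite boundary deviation (always a `boundary_mismatch`), because
  per-segment deviations are undefined.
- All iteration orders that reach output files are explicitly sorted
  (sunid, chain key, sid), making every writer byte-stable.

## Open design decisions

- **D1 — interior linkers.** When two predictions are separated by a
  short (≤ `extension_limit`) observed linker, the linker is appended to
  the *preceding* domain. Appending to the following domain or
  splitting the linker would be equally defensible; preceding-domain
  absorption was chosen because it reproduces the worked example's
  boundary pair (…225 / 226…) and is the simpler rule.
- **D2 — tie-breaking among hit groups.** Equal-coverage groups are
  ordered by best E-value, then lexicographic chain key. Any
  deterministic rule suffices; this one needs no extra state.
- **D3 — placement depth thresholds.** The species/protein/family
  identity thresholds (100/90/70) are heuristics, not fitted values.
  In particular the family threshold is genuinely underdetermined: a
  55%-identity full-coverage match is placed in an "automated matches"
  family under the superfamily rather than in the source family. The
  thresholds are `Parameters` fields so they can be varied without code
  changes.
- **D4 — multi-domain gate shape.** Beyond two domains, automated
  decomposition is accepted only when the query is sequence-identical
  to the target chain; otherwise a human should decide. Exactly-two
  contiguous domains are accepted because the single internal boundary
  is directly supported by the two hits.

## Limitations

- Sequence-only: no structure comparison, so remote homologs invisible
  to BLOSUM62 local alignment are never classified (by design — they
  fall to manual curation).
- The Karlin–Altschul parameters are fixed constants, not estimated per
  database composition; E-values are approximate for very short or
  compositionally biased sequences.
- Genetic (multi-chain) domains are indexed and gated against but never
  predicted.
- The benchmark's greedy overlap pairing can, for pathological overlap
  patterns, differ from an optimal assignment; with the 10-residue
  tolerance and realistic decompositions this does not occur in the
  test suite.
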