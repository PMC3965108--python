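# scope-autoclass

Automated transfer of curated protein-domain classifications to newly
solved structures, in the style of the SCOP/SCOPe family of databases.

## The problem

Structural classifications such as SCOP organise protein domains into a
seven-level hierarchy — class, fold, superfamily, family, protein,
species, domain — where each domain is a region of one (or, for genetic
domains, more than one) PDB chain, written in 1-based inclusive SEQRES
coordinates (e.g. `A:2-224,A:226-544`). Manual curation cannot keep pace
with deposition rates, but most new chains are close homologs of
already-classified ones. The automatable core of the curation process
is:

1. find classified domains that align well to the new chain,
2. transfer their boundaries onto the new chain,
3. inherit their hierarchy placement, and
4. accept the result only when a battery of conservative checks passes,
   so the automated set can be published at near-curated accuracy.

`scope-autoclass` implements that pipeline end to end, plus the
infrastructure around it: parseable release files, a benchmark that
scores predictions against later manual curation, release diffing, and a
deterministic synthetic-fixture generator so everything runs offline.

## Method in brief

For a query chain with SEQRES sequence $q$ and observed residues
$O \subseteq \{1,\dots,|q|\}$:

- **Search.** Local alignment (Smith–Waterman, BLOSUM62, affine gaps
  with open 12 / extend 1) of $q$ against every classified domain
  sequence. Significance uses Karlin–Altschul statistics,
  $E = K\,m\,n\,e^{-\lambda S}$ with $\lambda = 0.267$, $K = 0.041$.
  Additional non-overlapping hits to the same domain are found by
  masking previous hit regions with `X` and re-aligning.
- **Filter.** Keep hits with $E \le 10^{-4}$ that cover the target
  domain to within 10 residues of each end, and whose target is not a
  genetic (multi-chain) domain.
- **Group and rank.** Hits are grouped by the chain their target domains
  live on; groups are ranked by the union of query residues covered
  (ties: best E-value, then chain key). The top group supplies the
  domain decomposition.
- **Boundary assignment.** Each hit's query extent becomes a predicted
  domain. Ends within 10 residues of a chain terminus or the edge of an
  unobserved gap are extended to it; short (≤10-residue) observed
  linkers between adjacent predictions are absorbed into the preceding
  domain; everything is clipped to the observed set $O$.
- **Confidence gate.** A prediction set is accepted only if none of
  eight reason codes fire: no hits, low resolution (≥3.0 Å), ribosomal
  or synthetic-construct entries, homology to a genetic domain, a
  single-domain target that is not a whole chain, a multi-domain shape
  that is neither an identical chain match nor exactly two contiguous
  domains, an unassigned observed region longer than 10 residues, or two
  predictions sharing one target domain. Codes are pure predicates, so
  the verdict is independent of evaluation order.
- **Placement.** The superfamily is always inherited from the source
  domain. Species is inherited at 100% identity with full target
  coverage, protein at ≥90% with full coverage, family at ≥70%;
  otherwise the domain is placed under an "automated matches" fallback
  node created (once) at the deepest inherited level.
- **Benchmark.** Predictions are greedily paired with curated domains by
  residue overlap. A pair is *correct* when the superfamily matches,
  the segment counts agree, and every segment boundary deviates by at
  most 10 residues; otherwise it is a *superfamily_mismatch* or
  *boundary_mismatch*. Rates below 1% are reported to one significant
  figure (e.g. `0.08% (62 of 80 140)`), others to one decimal.

## Worked example

A 554-residue two-domain query chain (`1vj5` A, observed residues
2–547) is classified against a reference release containing its two
constituent domains. Running the pipeline prints:

```
chain: ('1vj5', 'A') length: 554 observed: 2-547
hit d1ek1a1 query 2-224 target 1-223 E=2.08e-145 id=100.0%
hit d1ek1a2 query 226-544 target 1-319 E=1.67e-203 id=100.0%
accepted: True
predicted 2-225 -> superfamily c.1.1 (matched)
predicted 226-547 -> superfamily c.2.1 (matched)
vs curated 2-223: correct (max boundary deviation 2)
vs curated 224-547: correct (max boundary deviation 2)
```

The first hit's end is extended from 224 to 225 (absorbing a 1-residue
linker), and the second hit's end from 544 to 547 (within 10 residues of
the last observed residue). Both predictions land within the 10-residue
benchmark tolerance of the curated boundaries 2–223 and 224–547, so the
chain scores fully correct. To reproduce:

```python
from scope_autoclass.fixtures import fig2_fixture
from scope_autoclass.classifier import classify_chain
from scope_autoclass.benchmark import score_chain

fx = fig2_fixture()
predictions, verdict = classify_chain(fx.chain, fx.database,
                                      fx.release.hierarchy)
records = score_chain(predictions, fx.curated, fx.release.hierarchy,
                      tolerance=10)
```

## Command line

```sh
scope-autoclass build-db  --release <dir> --db <dir>
scope-autoclass classify  --db <dir> --chains <fasta> --out <dir> [--seed N]
scope-autoclass benchmark --old <dir> --new <dir> --out <file> [--tolerance N]
scope-autoclass diff      --old <dir> --new <dir> --out <file>
```

All outputs are deterministic TSV/text with a header recording the
command, seed and a hash of the effective configuration. Exit codes:
0 success, 2 usage or input errors, 1 internal errors.

## Layout

- `src/scope_autoclass/core_model.py` — residue ranges, hierarchy,
  domains, chains, parameters.
- `src/scope_autoclass/scop_io.py` — parseable release files
  (`dir.des`, `dir.hie`, `dir.cla`) and FASTA sets; byte-stable writer.
- `src/scope_autoclass/seq_search.py` — alignment backend, E-values,
  hit filtering, grouping/ranking, on-disk domain database.
- `src/scope_autoclass/classifier.py` — boundary assignment, confidence
  gate, hierarchy placement, `classify_chain`.
- `src/scope_autoclass/benchmark.py` — scoring, summaries, release-pair
  benchmarking, release diffing and history.
- `src/scope_autoclass/fixtures.py` — deterministic synthetic releases,
  derived query chains, and the worked-example fixture.
- `src/scope_autoclass/cli.py` — `scope-autoclass` command group.

See `docs/methods.md` for assumptions, parameter rationale, and open
design decisions.
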