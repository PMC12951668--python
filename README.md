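# codechron

A tested, reusable pipeline for building a complexity-constrained chronology
of amino acid recruitment into the genetic code. From a 20-amino-acid ×
16-metric molecular-complexity table it computes autoscaled Euclidean
distance matrices, a classical MDS embedding with automatic dimension
selection, an ε-neighborhood (Vietoris–Rips 1-skeleton) graph, the minimum
spanning tree via Prim's algorithm, a root-to-node chronology, permutation
and path-graph null models for mutational connectivity, and associations with
amino-acid usage vectors. It also includes an in-repo calculator for the
computable subset of molecular-complexity indices (total walk count, Zagreb,
Kier kappa, Balaban J, chiral/sp³ fractions, Euclidean-norm composites) and
seeded synthetic-data generators so every stage is testable offline.

## Layout

| module | purpose |
|---|---|
| `codechron.genetic_code` | standard-code codon combinatorics: single-point mutation counts `S`, capacities `M = 9n` / `3n`, fractions `F = S/M`, per-pair background means, path-graph expectations |
| `codechron.complexity_metrics` | molecular-graph indices and the metrics-table reader (CSV; framework tags as `name#graph` / `name#information` headers) |
| `codechron.complexity_space` | autoscaling, Euclidean distance matrices with missing-pair masking, min-max normalization, Pearson/Spearman/KS matrix comparison |
| `codechron.embedding_mds` | classical (Torgerson) MDS with rank truncation, reconstruction error, minimal-dimension search |
| `codechron.tree_inference` | ε-graphs, Prim MST, root-to-node chronology, tie-grouped rank composites, Jaccard/adjacency tree comparison, TSV/Newick export |
| `codechron.enrichment_stats` | observed tree mutation counts, seeded permutation null (μ ± 1.96σ/√N CIs), path-graph null, substitution-matrix comparison |
| `codechron.usage_association` | OLS of usage on chronology scores; pooled molecular-weight correlation |
| `codechron.synthetic_data` | seeded generators: low-rank metric tables, linear usage vectors, path alkanes, uniform random (Prüfer) trees |
| `codechron.pipeline` / `codechron.cli` | end-to-end orchestration and the `codechron` command |

## CLI

```bash
codechron code --pair K N --position 3      # mutation count/fraction for a pair
codechron code --background                 # per-pair background means + path-graph E(p)
codechron metrics --graph decane.json       # in-repo indices for one molecular graph
codechron distances table.csv               # autoscale + Euclidean distance matrix
codechron compare D1.csv D2.csv             # Pearson / Spearman / KS
codechron embed distances.csv --dim 7       # classical MDS (omit --dim for auto)
codechron tree --metrics table.csv --root G # MST + root-to-node chronology
codechron enrich tree.tsv --trials 100000 --seed 42
codechron associate scores.csv usage.csv    # OLS of usage on a chronology score
codechron simulate metrics --seed 1 --out synthetic/
codechron run --metrics table.csv --out run/  # full pipeline, report.json
```

Metrics CSV format: first column `aa` (one-letter symbols, all 20 required),
one column per metric; a framework tag may be embedded in the header
(`logWCX#graph`, `FCC#information`). Missing cells are preserved and masked
pairwise in distance computations.

## Tests

```bash
python -m pytest -q tests/
```

One acceptance test, `tests/test_acceptance.py::test_full_reproduction`, is
expected to fail unless you provide the externally published 16-metric
amino-acid table at `data/reference_metrics.csv` — those values come from
external tools/databases and are not redistributable here. Everything else
runs offline from built-in or generated data.

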