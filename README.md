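# mchem

Multiplexed chemical metabolomics data analysis: derivatization-aware
annotation of non-targeted LC-MS/MS data.

## The problem

In non-targeted metabolomics most ion features are never confidently
annotated, because spectral libraries cover only a sliver of chemical space
and in-silico fragmentation is hard.  Post-column chemical derivatization
adds an orthogonal, feature-resolved layer of evidence: a reagent infused
after the chromatographic column labels specific functional groups, so each
reactive metabolite shows up twice in the same run — as the unreacted
*educt* and as a co-eluting *product* shifted by the reagent's exact net
mass change.  Detecting those educt/product pairs tells you, per feature,
which functional groups the unknown molecule carries, and that evidence can
be pushed into downstream structure annotation.

`mchem` implements the data-analysis side of such a workflow, for
mass-spectrometrists and computational metabolomics developers:

* **Reaction registry** (`mchem.reactions`) — three orthogonal labeling
  chemistries: **A** cysteine conjugation of electrophiles (Δm/z 121.0197,
  net +C3H7NO2S), **B** AQC derivatization of amines/phenols/N-hydroxy
  groups (Δm/z 170.0480, net +C10H6N2O), and **C** hydroxylamine oximation
  of aldehydes/ketones (Δm/z 15.0109, net +NH2OH −H2O = +NH).  Each reaction
  carries a curated, overridable SMARTS pattern set for its reactive groups.
* **Feature linking** (`mchem.linking`) — pairs features `p → q` when
  `|(m/z_q − m/z_p) − Δ| ≤ tol` and `|RT_q − RT_p| ≤ rt_tol`, computes the
  conversion yield `product/(product + educt) × 100 %` from
  reagent-condition areas, applies the 5 % minimum-yield cut for reaction A,
  and builds the reactivity network.
* **Spectral analog search** (`mchem.specsearch`) — modified-cosine
  similarity with exact maximum-weight one-to-one peak pairing (peaks match
  directly or shifted by the precursor mass difference), open-modification
  analog retrieval, exact-match/duplicate removal, and functional-group-first
  reranking: matches whose structures carry every observed reaction's group
  are moved ahead, preserving cosine order inside each block.
* **Evaluation** (`mchem.evalkit`) — before/after Tanimoto similarity of the
  top-1/top-5 hits to the true structure, rank of the most similar analog,
  cohort splits (improved/decreased/unchanged), and top-k accuracy for
  in-silico candidate lists.
* **Synthetic data** (`mchem.fixtures`) — seeded generators for paired
  with/without-reagent feature tables with planted edges, toy MS/MS spectra,
  and an analog benchmark where cosine alone ranks the wrong structures
  first, so every stage is testable offline with known ground truth.

## Worked example

```python
from mchem import reactions as rx, linking as lk

registry = rx.default_registry()
for r in registry:
    print(f"{r.id}  {r.reagent:<13s} {r.net_change.to_string():<10s} {r.delta_mass:.4f}")

feats = [
    lk.Feature(id="F1", mz=300.1000, rt=5.00, areas={"rx_1": 950.0},
               conditions={"rx_1": lk.Condition.DERIVATIZED}),
    lk.Feature(id="F2", mz=421.1197, rt=5.01, areas={"rx_1": 50.0},
               conditions={"rx_1": lk.Condition.DERIVATIZED}),
]
edges = lk.filter_edges(lk.attach_yields(lk.pair_features(feats, registry), feats), registry)
for e in edges:
    print(e.precursor_id, "->", e.product_id, e.reaction_id,
          f"mass_error={e.mass_error:+.4f}", f"yield={e.yield_pct:.1f}%")
```

prints

```
A  cysteine      C3H7NO2S   121.0197
B  AQC           C10H6N2O   170.0480
C  hydroxylamine HN         15.0109
F1 -> F2 A mass_error=-0.0000 yield=5.0%
```

F2 sits exactly one cysteine-adduct mass above F1 and co-elutes with it, so
it is linked as F1's reaction-A product.  Its conversion yield,
50/(50 + 950) = 5.0 %, sits exactly on the reaction-A cut and is therefore
kept (the exclusion is strict: only yields *below* 5 % are dropped).

The same flow is available from the shell:

```bash
mchem fixtures --seed 17 --out demo          # synthetic cohort + benchmark
mchem pair     --features demo/features.csv --out demo/paired
mchem search   --queries demo/queries.mgf --library demo/library.mgf --out demo/matches.csv
mchem rerank   --matches demo/matches.csv --queries demo/queries.mgf --out demo/reranked.csv
mchem evaluate --before demo/matches.csv --after demo/reranked.csv \
               --truth demo/query_truth.csv --out demo/eval
```

`demo/eval/summary.txt` reports the cohort metrics (mean top-1/top-5
Tanimoto before → after, rank of the best analog, improved/decreased
counts); annotated features are exported as MGF with `MCHEM_REACTIONS` and
`MCHEM_SMARTS` header keys, and the reactivity network as GraphML.

Formula strings accept signed segments and a trailing sign-run charge, e.g.
`"C6H12O6"`, `"+NH2OH-H2O"`, `"C43H64N3O15+"`.

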