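# chemosig

A tested, reusable pipeline for deriving and evaluating a tumor-response
gene signature for induction chemotherapy from two-channel microarray data,
and for transferring it to qRT-PCR (ddCt) scale.

Stages:

1. **io_formats** — GenePix-style per-spot tables, clinical sample sheets,
   long-format Ct tables; validating readers/writers with round-trip
   guarantees.
2. **synthetic_data** — seeded cohort simulator (planted differential genes,
   intensity-dependent dye bias, flagged spots, concordant Ct tables) so
   every downstream stage is testable without any real data.
3. **preprocess** — spot filtering (flagged spots and control probes
   discarded, no background subtraction) and intra-array loess
   normalization (M on A, tricube-weighted local linear fit, span 0.5).
4. **diffexp** — group summaries, empirical-Bayes moderated t-test
   (log-variance moment matching to a scaled inverse-chi-square prior),
   Benjamini–Hochberg adjustment, signed fold-change convention.
5. **signature_filter** — the six-criterion composite gene filter
   (adjusted p < 0.025, |FC| > 1.3, mean intensity > 7, max |group mean| >
   0.4, min group SD < 0.5, separation score > −0.55; all strict).
6. **classify** — linear SVM on z-scored features, leave-one-out
   cross-validation with the entire gene selection re-run inside every fold
   (leakage-free), signature derivation by cross-fold selection frequency,
   covariate augmentation, and a Fisher-LDA clinical-covariate baseline.
7. **tlda_quant** — ddCt relative quantification (RQ = 2^−ddCt against a
   reference gene and calibrator sample) and cross-platform signature
   transfer (fixed gene panel, weights refitted on log2 RQ).
8. **evaluate** — confusion-matrix rates (non-responder = positive class),
   midrank ROC/AUC, SMACOF multidimensional scaling with Kruskal stress-1,
   Fisher exact / Freeman–Halton tests, Welch/pooled t and Mann–Whitney.
9. **cli** — `chemosig` orchestration with YAML config and JSON reports.

The package also bundles (in `chemosig.datasets`) the published cohort
covariate table, per-cohort classification counts and the signature panel,
used to reproduce the published derived statistics exactly.

## CLI

```sh
# end-to-end on a simulated cohort, fully seeded and reproducible
chemosig run --simulate --seed 7 --out out/

# individual stages
chemosig simulate  --config sim.yaml --seed 3 --out simdir/
chemosig preprocess --arrays simdir/arrays --sheet simdir/sheet.tsv --out expr.tsv
chemosig diffexp   --expr expr.tsv --sheet simdir/sheet.tsv --out de.tsv
chemosig select    --de de.tsv --out audit.tsv
chemosig train     --expr expr.tsv --sheet simdir/sheet.tsv --k 10 --out model.json
chemosig ddct      --ct simdir/ct.tsv --out rq.tsv
chemosig transfer  --model model.json --ct simdir/ct.tsv --sheet simdir/sheet.tsv --out pred.tsv
chemosig evaluate  --pred pred.tsv --truth simdir/sheet.tsv --out report.json
```

`chemosig run` writes a single `run_report.json` with the selected genes,
the signature model, LOOCV confusion metrics and AUC, MDS stress, and (for
simulated or provided Ct data) the qPCR transfer metrics.

## Layout

```
src/chemosig/        the nine pipeline modules + bundled data tables
tests/               pytest suite; test_acceptance.py holds the
                     acceptance criteria at their stated tolerances
scripts/acceptance.py  the acceptance report generator
```
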