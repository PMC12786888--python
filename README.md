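# erytex

Quantitative facial-erythema assessment: grey-level co-occurrence (GLCM)
texture scoring of masked facial regions, weighted whole-face aggregation,
clinician-grade (CEA) handling with inter-rater agreement, and the
nonparametric longitudinal statistics (Friedman + Dunn, Spearman) linking the
two — exercised end-to-end on a synthetic cross-polarized face-image
simulator, so no clinical image data is required.

## Layout

| module | purpose |
|---|---|
| `erytex.glcm` | 256-level co-occurrence matrices over ROI masks; contrast and homogeneity; brute-force test oracle |
| `erytex.pipeline` | image/mask loading, per-zone features, weighted whole-face scores (0.35/0.35/0.15/0.15), batch manifest processing |
| `erytex.stats` | mean CEA, complete-agreement fraction, treatment-energy summaries, percent change, Spearman with t(N−2), tie-corrected Friedman with Dunn/Bonferroni post hoc, whole-study analysis bundle |
| `erytex.simulate` | synthetic study generator: faces with clustered erythema lesions and telangiectasia fading across T0/T1/T2, fixed per-subject masks, noisy three-rater grades; deterministic under a seed |
| `erytex.cli` | `erytex` command: `simulate`, `extract`, `analyze`, `reproduce-arithmetic` |

GLCM conventions: asymmetric left→right tally at distance 1, direction 0°;
pairs straddling the mask boundary are dropped; features are computed on the
normalised probability grid; homogeneity uses the `1 + |i−j|` denominator.

## CLI

```bash
# synthetic study (images, masks, manifest.csv, cea.csv, truth.csv)
erytex simulate --seed 1 --out study/
erytex simulate --print-defaults          # flat key: value config schema

# per-zone + whole-face features for every manifest row
erytex extract --manifest study/manifest.csv --out features.csv

# medians, percent changes, Friedman/Dunn, agreement, Spearman vs mean CEA
erytex analyze --features features.csv --cea study/cea.csv --out report

# recompute every published-arithmetic check from packaged fixtures
erytex reproduce-arithmetic
```

`analyze` writes `report.json` (machine) and `report.md` (human) including the
run configuration and an N / R / t(N−2) / p correlation table.

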