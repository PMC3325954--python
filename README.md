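# senecon

Quantification toolkit for cellular-senescence phenotyping assays: directional
differential-expression signatures and their cross-comparison concordance,
image-cytometry DNA-content (ploidy) profiling with a re-replication bracket
scheme, γH2AX foci-distribution testing, comet-assay damage-recovery kinetics,
and small growth / qPCR / proportion quantifications — together with seeded
synthetic-data generators that plant recoverable ground truth for every stage.

## Modules

| module | what it does |
| --- | --- |
| `senecon.synthdata` | seeded generators: expression matrices with planted two-contrast DE signatures, per-nucleus ploidy mixtures with EdU/foci models, comet recovery time-courses, growth series, two-reference qPCR Ct tables |
| `senecon.expr_de` | per-contrast t-test DE on log2 matrices, cutoff signature selection (`\|lfc\| >= 0.5`, `p < 1e-4` defaults), signature unions, optional probe-to-gene collapse |
| `senecon.concordance` | direction-partitioned overlap of two signatures, 2×2 contingency chi-squared (df = 1, no continuity correction), marginal-conditioned permutation p-value, three-way Venn regions |
| `senecon.cytoprofile` | DNA-content histogram with 2N/4N peak detection, six-class ploidy classification incl. the two >4N brackets, EdU-in-bracket2 fraction with Wilson CI, mixture-model fraction recovery, foci binning {0, 1–5, 6–10, >10} and goodness-of-fit test |
| `senecon.damage_kinetics` | five-number tail-percent summaries, t/rank-sum group comparisons, bounded exponential-recovery fit `D(t) = D_inf + (D0 − D_inf)·exp(−k·t)` |
| `senecon.quantify` | cumulative serial-passage growth, two-reference delta-Ct relative expression, replicate proportion summaries with t-tests |
| `senecon.cli` | `senecon` command line and YAML-config pipeline orchestration |

## Command line

```sh
# generate synthetic inputs (any of: expr | nuclei | comet | growth | qpcr)
senecon simulate expr --seed 1 --out sim/

# differential expression and signature selection
senecon de --matrix sim/matrix.tsv --design sim/design.csv \
    --contrast c1:base --lfc 0.5 --p 1e-4 --out de/

# directional concordance of two signatures (+ permutation p-value)
senecon concord --a de/sig_c1-base.csv --b de/sig_c2-base.csv \
    --perm 10000 --seed 1 --out concordance.json
senecon venn --a s1.csv --b s2.csv --c s3.csv --out venn.csv

# cytometry / comet / small quantifications
senecon cyto profile|classify|fractions|foci --in nuclei.csv --out ...
senecon comet summary|compare|fit --in comet.csv --out ...
senecon growth --in growth.csv --out g.csv
senecon qpcr --in qpcr.csv --control-group ctrl --out q.csv
senecon proportions --in props.csv --out p.json

# config-driven pipeline (simulate -> de -> concord), deterministic per seed
senecon run --config pipeline.yaml --seed 1 --out results/
```

## Conventions worth knowing

- Signature selection is inclusive on the fold-change cutoff and strict on
  the p-value cutoff; no multiple-testing correction is applied by design.
- The concordance chi-squared is computed only over the overlap (probes
  significant in both signatures); set-exclusive counts are reported but not
  tested. Expected cells < 5 set a flag recommending the permutation p-value.
- Ploidy classes use symmetric ±15 % tolerance bands around the detected 2N
  and 4N modes; the >4N region is halved into bracket1/bracket2 with the
  split point belonging to bracket1. Band classification is intentionally
  simple and biased for overlapping classes — `deconvolved_fractions` fits
  the parametric intensity mixture when unbiased fraction recovery is needed.
- Box-plot percentiles use linear interpolation between order statistics.
- The exponential recovery fit is a modeling extension beyond per-timepoint
  testing and is labeled as such in its JSON report.
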