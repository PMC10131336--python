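# toplinegs

Top-line selection in genomic prediction. The package implements three ways
of classifying breeding lines as "top" (trait value at or above a threshold
`Y_tau`) from genome-wide marker data, and a nested cross-validation harness
that compares them:

* **Model R** — the conventional GBLUP regression (`Y_i = mu + g_i + eps_i`,
  `g ~ N(0, sigma_g^2 G)` with the VanRaden genomic relationship matrix `G`),
  classifying lines whose predicted value exceeds `Y_tau`. Because predictions
  shrink toward the mean and top lines are a minority, this rule has very high
  specificity and very low sensitivity.
* **Model B** — a Bayesian probit threshold classifier
  (`P(Y_bi = 1 | g_i) = Phi(beta0 + g_i)`, latent liabilities with unit
  residual variance, truncated-normal Gibbs sampling) trained on labels
  binarized at `Y_tau`, with the probability cutoff `tau0` tuned on inner CV
  folds to minimize the squared sensitivity–specificity gap.
* **Model RO** — a postprocessing step on model R's continuous predictions:
  the same inner-CV tuning yields an optimal continuous cutoff `Y_tau0`
  (equivalently, predictions rescaled by `Y_tau / Y_tau0` and compared to
  `Y_tau`), recovering sensitivity without refitting anything beyond GBLUP.

Modules:

| module | contents |
|---|---|
| `toplinegs.io_kinship` | genotype/phenotype readers (CSV/TSV, VCF), marker QC (MAF / missingness / heterozygosity), mean imputation, VanRaden GRM |
| `toplinegs.models` | GBLUP (Gibbs sampler or deterministic REML+BLUP) and probit TGBLUP (Gibbs with data augmentation) |
| `toplinegs.thresholding` | threshold specs (quantile / check-based / fixed), binarization, cutoff optimization and aggregation, prediction rescaling |
| `toplinegs.evaluation` | confusion counts, kappa / sensitivity / specificity / precision / F1, relative efficiency, fold summaries |
| `toplinegs.cv_pipeline` | outer-k / inner-k nested CV orchestration for models R, B, RO; deterministic, leakage-audited outputs |
| `toplinegs.synthetic_data` | genotype/phenotype simulator with known ground truth (benchmark bundles) |

## CLI

Simulate a benchmark dataset, run the three-model comparison, and print the
summary:

```sh
toplinegs simulate --n-lines 500 --n-markers 1000 --h2 0.5 --seed 1 --out bench/
toplinegs run --genotypes bench/genotypes.csv --phenotypes bench/phenotypes.csv \
    --models R,B,RO --tau 0.8 --outer-k 5 --inner-k 10 --seed 1 --out results/
toplinegs compare results/
```

`run` writes `predictions.csv` (line, fold, model, score, label),
`metrics.csv` (per-fold confusion counts and metrics), `summary.csv`
(fold means, SE, t-interval bounds, pairwise relative efficiencies) and
`provenance.json` (config hash, fold memberships, tuned cutoffs). Outputs
are byte-identical across reruns with the same config and seed.

Genotypes can also be read from uncompressed VCF (`--format vcf`; biallelic
SNPs only), and check-based thresholds are available via
`--threshold-kind check_mean --checks CHK01,CHK02`.

By default GBLUP is fit by fast deterministic REML + BLUP
(`--gblup-mode blup_deterministic`); `--gblup-mode gibbs` switches to the
Bayesian sampler. The probit classifier is always sampled (`--n-iter`,
`--burn-in`, `--thin` control the chain).

## Notes

* Markers are QC-filtered with MAF >= 0.05, missing fraction < 0.5 and
  heterozygosity < 0.05 by default; missing dosages are then mean-imputed
  (pre-impute externally if you prefer LD-aware imputation).
* Observed labels use `y >= Y_tau`; predicted labels use strict
  `score > cutoff`. Both boundaries are configurable.
* Undefined metrics (e.g. F1 when no positives are predicted) propagate as
  NA and are excluded from fold means, with NA counts reported.
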