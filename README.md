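# growthtraj

Longitudinal growth-trait analysis for clonal tree field trials.

Forest-tree breeders measure height and diameter at breast height (DBH) on
the same clones year after year, and want to know (a) which growth law best
describes the multi-year trajectory, (b) whether candidate SNPs shift the
*whole trajectory* rather than the trait at a single age, and (c) when a
stand passes from rapid to reduced growth — the quantity that informs
rotation age. `growthtraj` packages that workflow: nonlinear growth-curve
fitting, metric-based model selection, a likelihood-ratio trajectory
association test, per-year single-time association, and curvature-based
ontogenetic staging, together with a seeded generator of realistic synthetic
trial data.

## The models and the statistic

Four three-parameter saturating growth laws are supported
(`a`/`Asym` = plateau in trait units, the rest control rate and timing):

| model | y(t) |
|---|---|
| Gompertz | `a exp(−b c^t)`, `0 < c < 1` |
| Chapman–Richards ("Richard") | `a (1 − e^{−bt})^c` |
| logistic | `Asym / (1 + exp((xmid − t)/scal))` |
| asymptotic regression | `a + (b − a) exp(−e^c t)` |

Each clone × trait series is fitted by nonlinear least squares; fits are
ranked across clones by AIC, BIC, R², RMSE and MAE with paired t-tests and
Holm correction.

Genotype effects on trajectories are tested by comparing nested Gaussian
curve models for each SNP:

```
LR = −2 (log L0 − log L1) ~ χ²(df),   df = 3 (G − 1)
```

where `L0` is one curve fitted to all carriers pooled and `L1` lets each of
the `G` genotype classes have its own curve (one shared residual variance by
default, so `df` counts exactly the extra curve parameters). Classes with
indistinguishable fitted trajectories can be merged before testing.

Ontogeny is staged at the point of maximum curvature
`κ(t) = |y''| / (1 + y'²)^{3/2}` on the decelerating limb of the fitted
curve: ages up to `t_mc` are the rapid-growth phase, later ages the
reduced-growth phase.

## Worked example

```python
from growthtraj import (
    make_fixture_suite, build_classes, minor_allele_freq,
    lr_trajectory_test, phase_report,
)

bundle = make_fixture_suite(seed=7)["effect-20pct-24"]
geno, pheno = bundle["genotypes"], bundle["phenotypes"]

classing = build_classes(geno, "SNP1")
print(round(minor_allele_freq(geno, "SNP1"), 3))   # 0.354
print([(lab, len(m)) for lab, m in classing.classes])
# [('A/A', 10), ('A/G', 11), ('G/G', 3)]

res = lr_trajectory_test(pheno, classing, "richard", "height_m", seed=7)
print(f"LR = {res.lr:.2f}, df = {res.df}, p = {res.p:.3g}")
# LR = 1014.95, df = 6, p = 5.23e-216

print(phase_report(res.class_fits, obs_span=11.0)
      [["class", "t_mc", "t_max_growth", "asymptote"]].round(3))
# class    t_mc  t_max_growth  asymptote
#   A/A  13.658         2.608     28.190
#   A/G  14.171         2.641     33.051
#   G/G  15.820         2.578     40.858
```

The fixture carries one SNP whose alternate allele raises the height plateau
by 20% per copy. The LR test finds an overwhelming trajectory difference
between the three genotype classes (`df = 3·(3−1) = 6`), and the staging
table shows the classic pattern: classes with larger fitted plateaus enter
the reduced-growth phase later (`t_mc` 13.7 → 15.8 years) while the time of
maximum growth rate (~2.6 years) barely moves.

The same analysis is scriptable from the shell:

```
growthtraj simulate --seed 7 --outdir trial
growthtraj all --phenotypes trial/phenotypes.csv --genotypes trial/genotypes.csv --outdir results
```

which writes tidy CSV reports (descriptives, fits, model selection, per-SNP
QTL table, phase report) plus a `manifest.json` recording config, seed and
stage status.

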