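"""SNP-genotype effects on whole growth trajectories.

The central statistic is a likelihood-ratio comparison of two nested
Gaussian curve models for the clones carrying a SNP:

* H0 (pooled): one growth curve fits all clones' observations;
* H1 (class-wise): each genotype class gets its own curve.

    LR = -2 (logL0 - logL1),   LR ~ chi-square(df) under H0,

with df the number of extra free parameters of H1. With the default
``sigma_mode="pooled"`` (one residual variance shared by all classes) the
extra parameters are exactly the extra curve parameters, df = 3 (G - 1) for
G genotype classes. ``sigma_mode="per_class"`` lets every class estimate its
own sigma^2; set ``count_sigma_df=True`` with it so df also counts the extra
variance parameters (df = 4 (G - 1)) and the chi-square reference remains
calibrated.

The module also provides the surrounding genetic layer: minor-allele
frequency, genotype-class construction with a minimum class size, merging of
classes whose fitted trajectories are indistinguishable, per-year single-time
association (one-way fixed-effects GLM), a one-way MANOVA on fitted curve
parameters, and a Pearson chi-square test of genotype counts against a
Mendelian ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .fitting import FitResult, TraitSeries, fit_pooled, gaussian_loglik
from .growth_models import GrowthModel, MODEL_SPECS, asymptote

__all__ = [
    "GenotypeMatrix",
    "GenotypeClassing",
    "LRTestResult",
    "ManovaResult",
    "MISSING_CALL",
    "minor_allele_freq",
    "build_classes",
    "merge_similar_classes",
    "lr_trajectory_test",
    "per_year_glm",
    "param_multitrait_association",
    "genotype_count_test",
]

MISSING_CALL = "./."


def _normalize_call(call: object) -> str | None:
    """Canonicalize a diploid call: unordered alleles, 'A/G' == 'G/A'."""
    if call is None or (isinstance(call, float) and math.isnan(call)):
        return None
    s = str(call).strip()
    if s in ("", MISSING_CALL, "NA", "nan"):
        return None
    alleles = s.replace("|", "/").split("/")
    if len(alleles) != 2 or not all(alleles):
        raise ValueError(f"malformed diploid call {call!r}")
    return "/".join(sorted(alleles))


@dataclass
class GenotypeMatrix:
    """Diploid SNP calls for a panel of clones.

    ``calls`` is a clones x SNPs frame of strings like ``"A/G"`` (heterozygote
    order is canonicalized) with ``None`` for missing. ``alleles`` maps each
    SNP to its (ref, alt) pair; when not supplied it is inferred from the
    observed calls (ref = more frequent allele).
    """

    calls: pd.DataFrame
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.calls = self.calls.map(_normalize_call)
        for snp in self.calls.columns:
            observed = self._allele_counts(snp)
            declared = self.alleles.get(snp)
            if declared is None:
                ranked = sorted(observed, key=lambda a: (-observed[a], a))
                if len(ranked) == 1:
                    ranked.append(ranked[0])
                self.alleles[snp] = (ranked[0], ranked[1])
            else:
                extra = set(observed) - set(declared)
                if extra:
                    raise ValueError(
                        f"{snp}: calls use undeclared allele(s) {sorted(extra)}"
                    )

    @property
    def clone_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)

    def _allele_counts(self, snp_id: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        for call in self.calls[snp_id].dropna():
            for allele in call.split("/"):
                counts[allele] = counts.get(allele, 0) + 1
        if not counts:
            raise ValueError(f"{snp_id}: all calls missing")
        return counts

    def missing_fraction(self, snp_id: str) -> float:
        return float(self.calls[snp_id].isna().mean())


@dataclass
class GenotypeClassing:
    """Partition of the non-missing clones of one SNP into genotype classes."""

    snp_id: str
    classes: list[tuple[str, list[str]]]  # (genotype label, member clone ids)
    excluded: list[tuple[str, list[str]]] = field(default_factory=list)
    merged_from: list[list[str]] | None = None

    @property
    def testable(self) -> bool:
        return len(self.classes) >= 2

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.classes]

    def members(self, label: str) -> list[str]:
        return dict(self.classes)[label]

    def class_of(self) -> dict[str, str]:
        return {cid: lab for lab, members in self.classes for cid in members}


@dataclass
class LRTestResult:
    """Likelihood-ratio trajectory test of one SNP on one trait."""

    snp_id: str
    trait: str
    model: GrowthModel
    logL0: float
    logL1: float
    lr: float
    df: int
    p: float | None
    class_fits: dict[str, FitResult]
    pooled_fit: FitResult
    converged: bool
    sigma_mode: str


def minor_allele_freq(matrix: GenotypeMatrix, snp_id: str) -> float:
    """Frequency of the rarer allele among all non-missing allele calls."""
    counts = matrix._allele_counts(snp_id)
    total = sum(counts.values())
    if len(counts) == 1:
        return 0.0
    return min(counts.values()) / total


def build_classes(
    matrix: GenotypeMatrix, snp_id: str, min_class_size: int = 3
) -> GenotypeClassing:
    """Group clones by diploid genotype at one SNP.

    Classes with fewer than ``min_class_size`` members are excluded from
    testing (recorded in ``excluded``). A classing with < 2 usable classes is
    returned with ``testable == False`` -- the monomorphic-SNP case.
    """
    groups: dict[str, list[str]] = {}
    for clone, call in matrix.calls[snp_id].items():
        if call is not None:
            groups.setdefault(call, []).append(clone)
    usable = [(lab, m) for lab, m in sorted(groups.items()) if len(m) >= min_class_size]
    excluded = [(lab, m) for lab, m in sorted(groups.items()) if len(m) < min_class_size]
    return GenotypeClassing(snp_id=snp_id, classes=usable, excluded=excluded)


# --------------------------------------------------------------------------
# trajectory tests
# --------------------------------------------------------------------------


def _series_by_clone(
    phenotypes: pd.DataFrame, trait: str, clone_ids: Sequence[str]
) -> list[TraitSeries]:
    sub = phenotypes[(phenotypes["trait"] == trait) & phenotypes["clone"].isin(clone_ids)]
    out = []
    for clone, grp in sub.groupby("clone", sort=True):
        grp = grp.sort_values("age")
        out.append(TraitSeries(str(clone), trait, grp["age"].values, grp["value"].values))
    return out


def lr_trajectory_test(
    phenotypes: pd.DataFrame,
    classing: GenotypeClassing,
    model: GrowthModel | str,
    trait: str,
    seed: int = 0,
    sigma_mode: str = "pooled",
    count_sigma_df: bool = False,
) -> LRTestResult:
    """Likelihood-ratio test of genotype effects on the whole trajectory.

    L0 is the Gaussian log-likelihood of one curve fitted to all member
    clones' observations pooled; L1 is the class-wise alternative. With
    ``sigma_mode="pooled"`` both hypotheses share a single residual variance
    (sigma^2 = total SSE / total n) and df counts curve parameters only,
    df = 3 (G - 1). With ``sigma_mode="per_class"`` every class concentrates
    its own sigma^2; combine with ``count_sigma_df=True`` to also count the
    G - 1 extra variance parameters in df.
    """
    if not classing.testable:
        raise ValueError(f"{classing.snp_id}: fewer than 2 usable genotype classes")
    if sigma_mode not in ("pooled", "per_class"):
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    model = GrowthModel(model)

    all_members = [cid for _, members in classing.classes for cid in members]
    pooled_series = _series_by_clone(phenotypes, trait, all_members)
    pooled_fit = fit_pooled(pooled_series, model, seed=seed)

    class_fits: dict[str, FitResult] = {}
    for i, (label, members) in enumerate(classing.classes):
        class_fits[label] = fit_pooled(
            _series_by_clone(phenotypes, trait, members), model, seed=seed + i + 1
        )

    n_total = pooled_fit.n
    k = MODEL_SPECS[model].n_params
    n_classes = len(classing.classes)
    logL0 = gaussian_loglik(pooled_fit.sse, n_total)
    if sigma_mode == "pooled":
        sse1 = sum(f.sse for f in class_fits.values())
        logL1 = gaussian_loglik(sse1, n_total)
    else:
        logL1 = sum(f.loglik for f in class_fits.values())
    lr = -2.0 * (logL0 - logL1)
    df = k * (n_classes - 1)
    if count_sigma_df and sigma_mode == "per_class":
        df += n_classes - 1
    converged = pooled_fit.converged and all(f.converged for f in class_fits.values())
    p = float(stats.chi2.sf(max(lr, 0.0), df)) if converged else None
    return LRTestResult(
        snp_id=classing.snp_id,
        trait=trait,
        model=model,
        logL0=logL0,
        logL1=logL1,
        lr=lr,
        df=df,
        p=p,
        class_fits=class_fits,
        pooled_fit=pooled_fit,
        converged=converged,
        sigma_mode=sigma_mode,
    )


def trajectory_distance(
    fit_a: FitResult, fit_b: FitResult, t_lo: float, t_hi: float, n_grid: int = 200
) -> float:
    """Normalized L2 distance between two fitted trajectories.

    Mean squared difference of the predicted curves over [t_lo, t_hi],
    divided by the squared pooled (mean) asymptote -- a unit-free measure of
    how far apart two genotype classes grow.
    """
    grid = np.linspace(t_lo, t_hi, n_grid)
    fa = np.asarray(fit_a.predict(grid), float)
    fb = np.asarray(fit_b.predict(grid), float)
    pooled_asym = 0.5 * (
        asymptote(fit_a.model, fit_a.params) + asymptote(fit_b.model, fit_b.params)
    )
    return float(np.mean((fa - fb) ** 2) / pooled_asym**2)


def merge_similar_classes(
    phenotypes: pd.DataFrame,
    classing: GenotypeClassing,
    model: GrowthModel | str,
    trait: str,
    threshold: float,
    seed: int = 0,
) -> GenotypeClassing:
    """Greedily merge genotype classes with indistinguishable trajectories.

    Repeatedly merges the pair of classes whose fitted curves have the
    smallest normalized L2 distance, as long as that distance is strictly
    below ``threshold`` (so ``threshold = 0`` never merges); classes are
    refitted after each merge. The pre-merge class labels are recorded in
    ``merged_from``.
    """
    model = GrowthModel(model)
    classes = list(classing.classes)
    history: list[list[str]] = []
    sub = phenotypes[phenotypes["trait"] == trait]
    t_lo, t_hi = float(sub["age"].min()), float(sub["age"].max())

    while len(classes) >= 2:
        fits = {
            lab: fit_pooled(_series_by_clone(phenotypes, trait, members), model, seed=seed)
            for lab, members in classes
        }
        best_pair, best_dist = None, math.inf
        for (la, _), (lb, _) in combinations(classes, 2):
            d = trajectory_distance(fits[la], fits[lb], t_lo, t_hi)
            if d < best_dist:
                best_pair, best_dist = (la, lb), d
        if best_pair is None or not (best_dist < threshold):
            break
        la, lb = best_pair
        merged_label = f"{la}+{lb}"
        merged_members = dict(classes)[la] + dict(classes)[lb]
        history.append([la, lb])
        classes = [(lab, m) for lab, m in classes if lab not in (la, lb)]
        classes.append((merged_label, merged_members))
        classes.sort()

    return GenotypeClassing(
        snp_id=classing.snp_id,
        classes=classes,
        excluded=classing.excluded,
        merged_from=history or None,
    )


# --------------------------------------------------------------------------
# single-time and parameter-vector association
# --------------------------------------------------------------------------


def per_year_glm(
    values: Mapping[str, float] | pd.Series, classing: GenotypeClassing
) -> tuple[float, float]:
    """Single-time association: one-way fixed-effects GLM F-test.

    ``values`` maps clone id -> trait value at one age. Genotype class enters
    as a categorical factor with no further covariates; the overall F-test is
    the classical one-way ANOVA.
    """
    class_of = classing.class_of()
    rows = [
        {"value": float(v), "genotype": class_of[c]}
        for c, v in dict(values).items()
        if c in class_of and v is not None and not (isinstance(v, float) and math.isnan(v))
    ]
    df = pd.DataFrame(rows)
    sizes = df.groupby("genotype").size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 classes with >= 2 members each at this age")
    if len(df) - len(sizes) <= 0:
        raise ValueError("zero residual degrees of freedom")
    fit = smf.ols("value ~ C(genotype)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    f = float(anova.loc["C(genotype)", "F"])
    p = float(anova.loc["C(genotype)", "PR(>F)"])
    return f, p


@dataclass
class ManovaResult:
    """One-way MANOVA of fitted curve-parameter vectors across classes."""

    wilks_lambda: float
    f_stat: float
    df1: float
    df2: float
    p: float  # Rao's F transformation (exact for 1-d or 2 groups)
    p_bartlett: float  # Bartlett chi-square approximation
    n: int
    n_groups: int
    n_dims: int


def param_multitrait_association(
    params: pd.DataFrame, classing: GenotypeClassing
) -> ManovaResult:
    """Test genotype effects on the fitted curve-parameter vectors jointly.

    One-way MANOVA with Wilks' Lambda = det(W) / det(W + B) on the per-clone
    parameter vectors (rows of ``params`` indexed by clone id). The primary
    p-value uses Rao's F transformation, which is exact when the parameter
    dimension is 1 or there are 2 groups and reduces to the one-way ANOVA
    F-test in one dimension; Bartlett's chi-square approximation is also
    reported.
    """
    class_of = classing.class_of()
    X = params.loc[[c for c in params.index if c in class_of]].astype(float)
    groups = np.array([class_of[c] for c in X.index])
    labels = np.unique(groups)
    n, p = X.shape
    g = len(labels)
    if g < 2:
        raise ValueError("need >= 2 genotype classes")
    if n < g + p + 2:
        raise ValueError(f"too few clones (n={n}) for {g} classes in {p} dims")

    grand = X.values.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for lab in labels:
        sub = X.values[groups == lab]
        mu = sub.mean(axis=0)
        centered = sub - mu
        W += centered.T @ centered
        d = (mu - grand).reshape(-1, 1)
        B += len(sub) * (d @ d.T)
    detW = np.linalg.det(W)
    detT = np.linalg.det(W + B)
    if detW <= 0 or detT <= 0:
        raise np.linalg.LinAlgError(
            "singular within-class covariance; consider standardizing parameters"
        )
    lam = detW / detT

    # Rao's F approximation of Wilks' Lambda
    m = n - 1 - (p + g) / 2.0
    denom = p**2 + (g - 1) ** 2 - 5
    s = math.sqrt((p**2 * (g - 1) ** 2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * (g - 1)
    df2 = m * s - df1 / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f_stat = (1.0 - lam_s) / lam_s * df2 / df1
    p_rao = float(stats.f.sf(f_stat, df1, df2)) if lam < 1.0 else 1.0
    chi2_stat = -m * math.log(lam)
    p_bartlett = float(stats.chi2.sf(chi2_stat, df1)) if lam < 1.0 else 1.0
    return ManovaResult(
        wilks_lambda=float(lam),
        f_stat=float(f_stat),
        df1=float(df1),
        df2=float(df2),
        p=p_rao,
        p_bartlett=p_bartlett,
        n=n,
        n_groups=g,
        n_dims=p,
    )


def genotype_count_test(
    classing: GenotypeClassing, expected_ratio: Sequence[float] | None = None
) -> tuple[float, float]:
    """Pearson chi-square of genotype-class counts against a Mendelian ratio.

    Default expected ratio is 1:2:1 for three classes and 1:1 for two; any
    ratio of matching length can be supplied. Classes are taken in label
    order (homozygote, heterozygote, homozygote for standard biallelic data).
    """
    counts = np.array([len(m) for _, m in classing.classes], dtype=float)
    if len(counts) < 2:
        raise ValueError("need >= 2 genotype classes")
    if expected_ratio is None:
        expected_ratio = (1.0, 2.0, 1.0) if len(counts) == 3 else (1.0,) * len(counts)
    ratio = np.asarray(expected_ratio, dtype=float)
    if len(ratio) != len(counts):
        raise ValueError("expected_ratio length must match number of classes")
    expected = counts.sum() * ratio / ratio.sum()
    if np.any(expected == 0):
        raise ValueError("expected count of zero in some class")
    stat, p = stats.chisquare(counts, f_exp=expected)
    return float(stat), float(p)
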