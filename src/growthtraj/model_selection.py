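"""Cross-clone comparison of the four growth laws for one trait.

Every clone is fitted with all four laws; each of the five goodness-of-fit
metrics is then compared between every pair of laws with a paired two-sided
t-test across clones (the clone is the natural pairing unit), Holm-adjusted
within metric. The winning law is the one with the best mean AIC among laws
that are never significantly worse than any other law on AIC; ties break by
mean BIC, then mean RMSE, then a fixed law order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .growth_models import GrowthModel

__all__ = ["ModelComparison", "compare_models", "METRICS", "LOWER_IS_BETTER"]

METRICS = ("aic", "bic", "r2", "rmse", "mae")
LOWER_IS_BETTER = {"aic": True, "bic": True, "r2": False, "rmse": True, "mae": True}

#: fixed tie-break order of the growth laws
MODEL_ORDER = tuple(GrowthModel)


@dataclass
class ModelComparison:
    """Result of comparing the four growth laws across clones for one trait."""

    trait: str
    metric_table: pd.DataFrame  # columns: clone, model, aic, bic, r2, rmse, mae
    pairwise: pd.DataFrame  # model_a, model_b, metric, statistic, p, p_adj, flag
    winner: GrowthModel
    decision_trace: list[str] = field(default_factory=list)


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Paired two-sided t-test with the constant-difference convention.

    A zero-variance, nonzero-mean difference vector is infinitely strong
    evidence under the paired-t model; report statistic +/-inf and p = 0
    with a flag instead of crashing. All-zero differences give p = 1.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 1.0, "identical"
        return float(np.sign(d.mean()) * np.inf), 0.0, "constant_difference"
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), ""


def compare_models(metric_table: pd.DataFrame, trait: str, alpha: float = 0.05) -> ModelComparison:
    """Select the best growth law for one trait from per-clone fit metrics.

    Parameters
    ----------
    metric_table
        Tidy frame with columns ``clone, model`` and the five metric columns
        (``aic, bic, r2, rmse, mae``), one row per clone x model. Clones
        missing any of the four models are dropped with a note in the
        decision trace.
    trait
        Label carried through to the report.
    alpha
        Significance level applied to Holm-adjusted p-values.
    """
    df = metric_table.copy()
    df["model"] = df["model"].map(lambda m: GrowthModel(m).value)
    trace: list[str] = []

    counts = df.groupby("clone")["model"].nunique()
    complete = counts[counts == len(MODEL_ORDER)].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        trace.append(f"dropped clones missing some model fits: {dropped}")
    df = df[df["clone"].isin(complete)]
    n_clones = df["clone"].nunique()
    if n_clones < 3:
        raise ValueError(f"need >= 3 clones with complete fits, have {n_clones}")

    wide = {
        metric: df.pivot(index="clone", columns="model", values=metric)
        for metric in METRICS
    }

    rows = []
    pairs = list(combinations([m.value for m in MODEL_ORDER], 2))
    for metric in METRICS:
        raw = []
        for ma, mb in pairs:
            t, p, flag = _paired_t(wide[metric][ma].values, wide[metric][mb].values)
            raw.append((ma, mb, metric, t, p, flag))
        p_adj = multipletests([r[4] for r in raw], method="holm")[1]
        for (ma, mb, metric_, t, p, flag), padj in zip(raw, p_adj):
            rows.append(
                dict(model_a=ma, model_b=mb, metric=metric_, statistic=t,
                     p=p, p_adj=float(padj), flag=flag)
            )
    pairwise = pd.DataFrame(rows)

    mean_aic = wide["aic"].mean()
    # a model is dominated if some other model is significantly better on AIC
    dominated: set[str] = set()
    aic_tests = pairwise[pairwise["metric"] == "aic"]
    for _, r in aic_tests.iterrows():
        if r["p_adj"] < alpha:
            worse = r["model_a"] if mean_aic[r["model_a"]] > mean_aic[r["model_b"]] else r["model_b"]
            dominated.add(worse)
            trace.append(
                f"AIC: {worse} significantly worse in pair ({r['model_a']}, "
                f"{r['model_b']}), adj p = {r['p_adj']:.3g}"
            )
    candidates = [m.value for m in MODEL_ORDER if m.value not in dominated]
    if not candidates:  # mutual domination is impossible, but guard anyway
        candidates = [m.value for m in MODEL_ORDER]
        trace.append("all models dominated on AIC (degenerate); full set restored")
    trace.append(f"non-dominated on AIC: {candidates}")

    mean_bic = wide["bic"].mean()
    mean_rmse = wide["rmse"].mean()
    enum_rank = {m.value: i for i, m in enumerate(MODEL_ORDER)}
    winner = min(
        candidates,
        key=lambda m: (
            round(float(mean_aic[m]), 12),
            round(float(mean_bic[m]), 12),
            round(float(mean_rmse[m]), 12),
            enum_rank[m],
        ),
    )
    trace.append(
        f"winner {winner}: mean AIC {mean_aic[winner]:.4f} "
        f"(tie-breaks: BIC {mean_bic[winner]:.4f}, RMSE {mean_rmse[winner]:.4f})"
    )
    return ModelComparison(
        trait=trait,
        metric_table=df.reset_index(drop=True),
        pairwise=pairwise,
        winner=GrowthModel(winner),
        decision_trace=trace,
    )
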