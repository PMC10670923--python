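"""Orchestration, I/O, descriptive statistics and reporting.

The pipeline runs the full analysis in the natural order: descriptive
statistics -> per-clone growth-law fits -> cross-clone model selection ->
per-SNP likelihood-ratio trajectory tests (with optional class merging) ->
per-year single-time association -> MANOVA on fitted curve parameters ->
curvature-based staging. All stage outputs are tidy CSV files plus a
machine-readable JSON manifest (config hash, seed, package versions, stage
status); a rerun with the same inputs and seed reproduces the manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .fitting import TraitSeries, compute_metrics, fit_growth_curve
from .growth_models import GrowthModel
from .model_selection import compare_models
from .ontogeny import phase_report
from .synthetic_data import SimulationConfig
from .trajectory_qtl import (
    GenotypeMatrix,
    MISSING_CALL,
    build_classes,
    lr_trajectory_test,
    merge_similar_classes,
    minor_allele_freq,
    param_multitrait_association,
    per_year_glm,
)

logger = logging.getLogger("growthtraj")

__all__ = [
    "PhenotypeSchemaError",
    "RunConfig",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes_csv",
    "read_genotypes_vcf",
    "fit_all_models",
    "descriptives",
    "run_pipeline",
]

PHENOTYPE_COLUMNS = ("clone", "trait", "age", "value")


class PhenotypeSchemaError(ValueError):
    """The phenotype CSV violates the long-format schema."""


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format phenotype CSV.

    Required header: ``clone,trait,age,value`` (extra columns such as
    ``ramet`` are kept). Schema violations are reported with row numbers;
    duplicate (clone, trait, age[, ramet]) records are an error. Gaps in the
    measurement schedule are data, not schema errors.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise PhenotypeSchemaError(f"{path}: empty file") from None
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeSchemaError(f"{path}: missing column(s) {missing}")
    problems = []
    age = pd.to_numeric(df["age"], errors="coerce")
    value = pd.to_numeric(df["value"], errors="coerce")
    for idx in df.index[age.isna()]:
        problems.append(f"row {idx + 2}: non-numeric age {df.loc[idx, 'age']!r}")
    for idx in df.index[value.isna()]:
        problems.append(f"row {idx + 2}: non-numeric value {df.loc[idx, 'value']!r}")
    for idx in df.index[(value <= 0) & value.notna()]:
        problems.append(f"row {idx + 2}: non-positive value {df.loc[idx, 'value']!r}")
    key = ["clone", "trait", "age"] + (["ramet"] if "ramet" in df.columns else [])
    dup = df.duplicated(subset=key)
    for idx in df.index[dup]:
        problems.append(f"row {idx + 2}: duplicate record for {tuple(df.loc[idx, key])}")
    if problems:
        raise PhenotypeSchemaError(f"{path}: " + "; ".join(problems))
    df = df.assign(age=age, value=value, clone=df["clone"].astype(str))
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_genotypes_csv(path: str | Path) -> GenotypeMatrix:
    """Read a clones x SNPs genotype matrix CSV (calls 'A/G', missing './.')."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return GenotypeMatrix(calls=df.replace(MISSING_CALL, None))


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a minimal VCF: only the GT field is consumed, 0/1 mapped via REF/ALT."""
    import pysam

    calls: dict[str, dict[str, str | None]] = {}
    alleles: dict[str, tuple[str, str]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            ref = rec.ref
            alt = rec.alts[0] if rec.alts else ref
            alleles[snp_id] = (ref, alt)
            col: dict[str, str | None] = {}
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(g is None for g in gt):
                    col[sample] = None
                else:
                    col[sample] = "/".join(sorted(rec.alleles[g] for g in gt))
            calls[snp_id] = col
    frame = pd.DataFrame(calls).loc[samples]
    frame.index = frame.index.astype(str)
    return GenotypeMatrix(calls=frame, alleles=alleles)


# --------------------------------------------------------------------------
# descriptives
# --------------------------------------------------------------------------


def descriptives(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-year summaries, clone ANOVA and year-vs-final correlations.

    Returns three frames per the classical field-trial descriptive workflow:

    * ``summary``: per trait x year mean/min/max/sd and n;
    * ``anova``: one-way ANOVA across clones per trait x year (requires
      ramet-level replication; skipped with a warning otherwise);
    * ``correlation``: Pearson r (and p) of each year's clone means against
      the final-year clone means.
    """
    if table["clone"].nunique() < 2 or table["age"].nunique() < 2:
        raise ValueError("need >= 2 clones and >= 2 measurement years")

    summary = (
        table.groupby(["trait", "age"])["value"]
        .agg(["mean", "min", "max", "std", "count"])
        .reset_index()
    )

    anova_rows = []
    has_ramets = "ramet" in table.columns
    for (trait, age), grp in table.groupby(["trait", "age"]):
        groups = [g["value"].values for _, g in grp.groupby("clone")]
        if not has_ramets or min(len(g) for g in groups) < 2:
            logger.warning(
                "descriptives: single observation per clone at %s age %s; "
                "clone ANOVA skipped", trait, age,
            )
            continue
        f, p = stats.f_oneway(*groups)
        anova_rows.append(dict(trait=trait, age=age, F=float(f), p=float(p)))
    anova = pd.DataFrame(anova_rows, columns=["trait", "age", "F", "p"])

    corr_rows = []
    clone_means = table.groupby(["trait", "age", "clone"])["value"].mean().reset_index()
    for trait, grp in clone_means.groupby("trait"):
        wide = grp.pivot(index="clone", columns="age", values="value")
        final = wide.columns.max()
        for age in wide.columns:
            mask = wide[age].notna() & wide[final].notna()
            x, y = wide.loc[mask, age], wide.loc[mask, final]
            if x.std() == 0 or y.std() == 0:
                # no clone variation: correlation undefined, except the
                # final year against itself which is identically 1
                r, p = (1.0, 0.0) if age == final else (float("nan"), float("nan"))
            else:
                r, p = stats.pearsonr(x, y)
            corr_rows.append(
                dict(trait=trait, age=age, final_age=final, r=float(r), p=float(p))
            )
    correlation = pd.DataFrame(corr_rows)
    return {"summary": summary, "anova": anova, "correlation": correlation}


# --------------------------------------------------------------------------
# fitting across clones
# --------------------------------------------------------------------------


def fit_all_models(
    table: pd.DataFrame,
    trait: str,
    models: tuple[GrowthModel, ...] = tuple(GrowthModel),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, GrowthModel], object]]:
    """Fit every clone's series with every growth law.

    Returns a tidy metric table (clone, model, params, sse, loglik and the
    five metrics -- the CSV the pipeline serializes) plus the FitResult
    objects keyed by (clone, model).
    """
    clone_means = (
        table[table["trait"] == trait]
        .groupby(["clone", "age"])["value"]
        .mean()
        .reset_index()
    )
    rows = []
    fits: dict[tuple[str, GrowthModel], object] = {}
    for i, (clone, grp) in enumerate(clone_means.groupby("clone", sort=True)):
        grp = grp.sort_values("age")
        series = TraitSeries(str(clone), trait, grp["age"].values, grp["value"].values)
        for model in models:
            fit = fit_growth_curve(series, model, seed=seed + i)
            fits[(str(clone), model)] = fit
            metrics = compute_metrics(fit, series)
            row = dict(
                clone=str(clone), trait=trait, model=model.value,
                sse=fit.sse, loglik=fit.loglik, converged=fit.converged,
                aic=metrics.aic, bic=metrics.bic, r2=metrics.r2,
                rmse=metrics.rmse, mae=metrics.mae,
            )
            row.update({f"param_{k}": v for k, v in fit.param_dict().items()})
            rows.append(row)
    return pd.DataFrame(rows), fits


# --------------------------------------------------------------------------
# run configuration and orchestration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    phenotypes: str
    genotypes: str
    outdir: str = "growthtraj_results"
    traits: tuple[str, ...] = ("height_m", "dbh_cm")
    models: tuple[str, ...] = tuple(m.value for m in GrowthModel)
    min_class_size: int = 3
    merge_threshold: float = 0.0  # normalized L2; 0 disables merging
    sigma_mode: str = "pooled"
    count_sigma_df: bool = False
    normalize: str | None = None  # curvature staging mode
    alpha: float = 0.05
    correction: str = "none"  # or "bh" across SNPs
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.correction not in ("none", "bh"):
            raise ValueError(f"unknown correction {self.correction!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        for key in ("traits", "models"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage and write CSV reports plus a manifest.

    Stage failures are recorded in the manifest; stages that depend on a
    failed stage are skipped while independent stages continue. Returns the
    manifest dict (also written to ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "growthtraj",
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "units": {
            "age": "years from planting",
            "height_m": "m",
            "dbh_cm": "cm (measured at 1.3 m)",
        },
        "stages": {},
    }

    def _record(stage: str, status: str, **extra):
        manifest["stages"][stage] = {"status": status, **extra}
        logger.info("stage %s: %s %s", stage, status, extra or "")

    table = read_phenotypes(config.phenotypes)
    geno_path = Path(config.genotypes)
    if geno_path.suffix.lower() == ".vcf":
        genotypes = read_genotypes_vcf(geno_path)
    else:
        genotypes = read_genotypes_csv(geno_path)
    _record("load", "ok", n_phenotype_rows=len(table),
            n_clones=int(table["clone"].nunique()), n_snps=len(genotypes.snp_ids))

    try:
        desc = descriptives(table)
        for name, frame in desc.items():
            frame.to_csv(outdir / f"descriptives_{name}.csv", index=False)
        _record("descriptives", "ok")
    except Exception as exc:  # independent of later stages
        _record("descriptives", "failed", error=str(exc))

    winners: dict[str, GrowthModel] = {}
    all_fits: dict[str, dict] = {}
    metric_frames = []
    for trait in config.traits:
        try:
            models = tuple(GrowthModel(m) for m in config.models)
            metric_table, fits = fit_all_models(table, trait, models, seed=config.seed)
            metric_frames.append(metric_table)
            all_fits[trait] = fits
            comparison = compare_models(metric_table, trait, alpha=config.alpha)
            winners[trait] = comparison.winner
            comparison.pairwise.to_csv(
                outdir / f"model_selection_{trait}.csv", index=False
            )
            logger.info("%s: selected %s", trait, comparison.winner.value)
            _record(f"model_selection[{trait}]", "ok", winner=comparison.winner.value)
        except Exception as exc:
            _record(f"model_selection[{trait}]", "failed", error=str(exc))
    if metric_frames:
        pd.concat(metric_frames).to_csv(outdir / "fits.csv", index=False)
        _record("fits", "ok", n_rows=sum(map(len, metric_frames)))

    qtl_rows = []
    staging_frames = []
    for trait in config.traits:
        if trait not in winners:
            _record(f"qtl[{trait}]", "skipped", reason="model selection failed")
            continue
        model = winners[trait]
        for snp in genotypes.snp_ids:
            row: dict = dict(snp=snp, trait=trait, model=model.value)
            row["maf"] = minor_allele_freq(genotypes, snp)
            classing = build_classes(genotypes, snp, config.min_class_size)
            row["n_classes"] = len(classing.classes)
            if not classing.testable:
                row["status"] = "untestable"
                qtl_rows.append(row)
                continue
            if config.merge_threshold > 0:
                classing = merge_similar_classes(
                    table, classing, model, trait,
                    threshold=config.merge_threshold, seed=config.seed,
                )
                row["n_classes"] = len(classing.classes)
                row["merged"] = bool(classing.merged_from)
            if not classing.testable:
                row["status"] = "untestable"
                qtl_rows.append(row)
                continue
            try:
                lr = lr_trajectory_test(
                    table, classing, model, trait, seed=config.seed,
                    sigma_mode=config.sigma_mode, count_sigma_df=config.count_sigma_df,
                )
                row.update(lr=lr.lr, df=lr.df, p=lr.p, status="ok")
            except Exception as exc:
                row["status"] = f"failed: {exc}"
                qtl_rows.append(row)
                continue
            # per-year single-time association at each measured age
            sub = table[table["trait"] == trait]
            year_ps = []
            for age, grp in sub.groupby("age"):
                vals = grp.groupby("clone")["value"].mean()
                try:
                    f, p = per_year_glm(vals.to_dict(), classing)
                    year_ps.append(p)
                    row[f"glm_p_{age:g}"] = p
                except ValueError:
                    row[f"glm_p_{age:g}"] = None
            row["glm_min_p"] = min(year_ps) if year_ps else None
            # MANOVA on per-clone fitted parameter vectors of the winning law
            try:
                pvecs = {
                    clone: all_fits[trait][(clone, model)].params
                    for clone in genotypes.clone_ids
                    if (clone, model) in all_fits[trait]
                }
                frame = pd.DataFrame.from_dict(pvecs, orient="index")
                manova = param_multitrait_association(frame, classing)
                row["manova_p"] = manova.p
                row["wilks_lambda"] = manova.wilks_lambda
            except Exception as exc:
                row["manova_p"] = None
            qtl_rows.append(row)
            try:
                report = phase_report(
                    lr.class_fits,
                    obs_span=float(sub["age"].max()),
                    normalize=config.normalize,
                )
                report.insert(0, "snp", snp)
                report.insert(1, "trait", trait)
                staging_frames.append(report)
            except Exception as exc:
                _record(f"staging[{trait}:{snp}]", "failed", error=str(exc))
        _record(f"qtl[{trait}]", "ok")

    if qtl_rows:
        qtl = pd.DataFrame(qtl_rows)
        if config.correction == "bh" and qtl["p"].notna().any():
            from statsmodels.stats.multitest import multipletests

            mask = qtl["p"].notna()
            qtl.loc[mask, "p_adj"] = multipletests(
                qtl.loc[mask, "p"], method="fdr_bh"
            )[1]
        qtl.to_csv(outdir / "qtl_results.csv", index=False)
        _record("qtl_report", "ok", n_rows=len(qtl))
    if staging_frames:
        pd.concat(staging_frames).to_csv(outdir / "phase_report.csv", index=False)
        _record("staging", "ok")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def simulate_to_dir(seed: int, outdir: str | Path, config: SimulationConfig | None = None):
    """Write a default synthetic dataset (phenotypes + genotypes) to disk."""
    from .synthetic_data import simulate_genotypes, simulate_trajectories

    config = config or SimulationConfig(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(config, seed=seed)
    pheno = simulate_trajectories(geno, config, seed=seed)
    pheno.to_csv(outdir / "phenotypes.csv", index=False)
    geno.calls.fillna(MISSING_CALL).to_csv(outdir / "genotypes.csv", index_label="clone")
    return outdir / "phenotypes.csv", outdir / "genotypes.csv"
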