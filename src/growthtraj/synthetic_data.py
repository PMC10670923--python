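"""Seeded generator of clonal-trial genotypes and growth phenotypes.

Emulates the data structure of a multi-year clonal field trial: a panel of
clones (default 24), biallelic SNPs drawn at Hardy-Weinberg genotype
frequencies with minor-allele frequencies spread over [0.08, 0.44], and
per-clone height/DBH trajectories that follow the Chapman-Richards law with
genotype-dependent parameters. SNP effects act multiplicatively on curve
parameters -- parameter vector = base * (1 + effect)^dose after dominance
coding -- so genotype classes diverge progressively with age, which is the
generative assumption the trajectory likelihood-ratio test targets.
Measurements are ramet means (default 3 ramets per clone) plus iid Gaussian
noise on the irregular schedule {1, 2, 3, 5, 6, 7, 9, 10, 11} years.

Every output is a pure function of the configuration and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_models import GrowthModel, eval_model, validate_params
from .trajectory_qtl import GenotypeMatrix

__all__ = [
    "SnpSpec",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_trajectories",
    "make_fixture_suite",
    "DEFAULT_AGES",
    "DEFAULT_BASE_PARAMS",
]

#: irregular measurement schedule (years from planting); years 4 and 8 skipped
DEFAULT_AGES = (1.0, 2.0, 3.0, 5.0, 6.0, 7.0, 9.0, 10.0, 11.0)

#: Chapman-Richards base parameters per trait: plausible plateau/rate/shape
#: for a fast-growing poplar stand (height in m, DBH in cm)
DEFAULT_BASE_PARAMS: dict[str, tuple[float, float, float]] = {
    "height_m": (28.0, 0.18, 1.6),
    "dbh_cm": (33.0, 0.22, 1.3),
}

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "T"), ("G", "T"), ("A", "C"), ("C", "G"))


@dataclass(frozen=True)
class SnpSpec:
    """One simulated biallelic SNP: frequency, effect target and mode."""

    snp_id: str
    maf: float
    effect_target: str = "none"  # "a", "b", "c" or "none"
    effect_size: float = 0.0  # relative shift per effective allele dose
    dominance: str = "additive"  # "additive", "dominant", "recessive"
    alleles: tuple[str, str] = ("A", "G")  # (ref, alt)

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.effect_size <= -1.0:
            raise ValueError(f"{self.snp_id}: effect_size must be > -1")
        if self.effect_target not in ("a", "b", "c", "none"):
            raise ValueError(f"{self.snp_id}: bad effect_target {self.effect_target!r}")
        if self.dominance not in ("additive", "dominant", "recessive"):
            raise ValueError(f"{self.snp_id}: bad dominance {self.dominance!r}")

    def dose(self, n_alt: int) -> float:
        """Effective allele dose after dominance coding (0, 1 or 2 alt alleles)."""
        if self.dominance == "additive":
            return float(n_alt)
        if self.dominance == "dominant":
            return 1.0 if n_alt >= 1 else 0.0
        return 1.0 if n_alt == 2 else 0.0


def _default_snp_specs() -> tuple[SnpSpec, ...]:
    """20 SNPs with MAF spread over [0.08, 0.44]; three carry trait effects."""
    mafs = np.round(np.linspace(0.08, 0.44, 20), 3)
    effects = {  # snp index -> (target, size, dominance)
        11: ("a", 0.10, "additive"),  # plateau QTL, clearly trajectory-active
        7: ("a", 0.06, "dominant"),
        3: ("b", 0.08, "additive"),  # rate QTL
    }
    specs = []
    for i, maf in enumerate(mafs):
        target, size, dom = effects.get(i, ("none", 0.0, "additive"))
        specs.append(
            SnpSpec(
                snp_id=f"SNP{i + 1}",
                maf=float(maf),
                effect_target=target,
                effect_size=size,
                dominance=dom,
                alleles=_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)],
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated clonal trial."""

    n_clones: int = 24
    snp_specs: tuple[SnpSpec, ...] = field(default_factory=_default_snp_specs)
    base_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_PARAMS)
    )
    model: GrowthModel = GrowthModel.RICHARD
    noise_sd: float = 0.015  # sd of measurement noise per ramet
    noise_mode: str = "relative"  # "relative" (x asymptote) or "absolute"
    ages: tuple[float, ...] = DEFAULT_AGES
    n_ramets: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.noise_mode not in ("relative", "absolute"):
            raise ValueError(f"bad noise_mode {self.noise_mode!r}")
        if not all(a < b for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("ages must be strictly increasing")
        for trait, p in self.base_params.items():
            validate_params(self.model, p)


def _clone_ids(n: int) -> list[str]:
    return [f"C{i + 1:03d}" for i in range(n)]


def simulate_genotypes(config: SimulationConfig, seed: int | None = None) -> GenotypeMatrix:
    """Draw diploid genotypes per SNP iid at Hardy-Weinberg frequencies.

    With alt-allele frequency q = maf, genotype probabilities are
    (1-q)^2, 2q(1-q), q^2 for ref-hom, het, alt-hom.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    clones = _clone_ids(config.n_clones)
    calls = {}
    alleles = {}
    for spec in config.snp_specs:
        q = spec.maf
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        n_alt = rng.choice(3, size=config.n_clones, p=probs)
        ref, alt = spec.alleles
        geno = {0: f"{ref}/{ref}", 1: "/".join(sorted((ref, alt))), 2: f"{alt}/{alt}"}
        calls[spec.snp_id] = [geno[int(k)] for k in n_alt]
        alleles[spec.snp_id] = spec.alleles
    frame = pd.DataFrame(calls, index=clones)
    return GenotypeMatrix(calls=frame, alleles=alleles)


def clone_params(
    genotypes: GenotypeMatrix, config: SimulationConfig, trait: str
) -> pd.DataFrame:
    """Per-clone curve parameters implied by the genotypes (no noise).

    Each effect SNP multiplies its target parameter by
    (1 + effect_size)^dose, dose being the dominance-coded alt-allele count.
    """
    base = np.asarray(config.base_params[trait], dtype=float)
    names = {"a": 0, "b": 1, "c": 2}
    rows = {}
    for clone in genotypes.clone_ids:
        p = base.copy()
        for spec in config.snp_specs:
            if spec.effect_target == "none":
                continue
            call = genotypes.calls.loc[clone, spec.snp_id]
            if call is None:
                continue
            n_alt = call.split("/").count(spec.alleles[1])
            p[names[spec.effect_target]] *= (1.0 + spec.effect_size) ** spec.dose(n_alt)
        validate_params(config.model, p)  # extreme effects must fail loudly
        rows[clone] = p
    return pd.DataFrame.from_dict(rows, orient="index", columns=["a", "b", "c"])


def simulate_trajectories(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    seed: int | None = None,
    return_ramets: bool = False,
) -> pd.DataFrame:
    """Simulate the long-format phenotype table for all clones and traits.

    Each ramet observation is the growth-law value plus iid Gaussian noise
    (sd = noise_sd * asymptote in "relative" mode); the clone-level record is
    the ramet mean. Columns: clone, trait, age, value (plus ramet when
    ``return_ramets``).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    ages = np.asarray(config.ages, dtype=float)
    records = []
    for trait in config.base_params:
        params = clone_params(genotypes, config, trait)
        sd = (
            config.noise_sd * float(config.base_params[trait][0])
            if config.noise_mode == "relative"
            else config.noise_sd
        )
        for clone in genotypes.clone_ids:
            mean_curve = np.asarray(eval_model(config.model, params.loc[clone].values, ages))
            ramets = mean_curve + rng.normal(0.0, sd, size=(config.n_ramets, len(ages)))
            # measurements are physically positive; floor rare sub-zero draws
            ramets = np.maximum(ramets, 0.01)
            if return_ramets:
                for r in range(config.n_ramets):
                    for age, val in zip(ages, ramets[r]):
                        records.append(
                            dict(clone=clone, trait=trait, age=age, value=val, ramet=r + 1)
                        )
            else:
                for age, val in zip(ages, ramets.mean(axis=0)):
                    records.append(dict(clone=clone, trait=trait, age=age, value=val))
    return pd.DataFrame.from_records(records)


def make_fixture_suite(seed: int, outdir: str | Path | None = None) -> dict[str, dict]:
    """Small canned datasets for tests and documentation.

    Returns (and optionally writes as CSV) four deterministic bundles:

    * ``null-24``: 24 clones, no SNP effects -- calibration data;
    * ``effect-20pct-24``: 24 clones, one additive SNP shifting the plateau
      by 20% per alt allele -- a clearly detectable trajectory QTL;
    * ``monomorphic-snp``: includes a monomorphic (untestable) SNP;
    * ``tiny-6``: 6-clone smoke set.
    """
    bundles: dict[str, dict] = {}

    def _bundle(name: str, config: SimulationConfig, offset: int):
        geno = simulate_genotypes(config, seed=seed + offset)
        pheno = simulate_trajectories(geno, config, seed=seed + offset)
        bundles[name] = {"config": config, "genotypes": geno, "phenotypes": pheno}

    null_specs = tuple(
        SnpSpec(snp_id=f"SNP{i + 1}", maf=m)
        for i, m in enumerate((0.25, 0.40, 0.15))
    )
    _bundle("null-24", SimulationConfig(snp_specs=null_specs, seed=seed), 0)

    effect_specs = (
        SnpSpec(snp_id="SNP1", maf=0.4, effect_target="a", effect_size=0.20),
        SnpSpec(snp_id="SNP2", maf=0.3),
    )
    _bundle("effect-20pct-24", SimulationConfig(snp_specs=effect_specs, seed=seed), 1)

    mono_specs = (
        SnpSpec(snp_id="SNP1", maf=1e-9 + 1e-12),  # effectively monomorphic
        SnpSpec(snp_id="SNP2", maf=0.3),
    )
    _bundle("monomorphic-snp", SimulationConfig(snp_specs=mono_specs, seed=seed), 2)

    tiny_specs = (SnpSpec(snp_id="SNP1", maf=0.4),)
    _bundle("tiny-6", SimulationConfig(n_clones=6, snp_specs=tiny_specs, seed=seed), 3)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, bundle in bundles.items():
            bundle["phenotypes"].to_csv(outdir / f"{name}.phenotypes.csv", index=False)
            calls = bundle["genotypes"].calls.fillna("./.")
            calls.to_csv(outdir / f"{name}.genotypes.csv", index_label="clone")
    return bundles
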