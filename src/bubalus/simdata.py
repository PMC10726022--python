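"""Synthetic herds with the covariance structure the analysis assumes.

The generator inverts the animal model: it draws direct additive and
maternal genetic values for every pedigree animal from N(0, A ⊗ Σ)
through the Cholesky factor of the relationship matrix A (Σ the
across-trait genetic covariance), attaches the dam's maternal value to
each calf's record, adds categorical fixed effects and an independent
residual, and produces

* a pedigree (founder sires and dams plus one or more calf cohorts),
* one 365-day phenotype per recorded calf together with the truth
  (breeding values, maternal values, fixed-effect sums),
* noisy repeated measurements on a linear growth trajectory through the
  365-day value, for exercising the age-standardization step,
* biallelic SNP genotypes gene-dropped from founder allele frequencies.

Defaults emulate the study herd: 313 calves across 36 farms, the
published per-trait variance components and genetic correlations, fixed
effect sizes matching the published least-square-mean contrasts, and
the skewed candidate-SNP allele frequencies.  A single seed drives all
stages through independent spawned streams, so any stage can be re-run
on its own and the whole bundle is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import refdata
from .pedigree import Pedigree, pedigree_from_records, relationship_matrix

__all__ = ["SimConfig", "SimulatedHerd", "simulate_pedigree",
           "simulate_phenotypes", "simulate_measurement_series",
           "simulate_genotypes", "simulate_herd"]

_FACTOR_LEVELS = {
    "birth_season": ("spring", "summer"),
    "sex": ("male", "female"),
    "dam_age_class": ("le6", "gt6"),
    "birth_weight_class": ("lt33", "ge33"),
}


def _default_components() -> pd.DataFrame:
    return refdata.VARIANCE_COMPONENTS[["sigma2_a", "sigma2_m", "sigma2_e"]].copy()


def _default_snp_loci() -> dict:
    # (allele1, allele2, founder frequency of allele1), from published counts
    return {
        "LCORL-AX-85166825": ("T", "C", 463 / 472),
        "HMGA2-AX-85179490": ("C", "T", 394 / 470),
    }


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic herd.

    ``true_components`` rows are traits with columns sigma2_a, sigma2_m,
    sigma2_e; ``true_rG`` is the across-trait genetic correlation matrix
    (also used for the maternal and, by default, residual correlation
    structure).  ``fixed_effect_contrasts`` maps factor -> trait -> full
    first-minus-second-level contrast; farm effects are drawn
    N(0, (farm_sd_frac * sigma_P)^2).  ``calves_per_dam`` bounds dam
    reuse; ``generations`` > 1 breeds later cohorts from earlier ones.
    """

    n_sires: int = 36
    n_dams: int = 313
    n_calves: int = 313
    n_farms: int = 36
    #: sires of the dams; >0 puts dams in paternal half-sib groups, which
    #: is what makes the maternal variance identifiable when every dam
    #: has a single calf (0 = dams are unrelated founders)
    n_grandsires: int = 25
    calves_per_dam: int = 1
    generations: int = 1
    traits: tuple[str, ...] = refdata.TRAITS
    true_components: pd.DataFrame = field(default_factory=_default_components)
    true_rG: pd.DataFrame = field(default_factory=refdata.genetic_correlation_frame)
    residual_corr: pd.DataFrame | None = None
    means: pd.Series = field(default_factory=lambda: refdata.OVERALL_MEANS.copy())
    fixed_effect_contrasts: dict = field(
        default_factory=lambda: {
            f: dict(v) for f, v in refdata.FIXED_EFFECT_CONTRASTS.items()
        }
    )
    farm_sd_frac: float = 0.5
    measurement_ages: tuple[int, ...] = (300, 360, 420)
    age_jitter_days: int = 15
    growth_rate: pd.Series | None = None  # trait units/day; default 0.7*mean/365
    measurement_noise_frac: float = 0.01
    snp_loci: dict = field(default_factory=_default_snp_loci)
    snp_effects: dict = field(default_factory=dict)  # locus -> trait -> per-copy
    seed: int = 0

    def __post_init__(self):
        if min(self.n_sires, self.n_dams, self.n_calves, self.n_farms) <= 0:
            raise ValueError("population counts must be positive")
        if self.n_calves > self.n_dams * self.calves_per_dam * self.generations:
            raise ValueError(
                "n_calves exceeds n_dams * calves_per_dam (litter bound)"
            )
        comp = self.true_components.loc[list(self.traits)]
        if (comp < 0).any().any():
            raise ValueError("variance components must be non-negative")
        object.__setattr__(self, "traits", tuple(self.traits))

    def streams(self) -> dict[str, np.random.Generator]:
        """Named independent RNG streams spawned from the single seed."""
        root = np.random.SeedSequence(self.seed)
        names = ("pedigree", "phenotypes", "measurements", "genotypes")
        return {
            nm: np.random.default_rng(s) for nm, s in zip(names, root.spawn(4))
        }


def _scaled_cov(sd: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Covariance D^.5 R D^.5; PSD is required of R, zero variances allowed."""
    cov = np.outer(sd, sd) * corr
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        raise ValueError("correlation matrix not positive semidefinite")
    return cov


def _psd_chol(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor tolerant of semidefinite (zero-variance) inputs."""
    scale = float(np.trace(cov)) / max(len(cov), 1)
    if scale <= 0:
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov + 1e-12 * scale * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Founder sires and dams plus ``generations`` calf cohorts.

    Every calf has a known sire and dam; dams are reused at most
    ``calves_per_dam`` times per generation.  With ``generations`` > 1,
    later cohorts draw their parents from the previous cohort.
    """
    rng = rng or cfg.streams()["pedigree"]
    grandsires = [f"G{i + 1:04d}" for i in range(cfg.n_grandsires)]
    sires = [f"S{i + 1:04d}" for i in range(cfg.n_sires)]
    dams = [f"D{i + 1:04d}" for i in range(cfg.n_dams)]
    entries: list[tuple[str, str | None, str | None]] = [
        (a, None, None) for a in grandsires + sires
    ]
    if grandsires:
        # dams form paternal half-sib families (maternal granddam unknown)
        dam_sires = rng.integers(0, len(grandsires), size=len(dams))
        entries += [
            (d, grandsires[dam_sires[i]], None) for i, d in enumerate(dams)
        ]
    else:
        entries += [(d, None, None) for d in dams]
    per_gen = [cfg.n_calves // cfg.generations] * cfg.generations
    per_gen[-1] += cfg.n_calves - sum(per_gen)
    males, females = sires, dams
    counter = 0
    for g, n_g in enumerate(per_gen):
        slots = np.repeat(
            np.arange(len(females)), cfg.calves_per_dam
        )
        dam_pick = rng.permutation(slots)[:n_g]
        sire_pick = rng.integers(0, len(males), size=n_g)
        cohort = []
        for k in range(n_g):
            counter += 1
            calf = f"C{counter:05d}"
            entries.append((calf, males[sire_pick[k]], females[dam_pick[k]]))
            cohort.append(calf)
        if g + 1 < cfg.generations:
            half = len(cohort) // 2
            males, females = cohort[:half], cohort[half:]
    return pedigree_from_records(entries)


def _recorded_calves(ped: Pedigree) -> list[str]:
    # calves carry both parents; dams bred from grandsires carry only a sire
    return [a for a, s, d in ped.entries if s is not None and d is not None]


def simulate_phenotypes(
    ped: Pedigree,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    genotypes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One 365-day record per calf, plus the generating truth.

    Returns ``(phenotypes, truth)``.  ``phenotypes`` is indexed by
    animal with the factor columns (farm, birth_season, sex,
    dam_age_class, birth_weight_class) and one column per trait.
    ``truth`` carries, per pedigree animal and trait, the drawn breeding
    value ``a`` and maternal value ``m`` (MultiIndex columns), so
    recovery tests can compare estimates with the generating values.
    When ``genotypes`` and ``cfg.snp_effects`` are supplied, each
    allele copy adds its per-copy effect to the configured traits.
    """
    rng = rng or cfg.streams()["phenotypes"]
    traits = list(cfg.traits)
    q = len(ped)
    ids = list(ped.ids)
    A = relationship_matrix(ped).values
    L_A = np.linalg.cholesky(A + 1e-10 * np.eye(q))
    comp = cfg.true_components.loc[traits]
    if all(t in cfg.true_rG.index for t in traits):
        R = cfg.true_rG.loc[traits, traits].to_numpy()
    elif len(traits) == 1:
        R = np.eye(1)
    else:
        missing = [t for t in traits if t not in cfg.true_rG.index]
        raise ValueError(f"true_rG lacks traits {missing}")
    sd_a = np.sqrt(comp["sigma2_a"].to_numpy())
    sd_m = np.sqrt(comp["sigma2_m"].to_numpy())
    sd_e = np.sqrt(comp["sigma2_e"].to_numpy())
    a_vals = L_A @ rng.standard_normal((q, len(traits))) @ _psd_chol(
        _scaled_cov(sd_a, R)
    ).T
    m_vals = L_A @ rng.standard_normal((q, len(traits))) @ _psd_chol(
        _scaled_cov(sd_m, R)
    ).T
    truth = pd.concat(
        {
            "a": pd.DataFrame(a_vals, index=ids, columns=traits),
            "m": pd.DataFrame(m_vals, index=ids, columns=traits),
        },
        axis=1,
    )
    calves = _recorded_calves(ped)
    n = len(calves)
    dam_of = {a: d for a, s, d in ped.entries}
    pos = {a: i for i, a in enumerate(ids)}
    Re = (cfg.residual_corr.loc[traits, traits].to_numpy()
          if cfg.residual_corr is not None else R)
    e_vals = rng.standard_normal((n, len(traits))) @ _psd_chol(
        _scaled_cov(sd_e, Re)
    ).T
    factors = pd.DataFrame(
        {
            "farm": rng.integers(1, cfg.n_farms + 1, size=n).astype(str),
            **{
                f: np.asarray(levels)[rng.integers(0, 2, size=n)]
                for f, levels in _FACTOR_LEVELS.items()
            },
        },
        index=pd.Index(calves, name="animal"),
    )
    farm_levels = sorted(factors["farm"].unique())
    out = factors.copy()
    for t_i, t in enumerate(traits):
        sp = float(comp.loc[t].sum())
        farm_eff = dict(
            zip(
                farm_levels,
                rng.normal(0.0, cfg.farm_sd_frac * np.sqrt(sp), len(farm_levels)),
            )
        )
        fixed = factors["farm"].map(farm_eff).to_numpy()
        for f, levels in _FACTOR_LEVELS.items():
            contrast = cfg.fixed_effect_contrasts.get(f, {}).get(t, 0.0)
            eff = {levels[0]: contrast / 2.0, levels[1]: -contrast / 2.0}
            fixed = fixed + factors[f].map(eff).to_numpy()
        a_rec = a_vals[[pos[c] for c in calves], t_i]
        m_rec = np.array(
            [m_vals[pos[dam_of[c]], t_i] if dam_of[c] is not None else 0.0
             for c in calves]
        )
        y = cfg.means[t] + fixed + a_rec + m_rec + e_vals[:, t_i]
        out[t] = y
    if genotypes is not None and cfg.snp_effects:
        geno_wide = genotypes.pivot(index="animal", columns="locus",
                                    values="genotype")
        for locus, per_trait in cfg.snp_effects.items():
            if locus not in geno_wide.columns:
                continue
            a1 = cfg.snp_loci[locus][0]
            dose = geno_wide[locus].reindex(out.index).str.count(a1)
            for t, eff in per_trait.items():
                out[t] = out[t] + dose.fillna(0.0) * eff
    return out, truth


def simulate_measurement_series(
    pheno365: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Noisy repeated measurements on linear trajectories through 365 d.

    Each animal is measured at the configured ages plus a per-animal
    jitter; values follow ``value_365 + slope * (age - 365)`` plus
    independent measurement noise of SD ``measurement_noise_frac *
    trait mean``.  Long format: animal, trait, age_days, value.
    """
    rng = rng or cfg.streams()["measurements"]
    traits = [t for t in cfg.traits if t in pheno365.columns]
    slope = (
        cfg.growth_rate
        if cfg.growth_rate is not None
        else 0.7 * cfg.means / 365.0
    )
    rows = []
    ages0 = np.asarray(cfg.measurement_ages)
    for animal, rec in pheno365.iterrows():
        jitter = rng.integers(-cfg.age_jitter_days, cfg.age_jitter_days + 1)
        ages = ages0 + jitter
        for t in traits:
            noise_sd = cfg.measurement_noise_frac * abs(cfg.means[t])
            for age in ages:
                rows.append(
                    (
                        animal,
                        t,
                        int(age),
                        rec[t] + slope[t] * (age - 365) + rng.normal(0, noise_sd),
                    )
                )
    return pd.DataFrame(rows, columns=["animal", "trait", "age_days", "value"])


def simulate_genotypes(
    ped: Pedigree, cfg: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Gene-drop biallelic SNP genotypes through the pedigree.

    Founders draw two gametes at the configured founder allele
    frequency; descendants inherit one random allele from each parent.
    Long format: animal, locus, genotype (alphabetically normalized).
    """
    rng = rng or cfg.streams()["genotypes"]
    rows = []
    for locus, (a1, a2, p1) in cfg.snp_loci.items():
        if not 0.0 < p1 <= 1.0:
            raise ValueError(f"founder frequency for {locus} outside (0, 1]")
        alleles: dict[str, tuple[str, str]] = {}
        for animal, sire, dam in ped.entries:
            pair = []
            for parent in (sire, dam):
                if parent is None:
                    pair.append(a1 if rng.random() < p1 else a2)
                else:
                    pair.append(alleles[parent][rng.integers(0, 2)])
            alleles[animal] = (pair[0], pair[1])
            rows.append((animal, locus, "".join(sorted(pair))))
    return pd.DataFrame(rows, columns=["animal", "locus", "genotype"])


@dataclass(frozen=True)
class SimulatedHerd:
    """A complete synthetic data bundle plus its generating truth."""

    config: SimConfig
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    measurements: pd.DataFrame
    genotypes: pd.DataFrame


def simulate_herd(cfg: SimConfig | None = None, **overrides) -> SimulatedHerd:
    """Run every stage of the generator under one seed."""
    if cfg is None:
        cfg = SimConfig(**overrides)
    elif overrides:
        cfg = replace(cfg, **overrides)
    streams = cfg.streams()
    ped = simulate_pedigree(cfg, streams["pedigree"])
    genotypes = simulate_genotypes(ped, cfg, streams["genotypes"])
    phenotypes, truth = simulate_phenotypes(
        ped, cfg, streams["phenotypes"], genotypes=genotypes
    )
    measurements = simulate_measurement_series(
        phenotypes, cfg, streams["measurements"]
    )
    return SimulatedHerd(cfg, ped, phenotypes, truth, measurements, genotypes)
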