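"""End-to-end orchestration and table rendering.

``run_pipeline`` sequences the stages on a data bundle — age
standardization, per-trait fixed-effects analysis, EM-REML variance
components with BLUP breeding values, genetic parameters and selection
responses, and candidate-SNP association — persisting every stage's
output under the configured directory so each rendered number is
traceable to an intermediate file.  ``render_tables`` writes the
herd-book style reports: least-square means with Tukey letters,
variance components with heritabilities, the combined genetic/phenotypic
correlation matrix, the selection-response matrix and the SNP summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agestd, genpar, linmod, reml, snp
from .pedigree import Pedigree, read_pedigree

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_tables"]

log = logging.getLogger("bubalus")

DEFAULT_FACTORS = (
    "farm", "birth_season", "sex", "dam_age_class", "birth_weight_class"
)


@dataclass
class PipelineConfig:
    """File locations, the trait list and the analysis thresholds."""

    pedigree: str | Path
    measurements: str | Path
    genotypes: str | Path | None = None
    out_dir: str | Path = "results"
    traits: tuple[str, ...] = ()
    factors: tuple[str, ...] = DEFAULT_FACTORS
    min_farm_n: int = 4
    alpha: float = 0.05
    target_age: int = 365
    include_maternal: bool = True
    reml_tol: float = 1e-8
    reml_max_iter: int = 2000
    reml_accelerate: bool = True
    selection_intensity: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("pedigree", "measurements"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.genotypes is not None and not Path(self.genotypes).exists():
            raise FileNotFoundError(f"genotypes file not found: {self.genotypes}")
        if self.min_farm_n < 1 or not 0 < self.alpha < 1:
            raise ValueError("thresholds out of range")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, keyed the way the reports need."""

    standardized: agestd.StandardizedTable
    fits: dict[str, linmod.FixedFit]
    adjusted: pd.DataFrame
    components: dict[str, reml.VarianceComponents]
    herit: dict[str, genpar.Heritabilities]
    ebvs: dict[str, pd.DataFrame]
    correlations: genpar.CorrelationMatrices | None
    responses: pd.DataFrame | None
    snp_summaries: dict[str, snp.GenotypeSummary] = field(default_factory=dict)
    snp_tests: dict[tuple[str, str], snp.GenotypeAnova] = field(default_factory=dict)


def _factor_table(measurements: pd.DataFrame, factors) -> pd.DataFrame:
    cols = [c for c in factors if c in measurements.columns]
    return (
        measurements[["animal", *cols]]
        .drop_duplicates("animal")
        .set_index("animal")
    )


def run_pipeline(
    cfg: PipelineConfig, pedigree: Pedigree | None = None
) -> PipelineResult:
    """Run every stage in order, persisting intermediates under out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = pedigree if pedigree is not None else read_pedigree(cfg.pedigree)
    raw = pd.read_csv(cfg.measurements)
    log.info("loaded %d measurement rows, %d pedigree entries", len(raw), len(ped))

    # 1. age standardization
    std = agestd.standardize_table(
        raw[["animal", "trait", "age_days", "value"]], cfg.target_age
    )
    factor_info = _factor_table(raw, cfg.factors)
    pheno = factor_info.join(std.values, how="inner")
    std.values.to_csv(out / "standardized.csv")
    std.extrapolation_days.to_csv(out / "extrapolation_days.csv")
    traits = list(cfg.traits) or [
        c for c in std.values.columns if c not in cfg.factors
    ]
    log.info("standardized %d animals, traits: %s", len(pheno), traits)

    # 2. per-trait fixed-effects analysis and adjustment
    fits: dict[str, linmod.FixedFit] = {}
    adjusted = {}
    for t in traits:
        data_t = linmod.filter_farms(
            pheno.reset_index(), cfg.min_farm_n, trait=t
        )
        spec = linmod.FixedModelSpec(
            t, tuple(cfg.factors), cfg.min_farm_n, cfg.alpha
        )
        fit = linmod.fit_fixed_model(data_t, spec)
        fits[t] = fit
        adj = linmod.adjust_phenotypes(fit)
        adjusted[t] = pd.Series(
            adj.to_numpy(), index=data_t.loc[adj.index, "animal"]
        )
        log.info("fitted %s on %d records", t, len(fit.data))
    adjusted_df = pd.DataFrame(adjusted)
    adjusted_df.to_csv(out / "adjusted.csv")

    # 3. REML + BLUP per trait
    components: dict[str, reml.VarianceComponents] = {}
    herit: dict[str, genpar.Heritabilities] = {}
    ebvs: dict[str, pd.DataFrame] = {}
    for t in traits:
        records = fits[t].data[["animal", *cfg.factors, t]]
        sig = fits[t].significant_factors() or list(cfg.factors)[:1]
        aspec = reml.AnimalModelSpec(
            t, ped, tuple(sig), include_maternal=cfg.include_maternal
        )
        vc = reml.em_reml(
            records,
            aspec,
            tol=cfg.reml_tol,
            max_iter=cfg.reml_max_iter,
            accelerate=cfg.reml_accelerate,
        )
        components[t] = vc
        herit[t] = genpar.heritabilities(vc)
        ebvs[t] = reml.blup_ebv(records, aspec, vc)
        with open(out / f"components_{t}.json", "w") as fh:
            json.dump(vc.as_dict(), fh, indent=2)
        ebvs[t].to_csv(out / f"ebv_{t}.csv")
        log.info(
            "REML %s: sa2=%.4g sm2=%.4g se2=%.4g (%d it, converged=%s)",
            t, vc.sigma2_a, vc.sigma2_m, vc.sigma2_e,
            vc.n_iterations, vc.converged,
        )

    # 4. genetic parameters
    correlations = responses = None
    if len(traits) >= 2:
        ebv_series = {t: ebvs[t]["ebv_direct"] for t in traits}
        correlations = genpar.correlation_matrices(ebv_series, adjusted_df)
        h2s = {t: herit[t].h2_direct for t in traits}
        sp2 = {t: components[t].sigma2_p for t in traits}
        usable = [t for t in traits if h2s[t] > 0]
        responses = genpar.response_matrix(
            {t: h2s[t] for t in usable},
            {t: sp2[t] for t in usable},
            correlations.genetic.loc[usable, usable],
            cfg.selection_intensity,
        )
        correlations.combined().to_csv(out / "correlations.csv")
        responses.to_csv(out / "responses.csv")

    # 5. SNP association on adjusted phenotypes
    snp_summaries: dict[str, snp.GenotypeSummary] = {}
    snp_tests: dict[tuple[str, str], snp.GenotypeAnova] = {}
    if cfg.genotypes is not None:
        geno = pd.read_csv(cfg.genotypes)
        for locus, grp in geno.groupby("locus"):
            calls = grp.set_index("animal")["genotype"]
            summary = snp.genotype_summary(calls)
            snp_summaries[str(locus)] = summary
            if summary.monomorphic:
                log.info("locus %s monomorphic; no association test", locus)
                continue
            for t in traits:
                adj_t = adjusted_df[t].dropna()
                snp_tests[(str(locus), t)] = snp.genotype_anova(
                    adj_t, calls.reindex(adj_t.index)
                )
    result = PipelineResult(
        std, fits, adjusted_df, components, herit, ebvs,
        correlations, responses, snp_summaries, snp_tests,
    )
    render_tables(result, out)
    return result


def _stars(p: float) -> str:
    if pd.isna(p):
        return ""
    for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < thr:
            return s
    return ""


def render_tables(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write the human-readable report tables; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # least-square means with Tukey letters, per trait and factor
    rows = []
    for t, fit in result.fits.items():
        rows.append({"trait": t, "factor": "mu", "level": "", "n": len(fit.data),
                     "estimate": round(fit.mu, 4), "se": "", "letters": "",
                     "sig": ""})
        for f in fit.spec.factors:
            p = fit.anova.loc[f, "p"]
            try:
                groups = linmod.tukey_groups(fit, f, fit.spec.alpha)
            except ValueError:
                groups = linmod.ls_means(fit, f).assign(letters="")
            for level, g in groups.iterrows():
                rows.append({
                    "trait": t, "factor": f, "level": level, "n": int(g["n"]),
                    "estimate": round(g["estimate"], 2),
                    "se": round(g["se"], 2),
                    "letters": g["letters"] if _stars(p) else "",
                    "sig": _stars(p),
                })
    paths["lsmeans"] = out / "table_lsmeans.csv"
    pd.DataFrame(rows).to_csv(paths["lsmeans"], index=False)

    # variance components and heritabilities
    comp_rows = []
    for t, vc in result.components.items():
        h = result.herit[t]
        comp_rows.append({
            "trait": t,
            "sigma2_a": round(vc.sigma2_a, 3), "se_a": round(vc.se_a, 3),
            "sigma2_m": round(vc.sigma2_m, 3), "se_m": round(vc.se_m, 3),
            "sigma2_e": round(vc.sigma2_e, 3), "se_e": round(vc.se_e, 3),
            "sigma2_p": round(vc.sigma2_p, 3), "se_p": round(vc.se_p, 3),
            "h2_a": round(h.h2_direct, 3), "h2_a_se": round(h.se_direct, 3),
            "h2_m": round(h.h2_maternal, 3), "h2_m_se": round(h.se_maternal, 3),
            "h2_T": round(h.h2_total, 3), "h2_T_se": round(h.se_total, 3),
            "converged": vc.converged,
            "boundary": ",".join(k for k, v in vc.boundary.items() if v),
        })
    paths["components"] = out / "table_components.csv"
    pd.DataFrame(comp_rows).to_csv(paths["components"], index=False)

    if result.correlations is not None:
        combined = result.correlations.combined().round(2)
        star_g = result.correlations.genetic_p.map(_stars)
        star_p = result.correlations.phenotypic_p.map(_stars)
        traits = list(result.correlations.traits)
        disp = combined.astype(object)
        for i, t in enumerate(traits):
            for j, u in enumerate(traits):
                if i < j:
                    disp.loc[t, u] = f"{combined.loc[t, u]:.2f}{star_g.loc[t, u]}"
                elif i > j:
                    disp.loc[t, u] = f"{combined.loc[t, u]:.2f}{star_p.loc[t, u]}"
                else:
                    disp.loc[t, u] = "-"
        paths["correlations"] = out / "table_correlations.csv"
        disp.to_csv(paths["correlations"])
    if result.responses is not None:
        paths["responses"] = out / "table_responses.csv"
        result.responses.round(4).to_csv(paths["responses"])

    snp_rows = []
    for locus, summary in result.snp_summaries.items():
        snp_rows.append({
            "locus": locus,
            "counts": ";".join(f"{g}:{c}" for g, c in sorted(summary.counts.items())),
            "allele_freqs": ";".join(
                f"{a}:{f:.4f}" for a, f in sorted(summary.allele_freqs.items())
            ),
            "monomorphic": summary.monomorphic,
            "hwe_p": round(summary.hwe_p, 4),
        })
    if snp_rows:
        paths["snp_summary"] = out / "table_snp_summary.csv"
        pd.DataFrame(snp_rows).to_csv(paths["snp_summary"], index=False)
    test_rows = []
    for (locus, t), test in result.snp_tests.items():
        means = ";".join(
            f"{g}:{r['mean']:.2f}(n={int(r['n'])})"
            for g, r in test.groups.iterrows()
        )
        test_rows.append({
            "locus": locus, "trait": t, "group_means": means,
            "F": round(test.F, 4) if test.tested else "",
            "p": round(test.p, 4) if test.tested else "",
            "note": test.note,
        })
    if test_rows:
        paths["snp_anova"] = out / "table_snp_anova.csv"
        pd.DataFrame(test_rows).to_csv(paths["snp_anova"], index=False)
    return paths
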