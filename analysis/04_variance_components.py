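"""EM-REML variance components and BLUP breeding values per trait.

Fits the univariate animal model with an uncorrelated maternal genetic
effect (y = Xb + Z_a a + Z_m m + e, a ~ N(0, A sa2), m ~ N(0, A sm2))
to every standardized trait, using the significant environmental
effects as fixed factors, and derives direct, maternal and total
(Willham) heritabilities with average-information standard errors.

Writes results/components.csv and results/ebv_<trait>.csv.
"""

from pathlib import Path

import pandas as pd

from bubalus import genpar, linmod, reml
from bubalus.pedigree import read_pedigree

ROOT = Path(__file__).resolve().parents[1] / "results"
FACTORS = ("farm", "birth_season", "sex", "dam_age_class",
           "birth_weight_class")


def main() -> None:
    ped = read_pedigree(ROOT / "synthetic_herd" / "ped.csv")
    std = pd.read_csv(ROOT / "standardized.csv", index_col=0)
    raw = pd.read_csv(ROOT / "synthetic_herd" / "measurements.csv")
    info = raw[["animal", *FACTORS]].drop_duplicates("animal").set_index(
        "animal"
    )
    pheno = info.join(std)
    rows = []
    for t in std.columns:
        data = linmod.filter_farms(pheno.reset_index(), 4, trait=t)
        fit = linmod.fit_fixed_model(data, linmod.FixedModelSpec(t, FACTORS))
        fixed = tuple(fit.significant_factors()) or ("farm",)
        spec = reml.AnimalModelSpec(t, ped, fixed, include_maternal=True)
        vc = reml.em_reml(data, spec, tol=1e-6, max_iter=1000,
                          accelerate=True)
        h = genpar.heritabilities(vc)
        rows.append({
            "trait": t, "n": len(fit.data),
            "sigma2_a": round(vc.sigma2_a, 3),
            "sigma2_m": round(vc.sigma2_m, 3),
            "sigma2_e": round(vc.sigma2_e, 3),
            "sigma2_p": round(vc.sigma2_p, 3),
            "h2_a": round(h.h2_direct, 3), "h2_a_se": round(h.se_direct, 3),
            "h2_m": round(h.h2_maternal, 3), "h2_m_se": round(h.se_maternal, 3),
            "h2_T": round(h.h2_total, 3), "h2_T_se": round(h.se_total, 3),
            "iterations": vc.n_iterations, "converged": vc.converged,
            "boundary": ",".join(k for k, v in vc.boundary.items() if v),
        })
        ebv = reml.blup_ebv(data, spec, vc)
        ebv.to_csv(ROOT / f"ebv_{t}.csv")
        print(f"{t}: h2a={h.h2_direct:.3f}+-{h.se_direct:.3f} "
              f"h2m={h.h2_maternal:.3f} h2T={h.h2_total:.3f} "
              f"({vc.n_iterations} EM sweeps)")
    pd.DataFrame(rows).to_csv(ROOT / "components.csv", index=False)
    print(f"wrote variance components for {len(rows)} traits")


if __name__ == "__main__":
    main()
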