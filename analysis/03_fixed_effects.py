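"""Fixed-effects least squares per trait: LSmeans, Tukey letters, adjustment.

Fits y = mu + farm + birth_season + sex + dam_age + birth_weight_class
to each standardized trait on farms with at least four usable records,
prints the significant environmental effects, and writes

* results/lsmeans.csv             level means +- SE with Tukey letters,
* results/anova.csv               partial-SS F tests per trait,
* results/adjusted.csv            phenotypes minus significant effects.
"""

from pathlib import Path

import pandas as pd

from bubalus import linmod

ROOT = Path(__file__).resolve().parents[1] / "results"
FACTORS = ("farm", "birth_season", "sex", "dam_age_class",
           "birth_weight_class")


def main() -> None:
    std = pd.read_csv(ROOT / "standardized.csv", index_col=0)
    raw = pd.read_csv(ROOT / "synthetic_herd" / "measurements.csv")
    info = raw[["animal", *FACTORS]].drop_duplicates("animal").set_index(
        "animal"
    )
    pheno = info.join(std)
    traits = [c for c in std.columns]
    lsm_rows, anova_rows, adjusted = [], [], {}
    for t in traits:
        data = linmod.filter_farms(pheno.reset_index(), 4, trait=t)
        fit = linmod.fit_fixed_model(
            data, linmod.FixedModelSpec(t, FACTORS)
        )
        sig = fit.significant_factors()
        print(f"{t}: n={len(fit.data)}, mu={fit.mu:.2f}, "
              f"significant: {', '.join(sig) if sig else 'none'}")
        for f in FACTORS:
            anova_rows.append(
                {"trait": t, "factor": f, **fit.anova.loc[f].to_dict()}
            )
            if f == "farm":
                continue  # 36 farm levels: kept out of the lsmeans table
            groups = linmod.tukey_groups(fit, f)
            for level, g in groups.iterrows():
                lsm_rows.append({
                    "trait": t, "factor": f, "level": level,
                    "n": int(g["n"]), "lsmean": round(g["estimate"], 3),
                    "se": round(g["se"], 3), "letters": g["letters"],
                })
        adj = linmod.adjust_phenotypes(fit)
        adjusted[t] = pd.Series(
            adj.to_numpy(), index=data.loc[adj.index, "animal"]
        )
    pd.DataFrame(lsm_rows).to_csv(ROOT / "lsmeans.csv", index=False)
    pd.DataFrame(anova_rows).to_csv(ROOT / "anova.csv", index=False)
    pd.DataFrame(adjusted).to_csv(ROOT / "adjusted.csv")
    print(f"wrote lsmeans/anova/adjusted tables for {len(traits)} traits")


if __name__ == "__main__":
    main()
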