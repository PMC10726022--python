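"""Generate the synthetic study herd.

No raw data are deposited for this population ("available upon
reasonable request"), so every downstream analysis step runs on a
synthetic herd that carries the published structure: 313 calves across
36 farms, shallow calf-dam-sire pedigree, the published per-trait
variance components and genetic correlations, fixed-effect contrasts
matching the published least-square means, repeated measurements
bracketing 365 d of age, and candidate SNPs at the published skewed
allele frequencies.

Writes ped.csv, measurements.csv, geno.csv and truth.csv under
results/synthetic_herd/.
"""

from pathlib import Path

import pandas as pd

from bubalus import simdata

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_herd"


def main(seed: int = 20190201) -> None:
    herd = simdata.simulate_herd(seed=seed)
    OUT.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        herd.pedigree.entries, columns=["animal", "sire", "dam"]
    ).to_csv(OUT / "ped.csv", index=False)
    factors = ["farm", "birth_season", "sex", "dam_age_class",
               "birth_weight_class"]
    herd.measurements.merge(
        herd.phenotypes[factors], left_on="animal", right_index=True
    ).to_csv(OUT / "measurements.csv", index=False)
    herd.genotypes.to_csv(OUT / "geno.csv", index=False)
    herd.truth.to_csv(OUT / "truth.csv")
    n_calves = len(herd.phenotypes)
    n_farms = herd.phenotypes["farm"].nunique()
    print(f"synthetic herd: {n_calves} calves on {n_farms} farms, "
          f"{len(herd.pedigree)} pedigree entries, "
          f"{len(herd.measurements)} measurement rows -> {OUT}")


if __name__ == "__main__":
    main()
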