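"""Least-squares fixed-effects analysis of the herd data.

One trait at a time, the model is purely additive in categorical
factors — farm, birth season, sex, dam-age class and birth-weight
class::

    y = mu + farm_i + season_j + sex_k + damage_l + bwclass_m + e

Effects are sum-to-zero coded, so level "effects" are deviations from
the overall mean and least-square means are ``mu + effect``.  ANOVA uses
partial (adjusted) sums of squares; multiple comparisons use Tukey's
studentized-range test on the least-square means (Tukey–Kramer SEs in
unbalanced data), with compact letter display ordered highest mean
first.  Phenotypes are adjusted for the significant environmental
effects before correlation and SNP-association analyses.

The numerics behind the fit are ordinary least squares via statsmodels;
the design matrix, partial SS, least-square means, letter display and
adjustment are constructed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

__all__ = [
    "FixedModelSpec",
    "FixedFit",
    "SingularDesignError",
    "filter_farms",
    "fit_fixed_model",
    "ls_means",
    "tukey_groups",
    "adjust_phenotypes",
]


class SingularDesignError(ValueError):
    """Raised when the fixed-effects design is singular (aliased factors)."""


@dataclass(frozen=True)
class FixedModelSpec:
    """What to fit: the trait, the factors, and the farm-size filter."""

    response: str
    factors: tuple[str, ...]
    min_group_size: int = 4
    alpha: float = 0.05

    def __post_init__(self):
        if not self.factors:
            raise ValueError("at least one factor is required")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        object.__setattr__(self, "factors", tuple(self.factors))


def filter_farms(
    data: pd.DataFrame,
    min_group_size: int,
    trait: str | None = None,
    farm_col: str = "farm",
) -> pd.DataFrame:
    """Keep only farms with at least ``min_group_size`` usable records.

    When ``trait`` is given, a record counts only if that trait is
    non-missing, so a farm can be retained for one trait and dropped for
    another.  Dropped farm counts are reported via a warning; an empty
    result raises.
    """
    if farm_col not in data.columns:
        raise ValueError(f"no {farm_col!r} column in data")
    usable = data if trait is None else data[data[trait].notna()]
    sizes = usable.groupby(farm_col, sort=False).size()
    keep = set(sizes.index[sizes >= min_group_size])
    dropped = sizes.index.difference(keep)
    if len(dropped):
        warnings.warn(
            f"dropped {len(dropped)} farm(s) with fewer than {min_group_size} "
            f"records{f' for {trait}' if trait else ''}: "
            f"{sorted(map(str, dropped))[:10]}",
            stacklevel=2,
        )
    out = usable[usable[farm_col].isin(keep)]
    if out.empty:
        raise ValueError(
            f"no farm reaches {min_group_size} records"
            f"{f' for {trait}' if trait else ''}; lower the threshold"
        )
    return out


def _design(data: pd.DataFrame, factors) -> tuple[np.ndarray, list, dict]:
    """Sum-to-zero coded design matrix with an intercept.

    Returns the matrix, a column labelling ``[("mu", None), (factor,
    level), ...]`` (one column per non-reference level; the last level
    of each factor is the implicit ``-sum`` reference), and the observed
    level ordering per factor.
    """
    n = len(data)
    cols = [np.ones(n)]
    labels: list[tuple[str, str | None]] = [("mu", None)]
    levels: dict[str, list] = {}
    for f in factors:
        lv = sorted(data[f].astype(str).unique())
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 observed levels")
        levels[f] = lv
        codes = data[f].astype(str)
        last = codes == lv[-1]
        for level in lv[:-1]:
            col = (codes == level).astype(float) - last.astype(float)
            cols.append(col.to_numpy())
            labels.append((f, level))
    return np.column_stack(cols), labels, levels


@dataclass
class FixedFit:
    """A fitted additive fixed-effects model.

    ``effects[factor][level]`` are sum-to-zero deviations (the implicit
    last level equals minus the sum of the others); ``anova`` holds the
    partial-SS F tests; ``cov_params`` is the coefficient covariance in
    the column order of ``labels``.
    """

    spec: FixedModelSpec
    data: pd.DataFrame
    mu: float
    effects: dict[str, dict[str, float]]
    anova: pd.DataFrame
    params: np.ndarray
    cov_params: np.ndarray
    labels: list
    levels: dict[str, list]
    residuals: pd.Series
    fitted: pd.Series
    df_resid: int
    mse: float
    _col_of: dict = field(init=False, repr=False)

    def __post_init__(self):
        self._col_of = {lab: j for j, lab in enumerate(self.labels)}

    def effect_columns(self, factor: str) -> list[int]:
        return [j for j, (f, _) in enumerate(self.labels) if f == factor]

    def lsmean_contrast(self, factor: str, level: str) -> np.ndarray:
        """Contrast row c such that c'beta is the least-square mean."""
        c = np.zeros(len(self.labels))
        c[0] = 1.0
        if level == self.levels[factor][-1]:
            for j in self.effect_columns(factor):
                c[j] = -1.0
        else:
            c[self._col_of[(factor, level)]] = 1.0
        return c

    def significant_factors(self, alpha: float | None = None) -> list[str]:
        alpha = self.spec.alpha if alpha is None else alpha
        pv = self.anova["p"]
        return [f for f in self.spec.factors if pd.notna(pv[f]) and pv[f] < alpha]


def fit_fixed_model(data: pd.DataFrame, spec: FixedModelSpec) -> FixedFit:
    """Fit the additive fixed-effects model by least squares.

    Records with a missing response or missing factor level are dropped.
    The ANOVA reports partial (adjusted) sums of squares: for each
    factor, the increase in residual SS when its columns are removed
    from the full model.  A rank-deficient design (confounded factors)
    raises :class:`SingularDesignError` naming the aliased factors.
    """
    used = data.dropna(subset=[spec.response, *spec.factors]).copy()
    if used.empty:
        raise ValueError("no complete records to fit")
    X, labels, levels = _design(used, spec.factors)
    y = used[spec.response].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = []
        for f in spec.factors:
            drop = [j for j, (g, _) in enumerate(labels) if g == f]
            Xr = np.delete(X, drop, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                aliased.append(f)
        raise SingularDesignError(
            "singular design: factor(s) "
            + ", ".join(aliased or ["<unidentified>"])
            + " are aliased with the remaining factors"
        )
    res = sm.OLS(y, X).fit()
    df_resid = int(res.df_resid)
    rss_full = float(res.ssr)
    mse = rss_full / df_resid if df_resid > 0 else np.nan
    if np.isfinite(mse) and mse < 1e-12 * max(float(np.var(y)), 1e-12):
        mse = 0.0  # numerically perfect fit: F undefined
    rows = []
    for f in spec.factors:
        drop = [j for j, (g, _) in enumerate(labels) if g == f]
        Xr = np.delete(X, drop, axis=1)
        rss_red = float(sm.OLS(y, Xr).fit().ssr)
        ss = max(rss_red - rss_full, 0.0)
        dff = len(drop)
        if not np.isfinite(mse) or mse <= 0:
            warnings.warn(
                f"zero residual variance: F for {f!r} undefined", stacklevel=2
            )
            F = p = np.nan
        else:
            F = (ss / dff) / mse
            from scipy.stats import f as f_dist

            p = float(f_dist.sf(F, dff, df_resid))
        rows.append({"factor": f, "df": dff, "sum_sq": ss, "F": F, "p": p})
    anova = pd.DataFrame(rows).set_index("factor")
    effects = {}
    for f in spec.factors:
        eff = {lev: float(res.params[j]) for j, (g, lev) in enumerate(labels) if g == f}
        eff[levels[f][-1]] = -sum(eff.values())
        effects[f] = eff
    return FixedFit(
        spec=spec,
        data=used,
        mu=float(res.params[0]),
        effects=effects,
        anova=anova,
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()),
        labels=labels,
        levels=levels,
        residuals=pd.Series(res.resid, index=used.index, name="resid"),
        fitted=pd.Series(res.fittedvalues, index=used.index, name="fitted"),
        df_resid=df_resid,
        mse=float(mse) if np.isfinite(mse) else np.nan,
    )


def ls_means(fit: FixedFit, factor: str) -> pd.DataFrame:
    """Least-square means ± SE per level of ``factor``.

    Each level's prediction is averaged over all levels of the other
    factors with equal weight; under sum-to-zero coding this is
    ``mu + effect`` with SE from the coefficient covariance.
    """
    if factor not in fit.spec.factors:
        raise KeyError(f"{factor!r} not in model")
    rows = []
    for level in fit.levels[factor]:
        c = fit.lsmean_contrast(factor, level)
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params @ c))
        n_level = int((fit.data[factor].astype(str) == level).sum())
        rows.append({"level": level, "n": n_level, "estimate": est, "se": se})
    return pd.DataFrame(rows).set_index("level")


def tukey_groups(fit: FixedFit, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey(-Kramer) HSD letter groupings of the least-square means.

    Pairwise studentized-range statistics use the SE of each lsmean
    difference from the coefficient covariance.  Levels sharing a letter
    do not differ at ``alpha``; "a" marks the highest mean, matching the
    superscripts of herd-book style tables.
    """
    if not np.isfinite(fit.mse) or fit.mse <= 0:
        raise ValueError("MS_error is zero; Tukey comparisons undefined")
    lsm = ls_means(fit, factor)
    lv = list(lsm.index)
    k = len(lv)
    C = np.array([fit.lsmean_contrast(factor, level) for level in lv])
    cov = C @ fit.cov_params @ C.T
    m = lsm["estimate"].to_numpy()
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sed = np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
            q = abs(m[i] - m[j]) * np.sqrt(2.0) / sed
            pmat[i, j] = pmat[j, i] = float(
                studentized_range.sf(q, k, fit.df_resid)
            )
    # compact letter display: letters = maximal cliques of the
    # "not significantly different" graph, lettered highest-mean first
    g = nx.Graph()
    g.add_nodes_from(range(k))
    g.add_edges_from(
        (i, j) for i in range(k) for j in range(i + 1, k) if pmat[i, j] >= alpha
    )
    cliques = sorted(nx.find_cliques(g), key=lambda c: -max(m[i] for i in c))
    letters = {i: "" for i in range(k)}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[i] += letter
    out = lsm.copy()
    out["letters"] = ["".join(sorted(letters[i])) for i in range(k)]
    return out.sort_values("estimate", ascending=False)


def adjust_phenotypes(
    fit: FixedFit,
    keep: set[str] | None = None,
    adjust_all: bool = False,
    alpha: float | None = None,
) -> pd.Series:
    """Phenotypes adjusted for (significant) environmental effects.

    Each record loses the sum of its estimated fixed effects for the
    factors being removed — by default only those significant at
    ``alpha`` in the partial-SS ANOVA; ``adjust_all=True`` removes every
    fitted factor.  ``keep`` names factors never removed (e.g. sex when
    a sex-specific analysis follows).  The result is recentred so the
    grand mean of the adjusted data equals the raw mean.
    """
    remove = (
        list(fit.spec.factors) if adjust_all else fit.significant_factors(alpha)
    )
    if keep:
        remove = [f for f in remove if f not in keep]
    y = fit.data[fit.spec.response].astype(float)
    correction = np.zeros(len(fit.data))
    for f in remove:
        eff = fit.effects[f]
        correction += fit.data[f].astype(str).map(eff).to_numpy()
    adjusted = y - correction
    adjusted += y.mean() - adjusted.mean()  # preserve the grand mean
    adjusted.name = f"{fit.spec.response}_adj"
    return adjusted
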