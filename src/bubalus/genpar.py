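"""Genetic parameters: heritabilities, correlations and selection responses.

From the REML variance components of each trait:

* direct heritability            h2_a = sa2 / sp2
* maternal heritability          h2_m = sm2 / sp2
* total heritability (Willham,   h2_T = (sa2 + 0.5 sm2) / sp2
  with Cov(a, m) = 0)

with standard errors by the delta method when the component covariance
is available.

Genetic correlations between traits are approximated as the Pearson
correlation of the two traits' estimated breeding values over the common
animals (the Calo approach); phenotypic correlations are Pearson
correlations of the fixed-effect-adjusted records.  Significance of
either uses the t test for a correlation coefficient at the common
sample size.

Expected selection responses at selection intensity ``i``:

* direct response    dG   = i * h2 * sigma_P          (trait units/generation)
* relative correlated response of trait ``i`` under selection on ``j``:
  CR_i = rG(i, j) * h_j / h_i                          (dimensionless),

``h`` denoting the square root of the direct heritability.  The response
matrix puts direct responses on the diagonal (row = trait selected on,
column = responding trait).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import VarianceComponents

__all__ = [
    "Heritabilities",
    "CorrelationResult",
    "CorrelationMatrices",
    "heritabilities",
    "genetic_correlation_ebv",
    "phenotypic_correlation",
    "correlation_matrices",
    "direct_response",
    "correlated_response",
    "response_matrix",
]


@dataclass(frozen=True)
class Heritabilities:
    """Direct, maternal and total heritability with delta-method SEs."""

    h2_direct: float
    h2_maternal: float
    h2_total: float
    se_direct: float = np.nan
    se_maternal: float = np.nan
    se_total: float = np.nan


def _delta_se(grad: np.ndarray, cov: np.ndarray | None) -> float:
    if cov is None:
        return float("nan")
    return float(np.sqrt(max(grad @ cov @ grad, 0.0)))


def heritabilities(vc: VarianceComponents) -> Heritabilities:
    """Heritabilities from one trait's variance components.

    The total heritability uses Willham's expression
    ``(sa2 + 0.5 sm2)/sp2``, the form appropriate when the
    additive-maternal covariance is constrained to zero.
    """
    sa, sm, se_ = vc.sigma2_a, vc.sigma2_m, vc.sigma2_e
    sp = sa + sm + se_
    if sp <= 0:
        raise ValueError("non-positive phenotypic variance")
    h2a = sa / sp
    h2m = sm / sp
    h2t = (sa + 0.5 * sm) / sp
    # delta method: gradients of each ratio wrt (sa2, sm2, se2)
    g_a = np.array([(sp - sa), -sa, -sa]) / sp**2
    g_m = np.array([-sm, (sp - sm), -sm]) / sp**2
    g_t = np.array(
        [sp - (sa + 0.5 * sm), 0.5 * sp - (sa + 0.5 * sm), -(sa + 0.5 * sm)]
    ) / sp**2
    cov = vc.cov
    return Heritabilities(
        h2a, h2m, h2t, _delta_se(g_a, cov), _delta_se(g_m, cov), _delta_se(g_t, cov)
    )


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with its two-sided p-value and sample size."""

    r: float
    p: float
    n: int
    defined: bool = True

    @property
    def stars(self) -> str:
        if not self.defined or np.isnan(self.p):
            return ""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=3)
        return CorrelationResult(np.nan, np.nan, n, defined=False)
    r, p = stats.pearsonr(x, y)
    clipped = float(np.clip(r, -1.0, 1.0))
    if clipped != r:
        warnings.warn("correlation clamped to [-1, 1]", stacklevel=3)
    return CorrelationResult(clipped, float(p), n)


def genetic_correlation_ebv(ebv_x: pd.Series, ebv_y: pd.Series) -> CorrelationResult:
    """Calo-style genetic correlation: Pearson r of paired EBVs.

    The covariance of the two traits' EBVs over the common animals is
    scaled by the geometric mean of the EBV variances, i.e. the ordinary
    Pearson correlation — the only scaling that keeps the estimate in
    [-1, 1].  Traits with a zero-variance EBV vector (a boundary
    heritability) yield an undefined, flagged result.
    """
    common = ebv_x.dropna().index.intersection(ebv_y.dropna().index)
    if len(common) < 3:
        raise ValueError("need at least 3 animals with EBVs for both traits")
    return _pearson(
        ebv_x.loc[common].to_numpy(dtype=float),
        ebv_y.loc[common].to_numpy(dtype=float),
    )


def phenotypic_correlation(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson correlation of adjusted phenotypes, pairwise complete."""
    df = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete pairs")
    return _pearson(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )


@dataclass(frozen=True)
class CorrelationMatrices:
    """Genetic (upper) and phenotypic (lower) correlations with p-values."""

    traits: tuple[str, ...]
    genetic: pd.DataFrame
    phenotypic: pd.DataFrame
    genetic_p: pd.DataFrame
    phenotypic_p: pd.DataFrame

    def combined(self) -> pd.DataFrame:
        """One matrix: genetic above the diagonal, phenotypic below."""
        out = pd.DataFrame(
            np.nan, index=list(self.traits), columns=list(self.traits)
        )
        for i, t in enumerate(self.traits):
            for j, u in enumerate(self.traits):
                if i < j:
                    out.loc[t, u] = self.genetic.loc[t, u]
                elif i > j:
                    out.loc[t, u] = self.phenotypic.loc[t, u]
        return out


def correlation_matrices(
    ebvs: dict[str, pd.Series], adjusted: pd.DataFrame
) -> CorrelationMatrices:
    """All pairwise genetic (EBV) and phenotypic (adjusted) correlations."""
    traits = tuple(ebvs)
    k = len(traits)
    rg = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    rp = rg.copy()
    pg = pd.DataFrame(np.nan, index=traits, columns=traits)
    pp = pg.copy()
    for i, t in enumerate(traits):
        for u in traits[i + 1 :]:
            g = genetic_correlation_ebv(ebvs[t], ebvs[u])
            rg.loc[t, u] = rg.loc[u, t] = g.r
            pg.loc[t, u] = pg.loc[u, t] = g.p
            ph = phenotypic_correlation(adjusted[t], adjusted[u])
            rp.loc[t, u] = rp.loc[u, t] = ph.r
            pp.loc[t, u] = pp.loc[u, t] = ph.p
    return CorrelationMatrices(traits, rg, rp, pg, pp)


def direct_response(h2: float, sigma2_p: float, intensity: float = 1.0) -> float:
    """Expected genetic gain per generation: i * h2 * sigma_P."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    if sigma2_p < 0:
        raise ValueError("sigma2_p must be non-negative")
    return intensity * h2 * float(np.sqrt(sigma2_p))


def correlated_response(
    rG: float, h2_selected: float, h2_correlated: float
) -> float:
    """Relative correlated response rG * h_selected / h_correlated.

    ``h2_selected`` belongs to the (auxiliary) trait selection acts on,
    ``h2_correlated`` to the trait whose response is expressed relative
    to direct selection on it.  A zero ``h2_correlated`` makes the ratio
    infinite and raises (near-boundary heritabilities such as a ~1e-4
    estimate already yield very large, fragile ratios).
    """
    if not -1.0 <= rG <= 1.0:
        raise ValueError("rG must lie in [-1, 1]")
    if h2_correlated <= 0:
        raise ValueError(
            "h2 of the responding trait is zero: the relative correlated "
            "response is unbounded (boundary heritability)"
        )
    if h2_selected < 0:
        raise ValueError("h2_selected must be non-negative")
    return rG * float(np.sqrt(h2_selected / h2_correlated))


def response_matrix(
    h2s: dict[str, float],
    sigma2_ps: dict[str, float],
    rG: pd.DataFrame,
    intensity: float = 1.0,
) -> pd.DataFrame:
    """Direct (diagonal) and relative correlated responses (off-diagonal).

    Rows index the trait selected on (the auxiliary trait); columns the
    responding trait.  Cell [j, i] with j != i is
    ``correlated_response(rG[i, j], h2s[j], h2s[i])``; cell [j, j] is
    ``direct_response(h2s[j], sigma2_ps[j], intensity)``.
    """
    traits = list(h2s)
    out = pd.DataFrame(np.nan, index=traits, columns=traits)
    for j in traits:  # selected / auxiliary trait (row)
        for i in traits:  # responding trait (column)
            if i == j:
                out.loc[j, i] = direct_response(h2s[j], sigma2_ps[j], intensity)
            else:
                out.loc[j, i] = correlated_response(
                    float(rG.loc[i, j]), h2s[j], h2s[i]
                )
    return out
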