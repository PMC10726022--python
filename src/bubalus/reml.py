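"""Univariate animal model: EM-REML variance components and BLUP breeding values.

The model is

    y = X b + Z_a a + Z_m m + e,
    a ~ N(0, A sa2),  m ~ N(0, A sm2),  e ~ N(0, I se2),  Cov(a, m) = 0,

with A the numerator relationship matrix, ``a`` each animal's direct
additive merit and ``m`` the dam-linked maternal genetic effect.

Variance components are estimated by EM-REML.  The restricted likelihood
depends on the data only through the phenotypic covariance

    V = sa2 * A_rr + sm2 * Z_d A_dd Z_d' + se2 * I,

where A_rr is A among recorded animals and A_dd among dams: carrying
unrecorded relatives as explicit random-effect levels or marginalising
them leaves the likelihood unchanged, so the EM iteration here works on
the record-level (marginalised) form.  Each sweep applies the classical
updates

    s_u2 <- s_u2 + (s_u2^2 / q_u) * (y'P G_u P y - tr(P G_u)),

(G_u the covariance structure of effect u, q_u its number of levels,
P the REML projection matrix), which never decrease the restricted
log-likelihood and keep every component non-negative.  An optional
Aitken-extrapolated step is attempted periodically and accepted only if
the restricted log-likelihood does not decrease.

Breeding values are predicted from Henderson's mixed-model equations
built on the full pedigree, so animals without records receive EBVs
through their relatives; prediction-error variances come from the
inverse coefficient matrix.  Standard errors of the components use the
average-information matrix at the optimum; heritability standard errors
follow by the delta method (see :mod:`bubalus.genpar`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotrf, dpotri

from .linmod import _design
from .pedigree import Pedigree, RelationshipMatrix, relationship_matrix

__all__ = [
    "AnimalModelSpec",
    "VarianceComponents",
    "MMESystem",
    "NonIdentifiableWarning",
    "em_reml",
    "build_mme",
    "solve_mme",
    "blup_ebv",
    "reml_se",
    "se_from_information",
    "restricted_loglik",
]


class NonIdentifiableWarning(UserWarning):
    """Variance split not identifiable from the supplied design/pedigree."""


@dataclass(frozen=True)
class AnimalModelSpec:
    """The trait, its fixed factors, the pedigree, and the maternal switch.

    ``dam_link`` maps a record's animal to the dam carrying the maternal
    effect; by default dams are taken from the pedigree.  Records whose
    dam is unknown get a private dummy founder dam (logged), so Z_m is
    always well defined.
    """

    trait: str
    pedigree: Pedigree
    fixed_factors: tuple[str, ...] = ()
    include_maternal: bool = True
    dam_link: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "fixed_factors", tuple(self.fixed_factors))


@dataclass
class VarianceComponents:
    """REML variance components for one trait (trait units squared).

    ``sigma2_p`` is the sum of the three components by construction.
    ``boundary`` flags components pinned at (effectively) zero, whose
    standard errors are reported as 0.  ``cov`` is the asymptotic
    covariance of (sigma2_a, sigma2_m, sigma2_e) from the inverse
    average-information matrix, with zero rows/columns for boundary or
    absent components.
    """

    sigma2_a: float
    sigma2_m: float
    sigma2_e: float
    sigma2_p: float = field(init=False)
    se_a: float = 0.0
    se_m: float = 0.0
    se_e: float = 0.0
    se_p: float = 0.0
    loglik: float = np.nan
    converged: bool = False
    n_iterations: int = 0
    include_maternal: bool = True
    boundary: dict = field(default_factory=dict)
    cov: np.ndarray | None = None
    loglik_history: list = field(default_factory=list)

    def __post_init__(self):
        self.sigma2_p = self.sigma2_a + self.sigma2_m + self.sigma2_e

    def as_dict(self) -> dict:
        return {
            "sigma2_a": self.sigma2_a,
            "sigma2_m": self.sigma2_m,
            "sigma2_e": self.sigma2_e,
            "sigma2_p": self.sigma2_p,
            "se_a": self.se_a,
            "se_m": self.se_m,
            "se_e": self.se_e,
            "se_p": self.se_p,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "boundary": dict(self.boundary),
        }


def se_from_information(info: np.ndarray) -> np.ndarray:
    """Standard errors from an information matrix: sqrt(diag(I^-1))."""
    return np.sqrt(np.diag(np.linalg.inv(np.asarray(info, dtype=float))))


# ---------------------------------------------------------------------------
# internal assembly


class _ModelData:
    """Record-level arrays shared by the EM iteration and the MME."""

    def __init__(self, data: pd.DataFrame, spec: AnimalModelSpec):
        used = data.dropna(subset=[spec.trait, *spec.fixed_factors]).copy()
        if used.empty:
            raise ValueError("no usable records")
        ped = spec.pedigree
        known = set(ped.ids)
        missing = [a for a in used["animal"].astype(str) if a not in known]
        if missing:
            raise ValueError(
                f"records for animals absent from the pedigree: {sorted(set(missing))[:5]}"
            )
        self.spec = spec
        self.data = used
        self.y = used[spec.trait].to_numpy(dtype=float)
        self.n = len(used)
        if spec.fixed_factors:
            self.X, self.labels, self.levels = _design(used, spec.fixed_factors)
        else:
            self.X = np.ones((self.n, 1))
            self.labels, self.levels = [("mu", None)], {}
        self.p = np.linalg.matrix_rank(self.X)
        if self.p < self.X.shape[1]:
            raise ValueError("fixed-effects design is rank deficient")
        self.A = relationship_matrix(ped)
        self.rec_animals = used["animal"].astype(str).tolist()

        # dams: from dam_link or pedigree; unknown -> private dummy founder
        self.dams: list[str] | None = None
        if spec.include_maternal:
            link = spec.dam_link or {}
            ped_dams = {a: d for a, _, d in ped.entries}
            dams = []
            n_dummy = 0
            for a in self.rec_animals:
                d = link.get(a, ped_dams.get(a))
                if d is None:
                    d = f"__dummy_dam_{a}"
                    n_dummy += 1
                dams.append(str(d))
            if n_dummy:
                warnings.warn(
                    f"{n_dummy} record(s) with unknown dam: dummy founder dams added",
                    stacklevel=3,
                )
            self.dams = dams

    # -- marginal (record-level) covariance structures ---------------------

    def _sub_A(self, ids: list[str]) -> np.ndarray:
        """A among ``ids``; ids outside the pedigree are unrelated founders."""
        idx = self.A.index
        known = [a for a in dict.fromkeys(ids) if a in idx]
        G = np.eye(len(dict.fromkeys(ids)))
        uniq = list(dict.fromkeys(ids))
        pos = {a: i for i, a in enumerate(uniq)}
        if known:
            sub = self.A.submatrix(known)
            kpos = [pos[a] for a in known]
            G[np.ix_(kpos, kpos)] = sub
        return G, uniq, pos

    def marginal_structures(self):
        """(G_list, q_list, names): record-level covariance structures."""
        Ga, uniq_a, pos_a = self._sub_A(self.rec_animals)
        Za = np.zeros((self.n, len(uniq_a)))
        Za[np.arange(self.n), [pos_a[a] for a in self.rec_animals]] = 1.0
        Ma = Za @ Ga @ Za.T
        structures = [("a", Ma, len(uniq_a))]
        if self.dams is not None:
            Gm, uniq_m, pos_m = self._sub_A(self.dams)
            Zm = np.zeros((self.n, len(uniq_m)))
            Zm[np.arange(self.n), [pos_m[d] for d in self.dams]] = 1.0
            structures.append(("m", Zm @ Gm @ Zm.T, len(uniq_m)))
        return structures


def _pos_inv(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric positive-definite matrix."""
    c, info = dpotrf(V, lower=0, overwrite_a=0)
    if info != 0:
        raise np.linalg.LinAlgError("covariance matrix not positive definite")
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    inv, info = dpotri(c, lower=0)
    if info != 0:
        raise np.linalg.LinAlgError("inversion failed")
    inv = np.triu(inv) + np.triu(inv, 1).T
    return inv, logdet


class _EMEngine:
    """One-trait EM-REML on the marginalised covariance form."""

    def __init__(self, md: _ModelData):
        self.md = md
        self.structures = md.marginal_structures()
        self.names = [s[0] for s in self.structures] + ["e"]
        self.G = [s[1] for s in self.structures] + [np.eye(md.n)]
        self.q = [s[2] for s in self.structures] + [md.n - md.p]
        self.X, self.y, self.n, self.p = md.X, md.y, md.n, md.p
        if len(self.structures) == 1:
            offdiag = self.G[0] - np.diag(np.diag(self.G[0]))
            if not np.any(offdiag):
                warnings.warn(
                    "no pedigree links among recorded animals: additive and "
                    "residual variances are confounded (likelihood flat in the "
                    "split); expect a boundary or arbitrary partition",
                    NonIdentifiableWarning,
                    stacklevel=4,
                )
        elif np.allclose(self.G[1], np.eye(md.n)):
            warnings.warn(
                "every dam has a single record and dams are unrelated: the "
                "maternal structure equals the residual one, so sigma2_m and "
                "sigma2_e are confounded (their sum is identified, the split "
                "is not)",
                NonIdentifiableWarning,
                stacklevel=4,
            )

    def stats(self, theta: np.ndarray):
        """Restricted log-likelihood, EM-updated theta, and P y at theta."""
        V = sum(t * G for t, G in zip(theta, self.G))
        Vinv, logdetV = _pos_inv(V)
        K = Vinv @ self.X
        S = self.X.T @ K
        cS = cho_factor(S)
        logdetS = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
        Ky = self.X.T @ (Vinv @ self.y)
        beta = cho_solve(cS, Ky)
        Py = Vinv @ self.y - K @ beta
        yPy = float(self.y @ Py)
        loglik = -0.5 * (logdetV + logdetS + yPy)
        new = np.empty_like(theta)
        for i, G in enumerate(self.G):
            w = G @ Py
            quad = float(Py @ w)
            trPG = float(np.sum(Vinv * G)) - float(
                np.trace(cho_solve(cS, K.T @ (G @ K)))
            )
            qi = self.q[i] if self.names[i] != "e" else self.n
            new[i] = theta[i] + theta[i] ** 2 * (quad - trPG) / qi
        return loglik, new, Py, Vinv, (K, cS)

    def loglik_only(self, theta: np.ndarray) -> float:
        V = sum(t * G for t, G in zip(theta, self.G))
        Vinv, logdetV = _pos_inv(V)
        K = Vinv @ self.X
        S = self.X.T @ K
        cS = cho_factor(S)
        logdetS = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
        beta = cho_solve(cS, self.X.T @ (Vinv @ self.y))
        Py = Vinv @ self.y - K @ beta
        return -0.5 * (logdetV + logdetS + float(self.y @ Py))

    def average_information(self, theta: np.ndarray):
        """AI matrix AI_ij = 0.5 y'P G_i P G_j P y at theta."""
        _, _, Py, Vinv, (K, cS) = self.stats(theta)

        def apply_P(v):
            return Vinv @ v - K @ cho_solve(cS, K.T @ v)

        w = [G @ Py for G in self.G]
        Pw = [apply_P(wi) for wi in w]
        k = len(self.G)
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(w[i] @ Pw[j])
        return AI


def restricted_loglik(
    data: pd.DataFrame, spec: AnimalModelSpec, components
) -> float:
    """Restricted log-likelihood of the animal model at given components.

    ``components`` may be a :class:`VarianceComponents` or a sequence
    (sigma2_a[, sigma2_m], sigma2_e) matching the model's random effects.
    """
    md = _ModelData(data, spec)
    eng = _EMEngine(md)
    theta = _as_theta(components, spec.include_maternal)
    return eng.loglik_only(theta)


def _as_theta(components, include_maternal: bool) -> np.ndarray:
    if isinstance(components, VarianceComponents):
        vals = [components.sigma2_a]
        if include_maternal:
            vals.append(components.sigma2_m)
        vals.append(components.sigma2_e)
        return np.asarray(vals, dtype=float)
    return np.asarray(list(components), dtype=float)


def em_reml(
    data: pd.DataFrame,
    spec: AnimalModelSpec,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
    loglik_tol: float | None = None,
    accelerate: bool = False,
    accel_every: int = 4,
) -> VarianceComponents:
    """Estimate (sigma2_a[, sigma2_m], sigma2_e) by EM-REML.

    Starting values default to an equal split of the sample variance.
    Convergence requires the relative change of every component below
    ``tol`` and the restricted log-likelihood change below
    ``loglik_tol`` (default ``tol * 1e-2``, i.e. 1e-10 at the default
    tolerance); otherwise the last iterate is returned with
    ``converged=False``.  With ``accelerate=True`` an Aitken-extrapolated
    jump is attempted every ``accel_every`` sweeps and kept only when it
    does not lower the restricted log-likelihood, so the likelihood path
    stays monotone either way.
    """
    if loglik_tol is None:
        loglik_tol = tol * 1e-2
    md = _ModelData(data, spec)
    eng = _EMEngine(md)
    k = len(eng.G)
    vary = float(np.var(md.y, ddof=1)) or 1.0
    floor = 1e-12 * vary
    if start is not None:
        theta = np.maximum(_as_theta(start, spec.include_maternal), floor)
    else:
        theta = np.full(k, vary / k)
    history: list[float] = []
    converged = False
    it = 0

    def em_step(th):
        """One EM sweep: records the likelihood at ``th``, returns update."""
        loglik, new, *_ = eng.stats(th)
        if history and loglik < history[-1] - 1e-8 * (1.0 + abs(history[-1])):
            warnings.warn(
                f"restricted log-likelihood decreased "
                f"({history[-1]:.10g} -> {loglik:.10g})",
                stacklevel=3,
            )
        history.append(loglik)
        return np.maximum(new, floor)

    while it < max_iter and not converged:
        it += 1
        th1 = em_step(theta)
        rel = np.max(np.abs(th1 - theta) / np.maximum(np.abs(theta), floor))
        dll = (
            abs(history[-1] - history[-2]) if len(history) > 1 else np.inf
        )
        if rel < tol and dll < loglik_tol:
            theta = th1
            converged = True
            break
        if not accelerate or it % accel_every or it >= max_iter:
            theta = th1
            continue
        # squared-extrapolation (SQUAREM-type) cycle: a second EM sweep,
        # then an extrapolated candidate kept only if the restricted
        # log-likelihood does not drop
        it += 1
        th2 = em_step(th1)
        r = th1 - theta
        v = th2 - th1 - r
        nv = float(np.sqrt(v @ v))
        theta_next = th2
        if nv > 0:
            alpha = -float(np.sqrt(r @ r)) / nv
            alpha = min(alpha, -1.0)
            cand = np.maximum(theta - 2 * alpha * r + alpha**2 * v, floor)
            if np.all(np.isfinite(cand)):
                try:
                    ll_cand = eng.loglik_only(cand)
                except np.linalg.LinAlgError:
                    ll_cand = -np.inf
                if np.isfinite(ll_cand) and ll_cand >= history[-1]:
                    theta_next = cand
        theta = theta_next
    final_ll = eng.loglik_only(theta)
    history.append(final_ll)
    vc = _pack_components(theta, spec.include_maternal, vary)
    vc.loglik = final_ll
    vc.converged = converged
    vc.n_iterations = it
    vc.loglik_history = history
    _attach_se(vc, eng, theta, vary)
    return vc


def _pack_components(theta, include_maternal: bool, vary: float) -> VarianceComponents:
    if include_maternal:
        sa, sm, se = (float(t) for t in theta)
    else:
        sa, se = (float(t) for t in theta)
        sm = 0.0
    vc = VarianceComponents(sa, sm, se, include_maternal=include_maternal)
    tot = max(vc.sigma2_p, 1e-300)
    vc.boundary = {
        "sigma2_a": sa / tot < 1e-6,
        "sigma2_m": include_maternal and sm / tot < 1e-6,
        "sigma2_e": se / tot < 1e-6,
    }
    return vc


def _attach_se(vc: VarianceComponents, eng: _EMEngine, theta, vary: float) -> None:
    """Average-information SEs; boundary components get SE 0 and a flag."""
    names = eng.names  # subset order, e.g. ["a", "m", "e"]
    key = {"a": "sigma2_a", "m": "sigma2_m", "e": "sigma2_e"}
    free = [i for i, nm in enumerate(names) if not vc.boundary[key[nm]]]
    cov3 = np.zeros((3, 3))
    order3 = {"a": 0, "m": 1, "e": 2}
    if free:
        try:
            AI = eng.average_information(np.asarray(theta, dtype=float))
            AIf = AI[np.ix_(free, free)]
            covf = np.linalg.inv(AIf)
            for ii, i in enumerate(free):
                for jj, j in enumerate(free):
                    cov3[order3[names[i]], order3[names[j]]] = covf[ii, jj]
        except np.linalg.LinAlgError:
            warnings.warn("average-information matrix singular; SEs unavailable",
                          stacklevel=3)
    vc.cov = cov3
    vc.se_a = float(np.sqrt(max(cov3[0, 0], 0.0)))
    vc.se_m = float(np.sqrt(max(cov3[1, 1], 0.0)))
    vc.se_e = float(np.sqrt(max(cov3[2, 2], 0.0)))
    vc.se_p = float(np.sqrt(max(np.ones(3) @ cov3 @ np.ones(3), 0.0)))


# ---------------------------------------------------------------------------
# Henderson's mixed-model equations (full pedigree) and BLUP


@dataclass
class MMESystem:
    """Henderson's mixed-model equations at fixed variance components.

    ``coef`` is the coefficient matrix in the lambda form
    (X'X, X'Z_a, ...; Z_a'Z_a + A^-1 * se2/sa2, ...), ``rhs`` = W'y.
    ``slices`` locates the beta / a / m blocks; genetic blocks span every
    pedigree animal (record or not).
    """

    coef: np.ndarray
    rhs: np.ndarray
    slices: dict
    ids: tuple[str, ...]
    labels: list
    sigma2_e: float
    spec: AnimalModelSpec


def build_mme(
    data: pd.DataFrame, spec: AnimalModelSpec, components
) -> MMESystem:
    """Assemble the mixed-model equations at the given variance components.

    Dams absent from the pedigree (including dummy dams for unknown
    mothers) are appended as unrelated founders so Z_m is well defined.
    A singular A receives a 1e-8 diagonal ridge before inversion.
    """
    theta = _as_theta(components, spec.include_maternal)
    if spec.include_maternal:
        sa2, sm2, se2 = theta
    else:
        (sa2, se2), sm2 = theta, 0.0
    if sa2 <= 0 and (not spec.include_maternal or sm2 <= 0):
        raise ValueError("both genetic variances are zero: nothing to predict")
    md = _ModelData(data, spec)
    ids = list(md.A.ids)
    extra = []
    if md.dams is not None:
        known = set(ids)
        extra = [d for d in dict.fromkeys(md.dams) if d not in known]
    all_ids = ids + extra
    q = len(all_ids)
    pos = {a: i for i, a in enumerate(all_ids)}
    A = np.eye(q)
    A[: len(ids), : len(ids)] = md.A.values
    try:
        Ainv, _ = _pos_inv(A)
    except np.linalg.LinAlgError:
        Ainv, _ = _pos_inv(A + 1e-8 * np.eye(q))
    n = md.n
    Za = np.zeros((n, q))
    Za[np.arange(n), [pos[a] for a in md.rec_animals]] = 1.0
    blocks = [md.X, Za]
    if spec.include_maternal:
        if sm2 <= 0:
            raise ValueError("include_maternal=True with sigma2_m = 0")
        Zm = np.zeros((n, q))
        Zm[np.arange(n), [pos[d] for d in md.dams]] = 1.0
        blocks.append(Zm)
    if sa2 <= 0:
        warnings.warn(
            "sigma2_a = 0: the animal model reduces to the fixed model",
            stacklevel=2,
        )
        sa2 = 1e-12 * float(np.var(md.y, ddof=1) or 1.0)
    W = np.hstack(blocks)
    M = W.T @ W
    p = md.X.shape[1]
    sl = {"beta": slice(0, p), "a": slice(p, p + q)}
    M[sl["a"], sl["a"]] += Ainv * (se2 / sa2)
    if spec.include_maternal:
        sl["m"] = slice(p + q, p + 2 * q)
        M[sl["m"], sl["m"]] += Ainv * (se2 / sm2)
    return MMESystem(
        coef=M,
        rhs=W.T @ md.y,
        slices=sl,
        ids=tuple(all_ids),
        labels=md.labels,
        sigma2_e=float(se2),
        spec=spec,
    )


def solve_mme(mme: MMESystem) -> np.ndarray:
    """Solution vector (beta, a[, m]) of the mixed-model equations."""
    return np.linalg.solve(mme.coef, mme.rhs)


def blup_ebv(
    data: pd.DataFrame, spec: AnimalModelSpec, components
) -> pd.DataFrame:
    """BLUP breeding values per pedigree animal at the given components.

    Returns a frame indexed by animal with ``ebv_direct``,
    ``ebv_maternal`` (zero-width when the model has no maternal effect)
    and prediction-error variances from the diagonal of the inverse
    coefficient matrix times sigma2_e.
    """
    mme = build_mme(data, spec, components)
    Cinv = np.linalg.inv(mme.coef)
    sol = Cinv @ mme.rhs
    a = sol[mme.slices["a"]]
    pev_a = np.diag(Cinv)[mme.slices["a"]] * mme.sigma2_e
    out = pd.DataFrame(
        {"ebv_direct": a, "pev_direct": np.maximum(pev_a, 0.0)},
        index=pd.Index(mme.ids, name="animal"),
    )
    if "m" in mme.slices:
        out["ebv_maternal"] = sol[mme.slices["m"]]
        out["pev_maternal"] = np.maximum(
            np.diag(Cinv)[mme.slices["m"]] * mme.sigma2_e, 0.0
        )
    return out


def reml_se(
    data: pd.DataFrame, spec: AnimalModelSpec, vc: VarianceComponents
) -> VarianceComponents:
    """Recompute average-information standard errors at a given optimum."""
    md = _ModelData(data, spec)
    eng = _EMEngine(md)
    theta = _as_theta(vc, spec.include_maternal)
    _attach_se(vc, eng, theta, float(np.var(md.y, ddof=1) or 1.0))
    return vc
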