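"""Independent oracles the tests check the implementation against.

Everything here deliberately avoids the code paths under test:
relationships come from gene-dropping Monte Carlo, mixed-model solutions
from direct inversion of the phenotypic covariance V, the restricted
likelihood from its V-based definition, and least-squares fits from an
explicit design-matrix pseudoinverse.
"""

from __future__ import annotations

import numpy as np


def gene_drop_kinship(entries, n_rep, rng):
    """Monte-Carlo numerator relationships by gene dropping.

    ``entries`` are parents-first (animal, sire, dam) triples.  Each
    replicate drops two founder alleles through the pedigree; the
    relationship estimate is twice the identity-by-descent probability
    of two alleles drawn at random, one from each animal (for i = j, the
    diagonal 1 + F uses the IBD of the animal's own two alleles).
    Returns (A_hat, se) matrices.
    """
    ids = [e[0] for e in entries]
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    acc = np.zeros((n, n))
    acc2 = np.zeros((n, n))
    for _ in range(n_rep):
        alleles = np.empty((n, 2), dtype=np.int64)
        counter = 0
        for a, s, d in entries:
            i = pos[a]
            for slot, parent in enumerate((s, d)):
                if parent is None:
                    alleles[i, slot] = counter
                    counter += 1
                else:
                    alleles[i, slot] = alleles[pos[parent], rng.integers(2)]
        # P(IBD) between random alleles of i and j, averaged analytically
        # over the 4 allele pairs
        ibd = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                if i == j:
                    ibd[i, i] = 1.0 + (alleles[i, 0] == alleles[i, 1])
                else:
                    m = np.mean(
                        [alleles[i, x] == alleles[j, y] for x in (0, 1) for y in (0, 1)]
                    )
                    ibd[i, j] = ibd[j, i] = 2.0 * m
        acc += ibd
        acc2 += ibd**2
    mean = acc / n_rep
    var = acc2 / n_rep - mean**2
    return mean, np.sqrt(np.maximum(var, 0) / n_rep)


def build_v(A, rec_pos, sigma2_a, sigma2_e, dam_pos=None, sigma2_m=0.0):
    """Phenotypic covariance V from the full relationship matrix."""
    n = len(rec_pos)
    q = A.shape[0]
    Za = np.zeros((n, q))
    Za[np.arange(n), rec_pos] = 1.0
    V = sigma2_a * Za @ A @ Za.T + sigma2_e * np.eye(n)
    if dam_pos is not None and sigma2_m > 0:
        Zm = np.zeros((n, q))
        Zm[np.arange(n), dam_pos] = 1.0
        V += sigma2_m * Zm @ A @ Zm.T
    return V


def gls_blup(A, rec_pos, X, y, sigma2_a, sigma2_e, dam_pos=None, sigma2_m=0.0):
    """GLS fixed effects and BLUP via direct V inversion.

    Returns (beta, a_hat, m_hat) where the genetic solutions cover every
    animal in A: a_hat = sigma2_a * A Za' V^-1 (y - X beta).
    """
    n, q = len(rec_pos), A.shape[0]
    Za = np.zeros((n, q))
    Za[np.arange(n), rec_pos] = 1.0
    V = build_v(A, rec_pos, sigma2_a, sigma2_e, dam_pos, sigma2_m)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    a_hat = sigma2_a * A @ Za.T @ Vi @ resid
    m_hat = None
    if dam_pos is not None and sigma2_m > 0:
        Zm = np.zeros((n, q))
        Zm[np.arange(n), dam_pos] = 1.0
        m_hat = sigma2_m * A @ Zm.T @ Vi @ resid
    return beta, a_hat, m_hat


def reml_loglik_v(A, rec_pos, X, y, theta, dam_pos=None):
    """Restricted log-likelihood by direct V inversion.

    ``theta`` is (sigma2_a, sigma2_e) or (sigma2_a, sigma2_m, sigma2_e)
    depending on whether ``dam_pos`` is given.
    """
    if dam_pos is None:
        sa2, se2 = theta
        sm2 = 0.0
    else:
        sa2, sm2, se2 = theta
    V = build_v(A, rec_pos, sa2, se2, dam_pos, sm2)
    Vi = np.linalg.inv(V)
    S = X.T @ Vi @ X
    beta = np.linalg.solve(S, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(S)[1] + r @ Vi @ r
    )


def pinv_ols(X, y):
    """Least-squares coefficients by explicit pseudoinverse."""
    return np.linalg.pinv(X) @ y
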