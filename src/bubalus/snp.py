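"""Candidate-gene SNP summaries and genotype-effect ANOVA.

Genotypes are unordered biallelic calls (``"TC"`` and ``"CT"`` are the
same genotype).  Per locus the module reports genotype counts and
frequencies, allele frequencies, a monomorphism flag and — as a QC
extension beyond the core analysis — an exact Hardy–Weinberg
equilibrium test.  Genotype effects on fixed-effect-adjusted phenotypes
are tested by one-way ANOVA over the genotype classes, excluding classes
below a configurable size floor (default 2, the smallest class for which
the within-class variance exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeSummary",
    "GenotypeAnova",
    "genotype_summary",
    "genotype_anova",
    "hwe_exact_test",
]

_VALID_ALLELES = set("ACGT")


def _normalize_call(call) -> str | None:
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return None
    s = str(call).strip().upper()
    if s in {"", "NA", "NAN", "--", "./."}:
        return None
    alleles = sorted(s)
    if len(alleles) != 2 or not set(alleles) <= _VALID_ALLELES:
        raise ValueError(f"not a biallelic genotype call: {call!r}")
    return "".join(alleles)


@dataclass(frozen=True)
class GenotypeSummary:
    """Counts, frequencies and QC diagnostics for one SNP locus."""

    counts: dict[str, int]
    genotype_freqs: dict[str, float]
    allele_freqs: dict[str, float]
    n: int
    monomorphic: bool
    hwe_p: float


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy–Weinberg test p-value for a biallelic locus.

    Sums the probabilities of all heterozygote counts (given the allele
    counts) no more probable than the observed one.  QC diagnostic only.
    """
    n = n_het + n_hom1 + n_hom2
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n == 0 or n_rare == 0:
        return 1.0

    def log_prob(h: int) -> float:
        # P(het = h | n, n_rare), Levene-Haldane distribution
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return (
            math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            + h * math.log(2.0)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[n_het]
    p = sum(math.exp(lp) for lp in logs.values() if lp <= obs + 1e-12)
    return min(p, 1.0)


def genotype_summary(calls) -> GenotypeSummary:
    """Summarize a biallelic locus from per-animal genotype calls.

    Missing calls are ignored; more than two distinct alleles raise.
    The allele frequency is the usual count frequency
    ``p = (2 n_AA + n_Aa) / (2 n)``.
    """
    norm = [c for c in (_normalize_call(c) for c in calls) if c is not None]
    if not norm:
        raise ValueError("no genotype calls")
    counts = pd.Series(norm).value_counts().to_dict()
    alleles = sorted({a for g in counts for a in g})
    if len(alleles) > 2:
        raise ValueError(f"more than two alleles observed: {alleles}")
    n = sum(counts.values())
    allele_counts = {a: 0 for a in alleles}
    for g, c in counts.items():
        allele_counts[g[0]] += c
        allele_counts[g[1]] += c
    allele_freqs = {a: c / (2 * n) for a, c in allele_counts.items()}
    monomorphic = len(alleles) == 1
    if monomorphic:
        hwe_p = 1.0
    else:
        a1, a2 = alleles
        hwe_p = hwe_exact_test(
            counts.get(a1 + a2, 0), counts.get(a1 + a1, 0), counts.get(a2 + a2, 0)
        )
    return GenotypeSummary(
        counts=counts,
        genotype_freqs={g: c / n for g, c in counts.items()},
        allele_freqs=allele_freqs,
        n=n,
        monomorphic=monomorphic,
        hwe_p=hwe_p,
    )


@dataclass(frozen=True)
class GenotypeAnova:
    """One-way ANOVA of a trait over genotype classes."""

    groups: pd.DataFrame  # per genotype: n, mean, sd, included
    F: float
    p: float
    df_between: int
    df_within: int
    tested: bool
    note: str = ""


def genotype_anova(
    adjusted_trait: pd.Series, genotypes: pd.Series, min_class_size: int = 2
) -> GenotypeAnova:
    """Test a SNP's genotype effect on an adjusted trait by one-way ANOVA.

    Classes with fewer than ``min_class_size`` animals are reported in
    the group table but excluded from the F test (logged).  With fewer
    than two usable classes the test is skipped with an explanation —
    the situation of a monomorphic or near-monomorphic locus.
    """
    geno = genotypes.map(_normalize_call)
    df = pd.DataFrame({"y": adjusted_trait, "g": geno}).dropna()
    summary = (
        df.groupby("g")["y"].agg(n="size", mean="mean", sd="std").sort_index()
    )
    summary["included"] = summary["n"] >= min_class_size
    excluded = summary.index[~summary["included"]].tolist()
    if excluded:
        warnings.warn(
            f"genotype class(es) below n={min_class_size} excluded from the "
            f"F test: {excluded}",
            stacklevel=2,
        )
    usable = summary.index[summary["included"]]
    if len(usable) < 2:
        return GenotypeAnova(
            groups=summary,
            F=np.nan,
            p=np.nan,
            df_between=0,
            df_within=0,
            tested=False,
            note="fewer than two usable genotype classes (monomorphic or "
            "classes below the size floor); test skipped",
        )
    samples = [df.loc[df["g"] == g, "y"].to_numpy(dtype=float) for g in usable]
    F, p = stats.f_oneway(*samples)
    n_used = sum(len(s) for s in samples)
    return GenotypeAnova(
        groups=summary,
        F=float(F),
        p=float(p),
        df_between=len(usable) - 1,
        df_within=n_used - len(usable),
        tested=True,
    )
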