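"""Imputation accuracy criteria and factor-importance statistics.

Two per-locus criteria score imputation against the simulated truth:

* reliability ``r2`` -- the squared Pearson correlation between the imputed
  and true 0/1/2 genotype vectors at a locus (undefined when either vector
  is monomorphic; such loci are excluded from averages);
* allelic error rate ``er%`` -- the percentage of imputed alleles that
  differ from the truth, using ``|g_imp - g_true|`` as the minimal unphased
  allele-mismatch count per genotype.

Factor influence is summarized by the coefficient of variation of the
factor-level marginal means (population standard deviation over mean) and by
ordinary least-squares regression of accuracy on factor level.  Population
relatedness is measured by a VanRaden-style genomic relationship matrix
halved to the kinship scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccuracyRecord",
    "AccuracyError",
    "DEFAULT_MAF_EDGES",
    "reliability",
    "error_rate",
    "maf_bin",
    "per_locus_accuracy",
    "marginal_mean",
    "coefficient_of_variation",
    "factor_regression",
    "kinship",
    "kinship_block_means",
]

DEFAULT_MAF_EDGES = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


class AccuracyError(ValueError):
    pass


@dataclass(frozen=True)
class AccuracyRecord:
    """Per-locus accuracy: MAF, reliability (NaN when undefined), error %."""

    locus: int
    maf: float
    r2: float
    error_rate: float


def reliability(imputed, truth) -> float:
    """Squared Pearson correlation between imputed and true 0/1/2 genotypes.

    Population (divide-by-n) moments; returns NaN when either vector is
    constant (the correlation is undefined for mono-allelic loci, which are
    excluded from averages downstream).
    """
    x = np.asarray(imputed, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise AccuracyError("imputed and true vectors differ in length")
    if x.ndim != 1 or len(x) < 2:
        raise AccuracyError("need vectors of length >= 2")
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return math.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def error_rate(imputed, truth) -> float:
    """Allelic imputation error, in percent.

    ``sum(|g_imp - g_true|) / (2 * n_entries) * 100``: each diploid genotype
    contributes its minimal unphased allele-mismatch count out of two alleles.
    """
    x = np.asarray(imputed)
    y = np.asarray(truth)
    if x.shape != y.shape:
        raise AccuracyError("imputed and true genotypes differ in shape")
    if x.size == 0:
        raise AccuracyError("no genotypes to score")
    bad = np.abs(x.astype(np.int64) - y.astype(np.int64)).sum()
    return float(bad) / (2 * x.size) * 100.0


def maf_bin(maf: float, edges=DEFAULT_MAF_EDGES) -> str:
    """Half-open MAF bin label ``[e_k, e_{k+1})``; the right edge 0.5 is included.

    Values below the first edge fall in an underflow bin ``[0, e_0)``.
    """
    if not (0 <= maf <= 0.5):
        raise AccuracyError(f"MAF {maf} outside [0, 0.5]")
    e = list(edges)
    if maf < e[0]:
        return f"[0,{e[0]})"
    for lo, hi in zip(e[:-2], e[1:-1]):
        if lo <= maf < hi:
            return f"[{lo},{hi})"
    return f"[{e[-2]},{e[-1]}]"


def per_locus_accuracy(
    imputed: np.ndarray,
    truth: np.ndarray,
    maf: np.ndarray,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score every hidden locus; rows are loci, columns maf / r2 / error_rate.

    ``imputed`` and ``truth`` are (individuals x loci) 0/1/2 matrices; r2 is
    NaN at loci where either vector is constant.
    """
    x = np.asarray(imputed, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise AccuracyError("imputed and true genotype matrices differ in shape")
    n, H = x.shape
    vx = x.var(axis=0)
    vy = y.var(axis=0)
    cov = ((x - x.mean(axis=0)) * (y - y.mean(axis=0))).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((vx > 0) & (vy > 0), cov * cov / (vx * vy), np.nan)
    err = np.abs(x - y).sum(axis=0) / (2 * n) * 100.0
    return pd.DataFrame(
        {
            "locus": np.arange(H),
            "position": positions if positions is not None else np.arange(H),
            "maf": np.asarray(maf, dtype=float),
            "r2": r2,
            "error_rate": err,
        }
    )


def marginal_mean(results: pd.DataFrame, factor: str, level, value: str) -> float:
    """Mean of ``value`` over all cells at ``factor == level``.

    The unweighted average across the levels of every other factor, matching
    how factor-level accuracies are summarized from the scenario grid.
    """
    if factor not in results.columns:
        raise AccuracyError(f"unknown factor {factor!r}")
    cells = results.loc[results[factor] == level, value]
    if cells.empty:
        raise AccuracyError(f"no cells at {factor} == {level!r}")
    return float(cells.mean())


def coefficient_of_variation(level_means) -> float:
    """Population standard deviation of the level means over their mean."""
    v = np.asarray(level_means, dtype=float)
    if len(v) < 2:
        raise AccuracyError("need at least two level means")
    m = v.mean()
    if m == 0.0:
        raise AccuracyError("mean of level means is zero; CV undefined")
    return float(v.std(ddof=0) / m)


def factor_regression(levels, accuracy) -> dict:
    """OLS of accuracy on factor level: slope, p-value, standardized slope.

    The standardized slope equals the Pearson correlation in simple
    regression; the p-value is the two-sided slope t-test.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(accuracy, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise AccuracyError("need >= 3 paired observations")
    if np.all(x == x[0]):
        raise AccuracyError("constant predictor; regression undefined")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "p_value": float(fit.pvalue),
        "standardized_slope": float(fit.rvalue),
    }


def kinship(genotypes: np.ndarray, allele_freqs: np.ndarray | None = None) -> np.ndarray:
    """Pairwise kinship matrix from 0/1/2 genotypes (VanRaden GRM / 2).

    ``k(i,j) = sum_l (x_il - 2 p_l)(x_jl - 2 p_l) / (2 sum_l 2 p_l (1-p_l))``
    with ``p_l`` the alternate-allele frequency (estimated from the input
    when not supplied).  Monomorphic loci contribute nothing; an input with
    no polymorphic locus is an error.
    """
    x = np.asarray(genotypes, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise AccuracyError("need a (>=2 individuals) x loci genotype matrix")
    p = x.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    denom = 2.0 * np.sum(2.0 * p * (1.0 - p))
    if denom <= 0.0:
        raise AccuracyError("all loci monomorphic; kinship undefined")
    z = x - 2.0 * p
    return (z @ z.T) / denom


def kinship_block_means(kin: np.ndarray, populations) -> pd.DataFrame:
    """Mean/min/max kinship per unordered population pair (diagonal excluded)."""
    pops = np.asarray(populations)
    uniq = list(dict.fromkeys(pops))
    rows = []
    for a_i, a in enumerate(uniq):
        for b in uniq[a_i:]:
            ia = np.flatnonzero(pops == a)
            ib = np.flatnonzero(pops == b)
            block = kin[np.ix_(ia, ib)]
            if a == b:
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "pop_a": a,
                    "pop_b": b,
                    "mean": float(vals.mean()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n_pairs": int(vals.size),
                }
            )
    return pd.DataFrame(rows)
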