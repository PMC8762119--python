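"""Genotype imputation with a Li-Stephens haplotype-copying HMM.

A target haplotype observed only at scaffold markers is modelled as an
imperfect mosaic of ``K`` phased reference haplotypes.  The hidden state at
each marker is the reference haplotype being copied; transitions between
adjacent markers follow the Li-Stephens kernel (switch mass
``q = 1 - exp(-rho * d / K)`` spread uniformly over states, where ``d`` is
the bp distance and ``rho`` the population-scaled recombination parameter),
and emissions allow a per-site copying error ``eps``.  State posteriors are
computed by a scaled forward-backward pass; posteriors at hidden
(unobserved) sites are obtained by exact propagation of the forward and
backward vectors across the flanking scaffold markers, and the haploid
allele dosage at a hidden site is the posterior-weighted mean of the
reference alleles there.

This engine is the pipeline's built-in imputation method; production tools
(Beagle, Minimac) implement state-space-reduced variants of the same model
and can be plugged in through :func:`external_imputer_roundtrip`.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReferencePanel",
    "HMMParams",
    "ImputationResult",
    "ForwardBackwardResult",
    "ImputationError",
    "MissingExecutableError",
    "MalformedOutputError",
    "SiteSetMismatchError",
    "transition_kernel",
    "emission_prob",
    "forward_backward",
    "impute_hidden_sites",
    "impute_diploid",
    "impute_panel",
    "external_imputer_roundtrip",
]


class ImputationError(ValueError):
    pass


class MissingExecutableError(ImputationError):
    """The configured external imputation tool is not on PATH."""


class MalformedOutputError(ImputationError):
    """The external tool produced output that cannot be parsed."""


class SiteSetMismatchError(ImputationError):
    """The external tool's output does not cover the expected hidden sites."""


@dataclass
class ReferencePanel:
    """K phased reference haplotypes over the full variant universe."""

    haplotypes: np.ndarray  # (K, S) 0/1
    positions: np.ndarray  # (S,) bp

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 1:
            raise ImputationError("reference panel needs K >= 1 haplotypes")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ImputationError("positions do not match haplotype columns")
        if np.any(self.haplotypes > 1):
            raise ImputationError("reference alleles must be 0/1")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]


@dataclass(frozen=True)
class HMMParams:
    """Copying-model parameters.

    ``rho`` is the population-scaled recombination parameter per bp
    (default ``4 * ne_eff * r``); ``eps`` the per-site copying error.
    """

    rho: float
    eps: float = 1e-3
    ne_eff: float | None = None

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ImputationError("rho must be >= 0")
        if not (0 < self.eps < 0.5):
            raise ImputationError("eps must lie in (0, 0.5)")

    @classmethod
    def from_rates(cls, recombination_rate: float, ne_eff: float = 1600.0, eps: float = 1e-3):
        return cls(rho=4.0 * ne_eff * recombination_rate, eps=eps, ne_eff=ne_eff)


@dataclass
class ImputationResult:
    """Imputed genotypes at the hidden sites.

    ``dosage`` is the expected alternate-allele count per individual and
    site (in [0, 2]); ``best_guess`` its nearest-integer genotype (ties
    round half to even); ``site_confidence`` the mean (over target
    haplotypes) of the maximum state posterior at each site.
    """

    positions: np.ndarray  # (H,) bp of the hidden sites
    dosage: np.ndarray  # (n_individuals, H)
    best_guess: np.ndarray  # (n_individuals, H) in {0,1,2}
    site_confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.dosage = np.atleast_2d(np.asarray(self.dosage, dtype=float))
        self.best_guess = np.atleast_2d(np.asarray(self.best_guess, dtype=np.int8))
        if np.any((self.dosage < -1e-9) | (self.dosage > 2 + 1e-9)):
            raise ImputationError("dosages must lie in [0, 2]")


def best_guess_genotype(dosage: np.ndarray) -> np.ndarray:
    """Nearest integer in {0,1,2}; ties (0.5, 1.5) round half to even."""
    return np.clip(np.rint(dosage), 0, 2).astype(np.int8)


# ---------------------------------------------------------------------------
# HMM primitives
# ---------------------------------------------------------------------------


def transition_kernel(distance_bp: float, K: int, rho: float) -> dict:
    """Li-Stephens transition over a gap of ``distance_bp``.

    Returns ``p_switch_each`` (probability of jumping to any one specific
    state, self included) and ``p_stay`` (total probability of ending in the
    same state: no-switch mass plus the uniform jump back to self).
    """
    if distance_bp < 0:
        raise ImputationError("distance must be >= 0")
    if K < 1:
        raise ImputationError("K must be >= 1")
    q = -np.expm1(-rho * distance_bp / K)
    return {"p_stay": (1.0 - q) + q / K, "p_switch_each": q / K, "q": q}


def emission_prob(ref_allele: int, obs_allele: int, eps: float) -> float:
    """Copying emission: ``1 - eps`` on an allele match, ``eps`` otherwise."""
    if not (0 < eps < 0.5):
        raise ImputationError("eps must lie in (0, 0.5)")
    return 1.0 - eps if ref_allele == obs_allele else eps


@dataclass
class ForwardBackwardResult:
    """Scaled forward/backward vectors and posteriors at the scaffold sites.

    ``forward[m]`` is proportional to P(o_1..m, state) normalized to sum 1;
    ``backward`` carries the matching scaling so ``gamma = forward*backward``
    sums to 1 at every site.  ``scales`` are the per-site normalizers, and
    ``weighted_backward[m] = emission_m * backward_m`` (needed for hidden-site
    propagation).
    """

    gamma: np.ndarray  # (M, K)
    forward: np.ndarray  # (M, K)
    backward: np.ndarray  # (M, K)
    scales: np.ndarray  # (M,)
    positions: np.ndarray  # (M,) scaffold bp
    q_right: np.ndarray  # (M-1,) switch mass of each inter-site gap
    emissions: np.ndarray  # (M, K)
    log_likelihood: float


def forward_backward(
    target_hap: np.ndarray,
    reference_scaffold: np.ndarray,
    positions: np.ndarray,
    params: HMMParams,
) -> ForwardBackwardResult:
    """Scaled forward-backward over the scaffold markers.

    ``target_hap`` holds the observed 0/1 alleles at ``M >= 1`` scaffold
    sites; ``reference_scaffold`` is the (K, M) reference restricted to those
    sites.  Per-site rescaling keeps the recursion in the unit range, so
    panels with K up to ~1e4 and M up to ~1e5 run without underflow.
    """
    obs = np.asarray(target_hap)
    ref = np.asarray(reference_scaffold)
    pos = np.asarray(positions, dtype=float)
    if obs.ndim != 1 or ref.ndim != 2 or ref.shape[1] != obs.shape[0]:
        raise ImputationError("scaffold shapes disagree")
    if len(pos) != obs.shape[0]:
        raise ImputationError("positions do not match scaffold sites")
    if np.any((obs != 0) & (obs != 1)) or np.any((ref != 0) & (ref != 1)):
        raise ImputationError("allele codes must be 0/1")
    K, M = ref.shape
    eps = params.eps

    emis = np.where(ref.T == obs[None, :].T, 1.0 - eps, eps)  # (M, K)
    d = np.diff(pos)
    q = -np.expm1(-params.rho * d / K)  # (M-1,)

    F = np.empty((M, K))
    scales = np.empty(M)
    f = emis[0] / K
    scales[0] = f.sum()
    F[0] = f / scales[0]
    for m in range(1, M):
        pred = (1.0 - q[m - 1]) * F[m - 1] + q[m - 1] / K
        f = emis[m] * pred
        scales[m] = f.sum()
        F[m] = f / scales[m]

    B = np.empty((M, K))
    B[M - 1] = 1.0
    for m in range(M - 2, -1, -1):
        w = emis[m + 1] * B[m + 1]
        B[m] = ((1.0 - q[m]) * w + (q[m] / K) * w.sum()) / scales[m + 1]

    gamma = F * B
    gamma /= gamma.sum(axis=1, keepdims=True)
    return ForwardBackwardResult(
        gamma=gamma,
        forward=F,
        backward=B,
        scales=scales,
        positions=pos,
        q_right=q,
        emissions=emis,
        log_likelihood=float(np.log(scales).sum()),
    )


def impute_hidden_sites(
    fb: ForwardBackwardResult,
    reference: ReferencePanel,
    hidden_indices: np.ndarray,
    params: HMMParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Haploid dosages at hidden sites by exact HMM propagation.

    For a hidden site between scaffold markers ``m`` and ``m+1`` the state
    distribution combines the forward vector at ``m`` advanced over the left
    gap with the backward information at ``m+1`` advanced over the right gap
    (the Li-Stephens kernel composes exactly over abutting gaps, so silent
    sites need no extra pass).  Flanking hidden sites use one-sided
    propagation.  Returns ``(dosage, max_posterior)`` per hidden site.
    """
    hid = np.asarray(hidden_indices, dtype=np.int64)
    K = reference.n_haplotypes
    hpos = reference.positions[hid].astype(float)
    spos = fb.positions
    if np.any(np.isin(hpos, spos)):
        raise ImputationError("hidden site coincides with a scaffold site (partition violated)")
    M = len(spos)
    right = np.searchsorted(spos, hpos)  # index of scaffold site to the right
    dosage = np.empty(len(hid))
    maxpost = np.empty(len(hid))

    # precompute w_m = emission_m * backward_m for the right-flank propagation
    W = fb.emissions * fb.backward  # (M, K)
    Wsum = W.sum(axis=1)

    for n, (t, rr) in enumerate(zip(hid, right)):
        p = hpos[n]
        if rr == 0:
            # before the first scaffold site: uniform prior, backward only
            q2 = -np.expm1(-params.rho * (spos[0] - p) / K)
            g = ((1.0 - q2) * W[0] + (q2 / K) * Wsum[0])
        elif rr == M:
            q1 = -np.expm1(-params.rho * (p - spos[M - 1]) / K)
            g = (1.0 - q1) * fb.forward[M - 1] + q1 / K
        else:
            m = rr - 1
            q1 = -np.expm1(-params.rho * (p - spos[m]) / K)
            q2 = -np.expm1(-params.rho * (spos[rr] - p) / K)
            alpha = (1.0 - q1) * fb.forward[m] + q1 / K  # sum(F)=1
            beta = (1.0 - q2) * W[rr] + (q2 / K) * Wsum[rr]
            g = alpha * beta
        g = g / g.sum()
        dosage[n] = float(g @ reference.haplotypes[:, t])
        maxpost[n] = float(g.max())
    return dosage, maxpost


def impute_diploid(
    hap1: np.ndarray,
    hap2: np.ndarray,
    scaffold_positions: np.ndarray,
    reference: ReferencePanel,
    observed_indices: np.ndarray,
    hidden_indices: np.ndarray,
    params: HMMParams,
) -> ImputationResult:
    """Impute one phased diploid: each haplotype independently, dosages summed.

    ``hap1``/``hap2`` are the individual's phased scaffold alleles; the two
    haploid copying chains are run separately (K states each) and the
    genotype dosage is the sum of the haploid dosages.
    """
    ref_sc = reference.haplotypes[:, observed_indices]
    d = np.zeros(len(hidden_indices))
    conf = np.zeros(len(hidden_indices))
    for hap in (hap1, hap2):
        fb = forward_backward(hap, ref_sc, scaffold_positions, params)
        dh, mp = impute_hidden_sites(fb, reference, hidden_indices, params)
        d += dh
        conf += mp
    return ImputationResult(
        positions=reference.positions[hidden_indices],
        dosage=d[None, :],
        best_guess=best_guess_genotype(d)[None, :],
        site_confidence=conf / 2.0,
    )


def impute_panel(
    target_haplotypes: np.ndarray,
    reference: ReferencePanel,
    observed_indices: np.ndarray,
    hidden_indices: np.ndarray,
    params: HMMParams,
) -> ImputationResult:
    """Impute every target individual of a scaffold-typed cohort.

    ``target_haplotypes`` is (2*n, M): the phased scaffold alleles of n
    diploids (rows 2k, 2k+1 belong to individual k), aligned to
    ``observed_indices`` of the reference's site axis.
    """
    th = np.asarray(target_haplotypes)
    if th.ndim != 2 or th.shape[0] % 2:
        raise ImputationError("target haplotypes must be (2n, M)")
    obs_idx = np.asarray(observed_indices, dtype=np.int64)
    hid_idx = np.asarray(hidden_indices, dtype=np.int64)
    spos = reference.positions[obs_idx].astype(float)
    ref_sc = reference.haplotypes[:, obs_idx]
    n = th.shape[0] // 2
    dosage = np.zeros((n, len(hid_idx)))
    conf = np.zeros(len(hid_idx))
    for h in range(th.shape[0]):
        fb = forward_backward(th[h], ref_sc, spos, params)
        dh, mp = impute_hidden_sites(fb, reference, hid_idx, params)
        dosage[h // 2] += dh
        conf += mp
    return ImputationResult(
        positions=reference.positions[hid_idx],
        dosage=dosage,
        best_guess=best_guess_genotype(dosage),
        site_confidence=conf / th.shape[0],
    )


# ---------------------------------------------------------------------------
# External-imputer adapter
# ---------------------------------------------------------------------------


def external_imputer_roundtrip(
    scaffold_vcf: str,
    reference_vcf: str,
    command_template: str,
    expected_positions: np.ndarray,
    *,
    workdir: str = ".",
) -> ImputationResult:
    """Run an external imputation tool through VCF files.

    ``command_template`` receives ``{scaffold}``, ``{reference}`` and
    ``{out}`` placeholders; the tool must write an imputed VCF at ``{out}``
    covering exactly ``expected_positions`` (0-based bp).  GT provides the
    best-guess genotypes; a DS FORMAT field, if present, provides dosages
    (otherwise dosage falls back to the GT allele count).
    """
    from pathlib import Path

    from imputesim.io import read_vcf_result

    out_path = str(Path(workdir) / "imputed.external.vcf")
    cmd = command_template.format(scaffold=scaffold_vcf, reference=reference_vcf, out=out_path)
    exe = cmd.split()[0]
    if shutil.which(exe) is None:
        raise MissingExecutableError(f"external imputer executable not found: {exe!r}")
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise MalformedOutputError(
            f"external imputer exited with status {proc.returncode}: {proc.stderr[-500:]}"
        )
    try:
        result = read_vcf_result(out_path)
    except Exception as exc:  # cyvcf2 raises assorted types on bad input
        raise MalformedOutputError(f"cannot parse external imputer output: {exc}") from exc
    expected = np.asarray(expected_positions, dtype=np.int64)
    if len(result.positions) != len(expected) or np.any(result.positions != expected):
        raise SiteSetMismatchError(
            f"external output covers {len(result.positions)} sites, "
            f"expected {len(expected)} hidden sites"
        )
    return result
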