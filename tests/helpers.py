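"""Independent oracles and small utilities shared by the test modules.

The brute-force HMM routines enumerate every state path explicitly and are
kept deliberately free of the package's forward-backward code so they can
serve as an exact cross-check for small state spaces.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp


def ls_transition_matrix(distance: float, K: int, rho: float) -> np.ndarray:
    q = 1.0 - np.exp(-rho * distance / K)
    return (1.0 - q) * np.eye(K) + q / K * np.ones((K, K))


def brute_force_posteriors(obs, ref, positions, rho, eps) -> np.ndarray:
    """State posteriors at every scaffold site by full path enumeration."""
    ref = np.asarray(ref)
    K, M = ref.shape
    trans = [ls_transition_matrix(positions[m + 1] - positions[m], K, rho) for m in range(M - 1)]
    joint = np.zeros((M, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=M):
        p = 1.0 / K
        for m, k in enumerate(path):
            if m > 0:
                p *= trans[m - 1][path[m - 1], k]
            p *= (1.0 - eps) if ref[k, m] == obs[m] else eps
        total += p
        for m, k in enumerate(path):
            joint[m, k] += p
    return joint / total


def brute_force_hidden_dosage(obs, ref_scaffold, scaffold_pos, ref_hidden_alleles,
                              hidden_pos, rho, eps) -> float:
    """Haploid dosage at one silent (hidden) site by path enumeration.

    The hidden site is inserted into the chain as an emission-free state;
    transitions use the two flanking sub-gap distances.
    """
    ref_scaffold = np.asarray(ref_scaffold)
    K, M = ref_scaffold.shape
    all_pos = list(scaffold_pos) + [hidden_pos]
    order = np.argsort(all_pos)
    site_kind = (["obs"] * M + ["hidden"])  # parallel to all_pos
    seq_pos = [all_pos[i] for i in order]
    seq_kind = [site_kind[i] for i in order]
    seq_obs_index = [i if i < M else None for i in order]
    T = len(seq_pos)
    trans = [ls_transition_matrix(seq_pos[t + 1] - seq_pos[t], K, rho) for t in range(T - 1)]
    joint_hidden = np.zeros(K)
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = 1.0 / K
        for t, k in enumerate(path):
            if t > 0:
                p *= trans[t - 1][path[t - 1], k]
            if seq_kind[t] == "obs":
                m = seq_obs_index[t]
                p *= (1.0 - eps) if ref_scaffold[k, m] == obs[m] else eps
        total += p
        t_hidden = seq_kind.index("hidden")
        joint_hidden[path[t_hidden]] += p
    gamma = joint_hidden / total
    return float(gamma @ np.asarray(ref_hidden_alleles))


def logspace_forward_backward(obs, ref, positions, rho, eps) -> np.ndarray:
    """Posteriors via an independent log-space recursion (underflow-proof)."""
    ref = np.asarray(ref)
    K, M = ref.shape
    log_emis = np.where(ref.T == np.asarray(obs)[:, None], np.log1p(-eps), np.log(eps))
    la = np.empty((M, K))
    la[0] = -np.log(K) + log_emis[0]
    for m in range(1, M):
        A = np.log(ls_transition_matrix(positions[m] - positions[m - 1], K, rho))
        la[m] = log_emis[m] + logsumexp(la[m - 1][:, None] + A, axis=0)
    lb = np.zeros((M, K))
    for m in range(M - 2, -1, -1):
        A = np.log(ls_transition_matrix(positions[m + 1] - positions[m], K, rho))
        lb[m] = logsumexp(A + (log_emis[m + 1] + lb[m + 1])[None, :], axis=1)
    lg = la + lb
    return np.exp(lg - logsumexp(lg, axis=1, keepdims=True))


def one_deme_model(N=1000.0, L=100_000.0, mu=1e-7, r=1e-7):
    from imputesim.demography import DemographicModel, Population

    return DemographicModel(
        sequence_length=L,
        mutation_rate=mu,
        recombination_rate=r,
        populations=[Population("P1", N)],
    )
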