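"""Li-Stephens HMM correctness: kernels, posteriors, hidden-site propagation."""

import math

import numpy as np
import pytest

from imputesim.ascertainment import filter_target_universe, select_evenly_spaced, select_random
from imputesim.imputation import (
    HMMParams,
    ImputationError,
    MalformedOutputError,
    MissingExecutableError,
    ReferencePanel,
    SiteSetMismatchError,
    best_guess_genotype,
    emission_prob,
    external_imputer_roundtrip,
    forward_backward,
    impute_diploid,
    impute_hidden_sites,
    impute_panel,
    transition_kernel,
)

from .helpers import (
    brute_force_hidden_dosage,
    brute_force_posteriors,
    logspace_forward_backward,
)


class TestTransitionKernel:
    def test_zero_distance_stays_put(self):
        k = transition_kernel(0.0, 4, rho=1e-3)
        assert k["p_stay"] == pytest.approx(1.0)
        assert k["p_switch_each"] == pytest.approx(0.0)

    def test_known_switch_mass(self):
        # K = 2, rho*d = 2: q = 1 - e^-1, P(stay) = (1-q) + q/2
        k = transition_kernel(2.0, 2, rho=1.0)
        q = 1 - math.exp(-1.0)
        assert k["q"] == pytest.approx(q, abs=1e-12)
        assert k["p_stay"] == pytest.approx(1 - q + q / 2, abs=1e-12)
        assert k["p_stay"] == pytest.approx(0.6839, abs=1e-4)

    def test_large_rho_approaches_uniform(self):
        k = transition_kernel(1e9, 5, rho=1.0)
        assert k["p_stay"] == pytest.approx(1 / 5, rel=1e-9)
        assert k["p_switch_each"] == pytest.approx(1 / 5, rel=1e-9)

    def test_row_sums_to_one(self):
        k = transition_kernel(123.0, 7, rho=2e-4)
        assert k["p_stay"] + 6 * k["p_switch_each"] == pytest.approx(1.0, abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ImputationError):
            transition_kernel(-1.0, 2, rho=1.0)


class TestEmission:
    def test_match_and_mismatch(self):
        assert emission_prob(1, 1, 0.01) == pytest.approx(0.99)
        assert emission_prob(1, 0, 0.01) == pytest.approx(0.01)
        # normalization over the two possible observations
        assert emission_prob(0, 0, 0.01) + emission_prob(0, 1, 0.01) == pytest.approx(1.0)

    @pytest.mark.parametrize("eps", [0.0, 0.5, 0.7])
    def test_eps_bounds(self, eps):
        with pytest.raises(ImputationError):
            emission_prob(0, 0, eps)


def _rand_ref(rng, K, M):
    return rng.integers(0, 2, size=(K, M)).astype(np.uint8)


class TestForwardBackward:
    def test_single_reference_posterior_is_one(self):
        ref = np.array([[0, 1, 1, 0]], dtype=np.uint8)
        fb = forward_backward(np.array([0, 1, 0, 0]), ref, np.array([0, 10, 20, 30]),
                              HMMParams(rho=1e-3))
        assert np.allclose(fb.gamma, 1.0)

    def test_identical_haplotype_dominates(self):
        rng = np.random.default_rng(1)
        ref = _rand_ref(rng, 5, 40)
        params = HMMParams(rho=1e-4, eps=1e-3)
        pos = np.arange(40) * 100
        fb = forward_backward(ref[3], ref, pos, params)
        assert np.all(fb.gamma.argmax(axis=1) == 3)

    def test_posteriors_normalized(self):
        rng = np.random.default_rng(7)
        ref = _rand_ref(rng, 30, 200)
        obs = rng.integers(0, 2, size=200)
        fb = forward_backward(obs, ref, np.sort(rng.choice(10**6, 200, replace=False)),
                              HMMParams(rho=6.4e-4))
        assert np.allclose(fb.gamma.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("K,M,seed", [(2, 3, 0), (3, 5, 1), (3, 4, 2), (2, 5, 3)])
    def test_matches_brute_force_path_enumeration(self, K, M, seed):
        rng = np.random.default_rng(seed)
        ref = _rand_ref(rng, K, M)
        obs = rng.integers(0, 2, size=M)
        pos = np.sort(rng.choice(5000, M, replace=False)).astype(float)
        rho, eps = 2e-3, 0.05
        fb = forward_backward(obs, ref, pos, HMMParams(rho=rho, eps=eps))
        expected = brute_force_posteriors(obs, ref, pos, rho, eps)
        assert np.allclose(fb.gamma, expected, atol=1e-10)

    def test_matches_logspace_reference(self):
        rng = np.random.default_rng(11)
        ref = _rand_ref(rng, 20, 120)
        obs = rng.integers(0, 2, size=120)
        pos = np.sort(rng.choice(10**5, 120, replace=False)).astype(float)
        fb = forward_backward(obs, ref, pos, HMMParams(rho=6.4e-4, eps=1e-3))
        expected = logspace_forward_backward(obs, ref, pos, 6.4e-4, 1e-3)
        assert np.allclose(fb.gamma, expected, atol=1e-9)

    def test_bad_allele_codes_rejected(self):
        with pytest.raises(ImputationError):
            forward_backward(np.array([0, 2]), np.zeros((2, 2), dtype=np.uint8),
                             np.array([0, 10]), HMMParams(rho=1e-3))


class TestHiddenSitePropagation:
    def _setup(self, seed=0, K=4, M=6, H=3):
        rng = np.random.default_rng(seed)
        all_pos = np.sort(rng.choice(3000, M + H, replace=False))
        hid = np.sort(rng.choice(M + H, H, replace=False))
        obs_idx = np.setdiff1d(np.arange(M + H), hid)
        haps = _rand_ref(rng, K, M + H)
        ref = ReferencePanel(haps, all_pos)
        target = rng.integers(0, 2, size=M)
        return ref, obs_idx, hid, target

    def test_matches_brute_force_with_silent_site(self):
        params = HMMParams(rho=1.5e-3, eps=0.05)
        for seed in range(4):
            ref, obs_idx, hid, target = self._setup(seed=seed, K=2, M=3, H=1)
            fb = forward_backward(target, ref.haplotypes[:, obs_idx],
                                  ref.positions[obs_idx], params)
            dosage, _ = impute_hidden_sites(fb, ref, hid, params)
            expected = brute_force_hidden_dosage(
                target, ref.haplotypes[:, obs_idx], ref.positions[obs_idx].astype(float),
                ref.haplotypes[:, hid[0]], float(ref.positions[hid[0]]),
                params.rho, params.eps,
            )
            assert dosage[0] == pytest.approx(expected, abs=1e-10)

    def test_flanking_sites_use_one_sided_propagation(self):
        # hidden sites before the first and after the last scaffold marker
        params = HMMParams(rho=2e-3, eps=0.05)
        rng = np.random.default_rng(5)
        haps = _rand_ref(rng, 2, 4)
        ref = ReferencePanel(haps, np.array([5, 100, 200, 305]))
        target = rng.integers(0, 2, size=2)
        obs_idx = np.array([1, 2])
        fb = forward_backward(target, haps[:, obs_idx], ref.positions[obs_idx], params)
        dosage, _ = impute_hidden_sites(fb, ref, np.array([0, 3]), params)
        for j, hid in enumerate((0, 3)):
            expected = brute_force_hidden_dosage(
                target, haps[:, obs_idx], ref.positions[obs_idx].astype(float),
                haps[:, hid], float(ref.positions[hid]), params.rho, params.eps,
            )
            assert dosage[j] == pytest.approx(expected, abs=1e-10)

    def test_vanishing_distance_recovers_site_posterior(self):
        # a hidden site 1 bp from a scaffold site with negligible rho per bp
        params = HMMParams(rho=1e-12, eps=0.05)
        ref, obs_idx, hid, target = self._setup(seed=3, K=4, M=6, H=2)
        fb = forward_backward(target, ref.haplotypes[:, obs_idx],
                              ref.positions[obs_idx], params)
        dosage, _ = impute_hidden_sites(fb, ref, hid, params)
        # with rho ~ 0 the chain never switches; state distribution at any
        # hidden site equals the (position-independent) site posterior
        for j, t in enumerate(hid):
            expected = float(fb.gamma[0] @ ref.haplotypes[:, t])
            assert dosage[j] == pytest.approx(expected, abs=1e-9)

    def test_monomorphic_reference_site_pins_dosage(self):
        params = HMMParams(rho=1e-3)
        rng = np.random.default_rng(9)
        haps = _rand_ref(rng, 3, 5)
        haps[:, 2] = 1  # all references carry the derived allele
        ref = ReferencePanel(haps, np.array([0, 50, 100, 150, 200]))
        obs_idx = np.array([0, 1, 3, 4])
        target = rng.integers(0, 2, size=4)
        fb = forward_backward(target, haps[:, obs_idx], ref.positions[obs_idx], params)
        dosage, _ = impute_hidden_sites(fb, ref, np.array([2]), params)
        assert dosage[0] == pytest.approx(1.0, abs=1e-12)

    def test_scaffold_collision_rejected(self):
        params = HMMParams(rho=1e-3)
        haps = np.zeros((2, 3), dtype=np.uint8)
        haps[0] = 1
        ref = ReferencePanel(haps, np.array([0, 10, 20]))
        fb = forward_backward(np.array([1, 0]), haps[:, [0, 2]], np.array([0, 20]), params)
        with pytest.raises(ImputationError, match="coincides"):
            impute_hidden_sites(fb, ref, np.array([0]), params)

    def test_reference_label_invariance(self):
        params = HMMParams(rho=1e-3, eps=1e-2)
        ref, obs_idx, hid, target = self._setup(seed=8, K=6, M=8, H=4)
        fb = forward_backward(target, ref.haplotypes[:, obs_idx],
                              ref.positions[obs_idx], params)
        d1, _ = impute_hidden_sites(fb, ref, hid, params)
        perm = np.random.default_rng(0).permutation(6)
        ref2 = ReferencePanel(ref.haplotypes[perm], ref.positions)
        fb2 = forward_backward(target, ref2.haplotypes[:, obs_idx],
                               ref2.positions[obs_idx], params)
        d2, _ = impute_hidden_sites(fb2, ref2, hid, params)
        assert np.allclose(d1, d2, atol=1e-12)


class TestDiploidImputation:
    def test_best_guess_rounds_half_to_even(self):
        assert list(best_guess_genotype(np.array([0.4, 0.5, 0.8, 1.5, 1.2, 2.0]))) == [
            0, 0, 1, 2, 1, 2,
        ]

    def test_copying_a_reference_individual_recovers_it(self):
        rng = np.random.default_rng(21)
        haps = _rand_ref(rng, 4, 60)
        pos = np.sort(rng.choice(10**5, 60, replace=False))
        ref = ReferencePanel(haps, pos)
        obs_idx = np.arange(0, 60, 2)
        hid_idx = np.arange(1, 60, 2)
        params = HMMParams(rho=1e-5, eps=1e-3)
        res = impute_diploid(
            haps[1, obs_idx], haps[1, obs_idx], pos[obs_idx].astype(float),
            ref, obs_idx, hid_idx, params,
        )
        assert np.array_equal(res.best_guess[0], 2 * haps[1, hid_idx])

    def test_dosages_add_across_haplotypes(self):
        rng = np.random.default_rng(2)
        haps = _rand_ref(rng, 5, 30)
        pos = np.arange(30) * 50
        ref = ReferencePanel(haps, pos)
        obs_idx = np.arange(0, 30, 3)
        hid_idx = np.setdiff1d(np.arange(30), obs_idx)
        params = HMMParams(rho=1e-4)
        h1, h2 = haps[0, obs_idx], haps[3, obs_idx]
        res = impute_diploid(h1, h2, pos[obs_idx].astype(float), ref, obs_idx, hid_idx, params)
        fb1 = forward_backward(h1, haps[:, obs_idx], pos[obs_idx], params)
        fb2 = forward_backward(h2, haps[:, obs_idx], pos[obs_idx], params)
        d1, _ = impute_hidden_sites(fb1, ref, hid_idx, params)
        d2, _ = impute_hidden_sites(fb2, ref, hid_idx, params)
        assert np.allclose(res.dosage[0], d1 + d2, atol=1e-12)


class TestAccuracyRecovery:
    def test_denser_scaffold_improves_reliability(self, small_one_deme_panel):
        """30 ref / 30 target diploids, one deme: r2 > 0.8 at 30% density,
        and strictly better than at 10% (matched panel)."""
        from imputesim.accuracy import per_locus_accuracy

        panel = small_one_deme_panel
        ref_ids = np.arange(30)
        tgt_ids = np.arange(30, 60)
        universe = filter_target_universe(panel, "P1", 0.01, target_individuals=tgt_ids)
        ref_haps = panel.subset_individuals(ref_ids).matrix[:, universe.site_indices]
        reference = ReferencePanel(ref_haps, panel.positions[universe.site_indices])
        tgt_haps = panel.subset_individuals(tgt_ids).matrix
        params = HMMParams.from_rates(1e-7, ne_eff=1000.0)

        mean_r2 = {}
        for prop in (0.10, 0.30):
            sel = select_random(universe, int(prop * len(universe)), seed=99)
            obs_u = np.searchsorted(universe.site_indices, sel.observed)
            hid_u = np.searchsorted(universe.site_indices, sel.hidden)
            res = impute_panel(tgt_haps[:, sel.observed], reference, obs_u, hid_u, params)
            truth = panel.genotypes()[np.ix_(tgt_ids, sel.hidden)]
            rec = per_locus_accuracy(res.best_guess, truth, universe.maf[hid_u])
            mean_r2[prop] = np.nanmean(rec["r2"])
        assert mean_r2[0.30] > 0.8
        assert mean_r2[0.30] > mean_r2[0.10]


class TestExternalAdapter:
    def _write_truth_vcf(self, path, positions, genotypes):
        from imputesim.demography import HaplotypePanel
        from imputesim.io import write_vcf

        haps = np.zeros((2 * genotypes.shape[0], len(positions)), dtype=np.uint8)
        for k in range(genotypes.shape[0]):
            haps[2 * k] = (genotypes[k] >= 1).astype(np.uint8)
            haps[2 * k + 1] = (genotypes[k] == 2).astype(np.uint8)
        panel = HaplotypePanel(
            matrix=haps, positions=positions,
            sample_populations=np.array(["P1"] * haps.shape[0]),
            sequence_length=float(positions[-1]) + 1,
        )
        write_vcf(panel, path)

    def test_identity_tool_gives_zero_error(self, tmp_path):
        from imputesim.accuracy import error_rate

        positions = np.array([3, 17, 40])
        truth = np.array([[0, 1, 2], [2, 0, 1]], dtype=np.int8)
        truth_vcf = tmp_path / "truth.vcf"
        self._write_truth_vcf(truth_vcf, positions, truth)
        (tmp_path / "scaffold.vcf").write_text("")
        (tmp_path / "ref.vcf").write_text("")
        res = external_imputer_roundtrip(
            str(tmp_path / "scaffold.vcf"), str(tmp_path / "ref.vcf"),
            "cp %s {out}" % truth_vcf,
            expected_positions=positions, workdir=str(tmp_path),
        )
        assert error_rate(res.best_guess, truth) == 0.0

    def test_missing_executable_reported_distinctly(self, tmp_path):
        with pytest.raises(MissingExecutableError):
            external_imputer_roundtrip(
                "a.vcf", "b.vcf", "no-such-imputer-binary {scaffold} {out}",
                expected_positions=np.array([1]), workdir=str(tmp_path),
            )

    def test_site_set_mismatch_reported_distinctly(self, tmp_path):
        positions = np.array([3, 17, 40])
        truth = np.array([[0, 1, 2]], dtype=np.int8)
        truth_vcf = tmp_path / "truth.vcf"
        self._write_truth_vcf(truth_vcf, positions, truth)
        with pytest.raises(SiteSetMismatchError):
            external_imputer_roundtrip(
                str(truth_vcf), str(truth_vcf), "cp %s {out}" % truth_vcf,
                expected_positions=np.array([3, 17, 40, 99]), workdir=str(tmp_path),
            )

    def test_malformed_output_reported_distinctly(self, tmp_path):
        bad = tmp_path / "bad.txt"
        bad.write_text("this is not a VCF\n")
        with pytest.raises(MalformedOutputError):
            external_imputer_roundtrip(
                str(bad), str(bad), "cp %s {out}" % bad,
                expected_positions=np.array([1]), workdir=str(tmp_path),
            )
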