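import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyespy import (
    CANONICAL_GRID,
    ColorantRecord,
    DyeProduct,
    MixtureLabel,
    SimulationConfig,
    Spectrum,
    cosine_similarity,
    enumerate_primary_coupler_pairs,
    generate_colorant_profile,
    lasm_mix,
    simulate_dye_spectrum,
)
from dyespy.exceptions import AlignmentError, UsageError
from dyespy.library import (
    NONOXIDATIVE,
    OXIDATIVE,
    SyntheticColorantSpec,
    build_phase1_training,
    build_phase2_nonox_training,
    grouped_train_test_split,
    indicator_matrix,
    reaction_product_spec,
)


def _primaries(n):
    return [ColorantRecord(f"P{i}", f"p{i}", "oxidative", "primary") for i in range(n)]


def _couplers(n):
    return [ColorantRecord(f"C{i}", f"c{i}", "oxidative", "coupler") for i in range(n)]


class TestColorantRecord:
    def test_role_pathway_consistency_enforced(self):
        with pytest.raises(UsageError):
            ColorantRecord("Q", "q", "nonoxidative", "coupler")
        with pytest.raises(UsageError):
            ColorantRecord("Q", "q", "oxidative", "direct")


class TestLasmMix:
    def test_single_spectrum_is_identity(self, make_gaussian):
        s = make_gaussian(900.0, baseline=0.01)
        from dyespy import area_normalize

        out = lasm_mix([s])
        np.testing.assert_allclose(out.intensities, area_normalize(s.intensities))

    def test_two_copies_equal_weights_unchanged(self, make_gaussian):
        s = make_gaussian(900.0, baseline=0.01)
        a = lasm_mix([s])
        b = lasm_mix([s, s])
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-15)

    def test_disjoint_one_hot_vectors_mix_to_half(self):
        grid = np.array([1.0, 2.0, 3.0])
        a = Spectrum(grid, [1.0, 0.0, 0.0])
        b = Spectrum(grid, [0.0, 0.0, 1.0])
        out = lasm_mix([a, b])
        np.testing.assert_allclose(out.intensities, [0.5, 0.0, 0.5])

    @given(seed=st.integers(0, 50))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_permutation_invariance_and_weight_homogeneity(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.arange(10.0)
        spectra = [Spectrum(grid, rng.random(10) + 0.01) for _ in range(4)]
        w = rng.random(4) + 0.1
        out = lasm_mix(spectra, w)
        perm = rng.permutation(4)
        out_p = lasm_mix([spectra[i] for i in perm], w[perm])
        np.testing.assert_allclose(out.intensities, out_p.intensities, atol=1e-12)
        out_s = lasm_mix(spectra, 7.3 * w)
        np.testing.assert_allclose(out.intensities, out_s.intensities, atol=1e-12)

    def test_grid_mismatch_and_zero_weights_rejected(self, make_gaussian):
        a = make_gaussian(900.0)
        b = make_gaussian(900.0, grid=np.linspace(450, 1650, 100))
        with pytest.raises(AlignmentError):
            lasm_mix([a, b])
        with pytest.raises(UsageError):
            lasm_mix([a, a], weights=[0.0, 0.0])


class TestEnumeratePairs:
    @pytest.mark.parametrize("n_p,n_c", [(5, 22), (1, 1), (5, 0), (0, 7)])
    def test_count_law(self, n_p, n_c):
        pairs = enumerate_primary_coupler_pairs(_primaries(n_p), _couplers(n_c))
        assert len(pairs) == n_p * n_c
        assert len(set(pairs)) == len(pairs)
        assert all(len(p) == 2 for p in pairs)

    def test_count_law_brute_force_over_small_sizes(self):
        for n_p in range(0, 6):
            for n_c in range(0, 6):
                pairs = enumerate_primary_coupler_pairs(
                    _primaries(n_p), _couplers(n_c)
                )
                brute = {
                    frozenset({p.esid, c.esid})
                    for p in _primaries(n_p)
                    for c in _couplers(n_c)
                }
                assert {p.esids for p in pairs} == brute

    def test_role_violation_rejected(self):
        with pytest.raises(UsageError):
            enumerate_primary_coupler_pairs(_couplers(1), _couplers(1))


class TestColorantGenerator:
    def test_gaussian_closed_form_before_preprocessing(self):
        spec = SyntheticColorantSpec(
            centers=[900.0], widths=[15.0], amplitudes=[2.0]
        )
        y_c = spec.signal(np.array([900.0]))[0]
        y_cw = spec.signal(np.array([915.0]))[0]
        assert y_c == pytest.approx(2.0, abs=1e-12)
        assert y_cw == pytest.approx(2.0 * np.exp(-0.5), abs=1e-12)

    def test_zero_peaks_gives_normalized_baseline_only(self):
        spec = SyntheticColorantSpec(
            centers=np.empty(0), widths=np.empty(0), amplitudes=np.empty(0),
            baseline_coeffs=[1.0, 0.5],
        )
        s = generate_colorant_profile(spec, seed=0)
        assert s.intensities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproduces_spectrum(self):
        spec = SyntheticColorantSpec(
            centers=[700.0, 1200.0], widths=[10.0, 20.0], amplitudes=[1.0, 0.5],
            noise_sigma=0.05, jitter=0.2,
        )
        a = generate_colorant_profile(spec, seed=11)
        b = generate_colorant_profile(spec, seed=11)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_invalid_spec_rejected(self):
        with pytest.raises(UsageError):
            SyntheticColorantSpec(centers=[100.0], widths=[5.0], amplitudes=[1.0])
        with pytest.raises(UsageError):
            SyntheticColorantSpec(centers=[900.0], widths=[-1.0], amplitudes=[1.0])

    def test_reaction_profile_deterministic_and_order_free(self):
        a = reaction_product_spec(["B", "AA"])
        b = reaction_product_spec(["AA", "B"])
        np.testing.assert_array_equal(a.centers, b.centers)
        c = reaction_product_spec(["B", "CC"])
        assert not np.array_equal(a.centers, c.centers)


class TestSimulateDye:
    def test_noise_free_nonoxidative_equals_lasm(self, tiny_library):
        _, speclib, _ = tiny_library
        mixture = MixtureLabel.of("AX", "BX")
        product = DyeProduct("p", mixture, "red", NONOXIDATIVE)
        quiet = SimulationConfig(noise_sigma=0.0, jitter=0.0)
        s = simulate_dye_spectrum(product, speclib, 5, quiet)
        recon = speclib.lasm_reconstruction(mixture)
        np.testing.assert_allclose(s.intensities, recon.intensities, atol=1e-12)

    def test_alpha_zero_oxidative_equals_lasm(self, tiny_library):
        _, speclib, _ = tiny_library
        mixture = MixtureLabel.of("A", "AA")
        product = DyeProduct("p", mixture, "red", OXIDATIVE)
        quiet = SimulationConfig(noise_sigma=0.0, jitter=0.0, alpha_range=(0.0, 0.0))
        s = simulate_dye_spectrum(product, speclib, 5, quiet)
        recon = speclib.lasm_reconstruction(mixture)
        np.testing.assert_allclose(s.intensities, recon.intensities, atol=1e-12)

    def test_oxidative_less_additive_than_nonoxidative(self, tiny_library):
        _, speclib, cfg = tiny_library
        quiet = cfg.simulation
        nonox = DyeProduct("n", MixtureLabel.of("AX", "CX"), "red", NONOXIDATIVE)
        ox = DyeProduct("o", MixtureLabel.of("A", "BB"), "red", OXIDATIVE)
        sims = {}
        for product in (nonox, ox):
            recon = speclib.lasm_reconstruction(product.mixture)
            scores = [
                cosine_similarity(
                    simulate_dye_spectrum(product, speclib, k, quiet).intensities,
                    recon.intensities,
                )
                for k in range(10)
            ]
            sims[product.pathway] = np.mean(scores)
        assert sims[NONOXIDATIVE] > sims[OXIDATIVE]


class TestTrainingSets:
    def test_phase1_composition_counts(self, tiny_library):
        _, speclib, _ = tiny_library
        lt = build_phase1_training(speclib, n_replicates=1, seed=0)
        # 3 direct + 3 primaries + 3 couplers + 3*3 pairs = 18 spectra
        assert len(lt.table) == 18
        assert lt.labels.count(NONOXIDATIVE) == 3
        assert lt.labels.count(OXIDATIVE) == 15
        without_couplers = build_phase1_training(
            speclib, n_replicates=1, seed=0, include_couplers_alone=False
        )
        assert len(without_couplers.table) == 15

    def test_phase2_nonox_covers_all_subsets(self, tiny_library):
        _, speclib, _ = tiny_library
        lt = build_phase2_nonox_training(
            speclib, max_subset_size=2, n_replicates=1, seed=0
        )
        # 3 singletons + 3 pairs
        assert len(lt.table) == 6
        assert len({str(l) for l in lt.labels}) == 6

    def test_zero_replicates_rejected(self, tiny_library):
        _, speclib, _ = tiny_library
        with pytest.raises(UsageError):
            build_phase1_training(speclib, n_replicates=0, seed=0)

    def test_grouped_split_shares_no_sample(self):
        sids = [f"s{i}" for i in range(20)]
        groups = [f"g{i % 4}" for i in range(20)]
        train, test = grouped_train_test_split(sids, groups, 0.2, seed=0)
        assert train.isdisjoint(test)
        assert train | test == set(sids)
        for g in set(groups):
            members = {s for s, gg in zip(sids, groups) if gg == g}
            assert members & train, "every product needs a training sample"

    def test_indicator_matrix(self):
        Y = indicator_matrix(
            [MixtureLabel.of("A"), MixtureLabel.of("A", "B")], ["A", "B", "C"]
        )
        np.testing.assert_array_equal(Y, [[1, 0, 0], [1, 1, 0]])
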