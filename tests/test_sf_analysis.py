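"""Peak estimation, peak shift, KDE modes, excess-mass multimodality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from snnface.sf_analysis import (
    estimate_peak_sf,
    excess_mass_test,
    estimate_mode_count,
    kde_mode_locations,
    make_tuning_record,
    peak_shift,
    peak_shift_distribution,
)
from snnface.stimuli import center_sf_grid
from snnface.synthetic_data import (
    SyntheticUnitSpec,
    generate_synthetic_unit_responses,
    generate_unit_population,
    synthetic_unit_curve,
)

GRID = center_sf_grid()


class TestPeakEstimation:
    def test_unique_interior_max(self):
        curve = np.zeros(61)
        curve[30] = 1.0
        peak, excl = estimate_peak_sf(curve)
        assert excl == "none"
        assert peak == pytest.approx(8.0)  # 2^(30·0.1)

    def test_monotone_curve_is_boundary_excluded(self):
        peak, excl = estimate_peak_sf(np.linspace(0.1, 1.0, 61))
        assert peak is None and excl == "boundary_peak"

    def test_flat_curve_is_sf_insensitive(self):
        peak, excl = estimate_peak_sf(np.full(61, 0.5))
        assert peak is None and excl == "sf_insensitive"

    def test_all_zero_curve_is_unresponsive(self):
        peak, excl = estimate_peak_sf(np.zeros(61))
        assert peak is None and excl == "unresponsive"

    def test_tie_breaks_to_lower_sf(self):
        curve = np.zeros(61)
        curve[[20, 40]] = 1.0
        peak, _ = estimate_peak_sf(curve)
        assert peak == pytest.approx(GRID[20])

    def test_raising_eps_never_reduces_insensitive_exclusions(self):
        rng = np.random.default_rng(0)
        curves = rng.random((50, 61)) * rng.random((50, 1))
        counts = []
        for eps in (0.05, 0.1, 0.2, 0.5):
            counts.append(
                sum(estimate_peak_sf(c, eps=eps)[1] == "sf_insensitive" for c in curves)
            )
        assert counts == sorted(counts)


class TestPeakShift:
    def test_pure_retina_based_unit_shifts_by_one(self):
        large, small = generate_synthetic_unit_responses(SyntheticUnitSpec(lam=1.0))
        assert peak_shift(large, small).shift == pytest.approx(1.0)

    def test_pure_object_based_unit_shifts_by_zero(self):
        large, small = generate_synthetic_unit_responses(SyntheticUnitSpec(lam=0.0))
        assert peak_shift(large, small).shift == pytest.approx(0.0)

    def test_planted_peaks_eight_and_four_give_shift_one(self):
        # log2(8) − log2(4) = 1, size ratio 2 → denominator 1
        large = make_tuning_record(np.exp(-((np.log2(GRID) - 3) ** 2)), 0, "happy", 198)
        small = make_tuning_record(np.exp(-((np.log2(GRID) - 2) ** 2)), 0, "happy", 99)
        rec = peak_shift(large, small)
        assert rec.shift == pytest.approx(1.0)
        assert rec.peak_large == pytest.approx(8.0)
        assert rec.peak_small == pytest.approx(4.0)

    def test_excluded_record_cannot_form_pair(self):
        large = make_tuning_record(np.zeros(61), 0, "happy", 198)
        small = make_tuning_record(np.exp(-((np.log2(GRID) - 2) ** 2)), 0, "happy", 99)
        with pytest.raises(ValueError, match="excluded"):
            peak_shift(large, small)

    def test_mismatched_unit_rejected(self):
        a = make_tuning_record(np.exp(-((np.log2(GRID) - 3) ** 2)), 0, "happy", 198)
        b = make_tuning_record(np.exp(-((np.log2(GRID) - 3) ** 2)), 1, "happy", 99)
        with pytest.raises(ValueError, match="same unit"):
            peak_shift(a, b)

    @pytest.mark.parametrize("profile", ["gaussian", "triangle", "cosine"])
    def test_any_retina_locked_unimodal_profile_gives_shift_one(self, profile):
        # reference-frame equivalence: any fixed function of retinal SF alone
        def response(size):
            retinal = np.log2(GRID * (198 / size))  # log2 cycles/canvas
            x = retinal - np.log2(16.0)
            if profile == "gaussian":
                return np.exp(-(x**2))
            if profile == "triangle":
                return np.clip(2.0 - np.abs(x), 0, None)
            return np.cos(np.clip(x, -1.5, 1.5))

        large = make_tuning_record(response(198), 0, "happy", 198)
        small = make_tuning_record(response(99), 0, "happy", 99)
        assert peak_shift(large, small).shift == pytest.approx(1.0)

    def test_lambda_recovery_with_noise(self):
        # planted λ ∈ {0, 0.5, 1}, tuning noise; mean |error| < 0.1
        for lam in (0.0, 0.5, 1.0):
            pairs = generate_unit_population([lam], 200, noise_sd=0.1, seed=5)
            shifts = [
                peak_shift(lg, sm).shift
                for lg, sm in pairs
                if lg.exclusion == "none" and sm.exclusion == "none"
            ]
            assert len(shifts) > 150
            assert abs(np.mean(shifts) - lam) < 0.1


class TestPeakShiftDistribution:
    def test_candidate_and_exclusion_bookkeeping(self):
        pairs = generate_unit_population([0.0, 1.0], 50, noise_sd=0.3, seed=1)
        records = [r for pair in pairs for r in pair]
        shifts, hist, book = peak_shift_distribution(records)
        assert book["candidates"] == 50
        assert book["retained"] + book["excluded"] == book["candidates"]
        assert len(shifts) == book["retained"]
        assert hist.sum() == book["retained"]

    def test_planted_retina_population_mass_on_shift_one_line(self):
        pairs = generate_unit_population([1.0], 40, noise_sd=0.0, seed=2)
        records = [r for pair in pairs for r in pair]
        shifts, hist, _ = peak_shift_distribution(records)
        assert all(s.shift == pytest.approx(1.0) for s in shifts)
        # all 2-D histogram mass sits where log2(large) − log2(small) = 1
        li, si = np.nonzero(hist)
        assert np.all(li - si == 10)  # 10 grid steps of 0.1 log2 units


class TestKDEModes:
    def test_single_gaussian_gives_one_dominant_mode_near_mean(self):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 0.1, 500)
        modes = kde_mode_locations(x)
        loc, height = modes[0]
        assert abs(loc - 2.0) < 0.1

    def test_two_separated_gaussians_give_two_modes(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.05, 500), rng.normal(1, 0.05, 500)])
        modes = kde_mode_locations(x)
        locs = sorted(m[0] for m in modes[:2])
        assert abs(locs[0] - 0.0) < 0.05 and abs(locs[1] - 1.0) < 0.05
        # symmetric mixture → comparable heights
        h = [m[1] for m in modes[:2]]
        assert min(h) / max(h) > 0.8

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            kde_mode_locations([1.0, 2.0, 3.0])


class TestExcessMass:
    def test_unimodal_null_not_rejected(self):
        rng = np.random.default_rng(42)
        res = excess_mass_test(rng.standard_normal(500), k=1, n_boot=500, seed=7)
        assert 0.0 <= res["p_value"] <= 1.0
        assert res["p_value"] > 0.05

    def test_strong_bimodal_mixture_rejected(self):
        rng = np.random.default_rng(42)
        x = np.concatenate([rng.normal(0, 0.05, 250), rng.normal(1, 0.05, 250)])
        res = excess_mass_test(x, k=1, n_boot=500, seed=7)
        assert res["p_value"] < 0.05

    def test_mode_count_estimate_on_bimodal_mixture(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 0.05, 200), rng.normal(1, 0.05, 200)])
        k, results = estimate_mode_count(x, n_boot=200, seed=1)
        assert k == 2

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            excess_mass_test(np.ones(100), k=1)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_p_value_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(60)
        res = excess_mass_test(x, k=1, n_boot=50, seed=seed)
        assert 0.0 <= res["p_value"] <= 1.0


class TestModelTuning:
    def test_fc1_tuning_records_from_model_probing(self):
        # untrained base model, reduced ladder: the record bookkeeping per
        # unit is 2 sizes × n expressions, FC1 responses are ReLU outputs
        import snnface as sf
        from snnface.sf_analysis import unit_tuning_records
        from snnface.synthetic_data import generate_dataset
        from snnface.training import initialize_weights

        model = initialize_weights(
            sf.build_model(sf.preset("snn"), sf.enumerate_dog_bank()), 0
        )
        ds = generate_dataset(3, seed=0)
        faces = {
            e: [ds.base_images[i] for i in np.flatnonzero(ds.expression == e)]
            for e in ("happy", "sad")
        }
        grid = GRID[::15]  # 5 ladder values
        records = unit_tuning_records(model, faces, grid=grid)
        assert len(records) == 32 * 2 * 2  # units × expressions × sizes
        per_unit = [r for r in records if r.unit == 0]
        assert len(per_unit) == 4
        assert all(len(r.responses) == len(grid) for r in records)
        assert all(r.responses.min() >= 0 for r in records)  # post-ReLU

    def test_candidate_arithmetic_at_study_scale(self):
        # 20 models × 32 units × 7 expressions = 4480 (unit, expression)
        # candidate pairs before exclusion
        rng = np.random.default_rng(0)
        records = []
        for model_id in range(20):
            for unit in range(32):
                for expr in ("a", "b", "c", "d", "e", "f", "g"):
                    curve = np.exp(-((np.log2(GRID) - 3) ** 2)) + rng.normal(0, 0.01, 61)
                    for size in (198, 99):
                        records.append(
                            make_tuning_record(curve, unit, expr, size, model_id=model_id)
                        )
        shifts, _, book = peak_shift_distribution(records)
        assert book["candidates"] == 20 * 32 * 7 == 4480
        assert book["retained"] + book["excluded"] == 4480
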