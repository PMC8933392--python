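"""Normalization, two-Gaussian EM fitting and gate mapping."""

import numpy as np
import pandas as pd
import pytest

from histogate import (
    CycifSimParams,
    MarkerMixture,
    TwoGaussianGateModel,
    ValidationError,
    ZeroVarianceError,
    call_positive,
    fit_gmm2,
    gate_marker,
    normalize_intensities,
    simulate_intensity_table,
)
from histogate.gating import NormalizationTransforms


def _table(values, sample_ids=None, marker="m"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, len(values) + 1),
            "sample_id": sample_ids if sample_ids is not None else ["S1"] * len(values),
            marker: values,
        }
    )


class TestNormalization:
    def test_single_sample_shift_is_zero(self, rng):
        raw = rng.uniform(0, 1000, 200)
        normed, tr = normalize_intensities(_table(raw))
        assert tr.shifts["m"]["S1"] == 0.0
        assert np.allclose(normed["m"], np.log10(raw + 1))

    def test_generator_scale_shift_recovered(self):
        # fraction 0.3 keeps the median inside the negative mode, where it is
        # a stable location estimate (a 50/50 mixture's median sits in the
        # empty valley between modes and median alignment degrades there)
        params = CycifSimParams(
            n_cells_per_sample=2000, n_samples=2, sample_shifts=(0.0, 1.0),
            markers={"m": MarkerMixture(1.0, 3.0, 0.1, 0.3)}, seed=4,
        )
        table, _ = simulate_intensity_table(params)
        _, tr = normalize_intensities(table)
        estimated = tr.shifts["m"]["S1"] - tr.shifts["m"]["S2"]
        assert estimated == pytest.approx(1.0, abs=0.05)

    def test_round_trip_inversion(self, rng):
        raw = rng.uniform(0, 5000, 300)
        sample_ids = ["S1"] * 150 + ["S2"] * 150
        table = _table(raw, sample_ids)
        normed, tr = normalize_intensities(table)
        for sid in ("S1", "S2"):
            mask = table["sample_id"] == sid
            back = tr.inverse(normed.loc[mask, "m"], "m", sid)
            assert np.max(np.abs(back - raw[mask.to_numpy()])) < 1e-9

    def test_all_zero_sample_flagged_with_zero_shift(self):
        table = _table([0.0] * 50 + [10.0] * 50, ["S1"] * 50 + ["S2"] * 50)
        _, tr = normalize_intensities(table)
        assert ("m", "S1") in tr.flagged
        assert tr.shifts["m"]["S1"] == 0.0

    def test_negative_intensities_rejected(self):
        with pytest.raises(ValidationError):
            normalize_intensities(_table([-1.0, 2.0]))


class TestFitGmm2:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(1, 0.1, 2000), rng.normal(3, 0.1, 2000)])
        fit = fit_gmm2(x, seed=seed)
        assert 0.95 <= fit.means[0] <= 1.05
        assert 2.95 <= fit.means[1] <= 3.05
        assert 0.45 <= fit.weights[0] <= 0.55

    def test_loglik_nondecreasing_every_iteration(self, rng):
        x = np.concatenate([rng.normal(1, 0.2, 500), rng.normal(2.2, 0.2, 500)])
        fit = fit_gmm2(x, seed=0)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_components_ordered_by_mean(self, rng):
        x = np.concatenate([rng.normal(5, 0.3, 800), rng.normal(1, 0.3, 200)])
        fit = fit_gmm2(x, seed=2)
        assert fit.means[0] < fit.means[1]
        assert fit.weights[0] + fit.weights[1] == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        x = np.concatenate([rng.normal(1, 0.1, 300), rng.normal(3, 0.1, 300)])
        fit_a = fit_gmm2(x, seed=5)
        fit_b = fit_gmm2(rng.permutation(x), seed=5)
        assert fit_a.means == pytest.approx(fit_b.means, abs=1e-6)
        assert fit_a.weights == pytest.approx(fit_b.weights, abs=1e-6)

    def test_degenerate_tight_mode_plus_outliers(self, rng):
        x = np.concatenate([rng.normal(2.0, 0.01, 500), [8.0, 8.1, 7.9, 8.2, 8.05]])
        fit = fit_gmm2(x, seed=3)  # must not crash or collapse
        assert fit.weights[1] < 0.1
        assert min(fit.variances) >= 1e-6

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check of the EM against sklearn's GaussianMixture."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x = np.concatenate([rng.normal(1, 0.1, 2000), rng.normal(3, 0.1, 2000)])
        fit = fit_gmm2(x, seed=0)
        gm = sklearn.GaussianMixture(n_components=2, random_state=0, tol=1e-8).fit(
            x.reshape(-1, 1)
        )
        ref_means = np.sort(gm.means_.ravel())
        assert fit.means == pytest.approx(ref_means, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroVarianceError):
            fit_gmm2(np.ones(100))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_gmm2(np.arange(10.0))


class TestGateMapping:
    @staticmethod
    def _fit(mu2=3.0):
        from histogate.gating import GmmFit

        return GmmFit(
            marker="m", weights=(0.5, 0.5), means=(1.0, mu2), variances=(0.01, 0.01),
            n_iterations=10, log_likelihood=0.0, converged=True,
        )

    def test_zero_shift_maps_to_raw_999(self):
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.0}})
        gate = gate_marker(self._fit(), tr)
        assert gate.threshold_normalized == 3.0
        assert gate.threshold_raw_per_sample["S1"] == pytest.approx(999.0, abs=1e-9)

    def test_half_shift_maps_to_raw_315(self):
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.5}})
        gate = gate_marker(self._fit(), tr)
        expected = 10 ** 2.5 - 1  # 315.2277660168...
        assert gate.threshold_raw_per_sample["S1"] == pytest.approx(expected, abs=1e-9)

    def test_equal_shifts_give_identical_raw_thresholds(self):
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.0, "S2": 0.0}})
        gate = gate_marker(self._fit(), tr)
        assert (
            gate.threshold_raw_per_sample["S1"] == gate.threshold_raw_per_sample["S2"]
        )

    def test_nonconverged_fit_requires_force(self):
        from histogate.gating import GmmFit

        fit = GmmFit(
            marker="m", weights=(0.5, 0.5), means=(1.0, 3.0), variances=(0.01, 0.01),
            n_iterations=500, log_likelihood=0.0, converged=False,
        )
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.0}})
        with pytest.raises(ValidationError):
            gate_marker(fit, tr)
        assert gate_marker(fit, tr, force=True).threshold_normalized == 3.0


class TestCallPositive:
    def test_value_exactly_at_threshold_is_negative(self):
        table = _table([3.0, 3.0001, 2.0])
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.0}})
        gate = gate_marker(TestGateMapping._fit(), tr)
        calls = call_positive(table, gate)
        assert list(calls) == [False, True, False]

    def test_unknown_sample_rejected(self):
        table = _table([1.0], sample_ids=["S9"])
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.0}})
        gate = gate_marker(TestGateMapping._fit(), tr)
        with pytest.raises(ValidationError):
            call_positive(table, gate)

    def test_all_values_below_gate_yield_no_positives(self, rng):
        table = _table(rng.uniform(0, 1, 50))
        tr = NormalizationTransforms(shifts={"m": {"S1": 0.0}})
        gate = gate_marker(TestGateMapping._fit(), tr)
        assert not call_positive(table, gate).any()


class TestGateModelSurface:
    def test_peak_gate_calls_about_half_the_positive_component(self):
        """Gating at the positive component's peak discards its lower half by
        construction, so the called fraction is ~positive_fraction / 2 and
        must agree exactly with the brute-force rule norm > mu2."""
        params = CycifSimParams(
            n_cells_per_sample=5000, n_samples=1,
            markers={"m": MarkerMixture(1.0, 3.0, 0.1, 0.4)}, seed=7,
        )
        table, _ = simulate_intensity_table(params)
        model = TwoGaussianGateModel(table)
        res = model.fit(seed=0)
        calls = res.call_positive()
        mu2 = res.fits["m"].means[1]
        oracle = model.normalized["m"] > mu2
        assert (calls["m"] == oracle).all()
        assert calls["m"].mean() == pytest.approx(0.2, abs=0.02)

    def test_gate_invariant_to_sample_relabeling(self):
        params = CycifSimParams(
            n_cells_per_sample=1500, n_samples=2, sample_shifts=(0.0, 0.0),
            markers={"m": MarkerMixture(1.0, 3.0, 0.1, 0.5)}, seed=8,
        )
        table, _ = simulate_intensity_table(params)
        res_a = TwoGaussianGateModel(table).fit(seed=1)
        swapped = table.copy()
        swapped["sample_id"] = swapped["sample_id"].map({"S1": "S2", "S2": "S1"})
        res_b = TwoGaussianGateModel(swapped).fit(seed=1)
        assert res_a.gates["m"].threshold_normalized == pytest.approx(
            res_b.gates["m"].threshold_normalized, abs=1e-6
        )

    def test_summary_and_report(self):
        params = CycifSimParams(
            n_cells_per_sample=500, n_samples=1,
            markers={"p16": MarkerMixture(1.0, 3.0, 0.1, 0.5)}, seed=9,
        )
        table, _ = simulate_intensity_table(params)
        res = TwoGaussianGateModel(table).fit(seed=0)
        assert "p16" in res.summary()
        report = res.gate_report()
        assert report["p16"]["threshold_normalized"] == res.gates["p16"].threshold_normalized
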