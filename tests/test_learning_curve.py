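"""Exponential practice-curve fitting, cueing curves, SI, and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from ccdm.learning_curve import (
    EPOCHS,
    amplitude_ci,
    cc_curve,
    fit_exponential,
    scatter_index,
    scatter_index_from_values,
)

CELLS2 = [("uni", "old"), ("uni", "new")]


def curve(rt0, rta, alpha, n=EPOCHS):
    return rta + (rt0 - rta) * np.exp(-alpha * np.asarray(n, dtype=float))


def test_noiseless_recovery_is_exact():
    truth = {
        ("uni", "old"): (1300.0, 950.0, 0.5),
        ("uni", "new"): (1300.0, 1100.0, 0.8),
        ("msv", "old"): (1300.0, 900.0, 0.4),
    }
    data = {c: curve(*p) for c, p in truth.items()}
    fit = fit_exponential(data)
    assert fit.rt0 == pytest.approx(1300.0, rel=1e-6)
    for c, (rt0, rta, alpha) in truth.items():
        assert fit.rt_a[c] == pytest.approx(rta, rel=1e-6)
        assert fit.alpha[c] == pytest.approx(alpha, rel=1e-6)


def test_flat_data_gives_zero_amplitude():
    data = {c: np.full(8, 1000.0) for c in CELLS2}
    fit = fit_exponential(data)
    for c in CELLS2:
        assert fit.rt_a[c] == pytest.approx(1000.0, abs=1e-3)
        assert abs(fit.rt0 - fit.rt_a[c]) < 1e-2 or fit.alpha[c] > 5


def test_refit_on_own_predictions_is_fixed_point():
    data = {c: curve(1250.0, 1000.0 - 50 * i, 0.6 + 0.2 * i) for i, c in enumerate(CELLS2)}
    fit = fit_exponential(data)
    refit = fit_exponential({c: np.asarray(fit.predict(c, EPOCHS)) for c in CELLS2})
    assert refit.rt0 == pytest.approx(fit.rt0, abs=1e-6)
    for c in CELLS2:
        assert refit.rt_a[c] == pytest.approx(fit.rt_a[c], abs=1e-6)
        assert refit.alpha[c] == pytest.approx(fit.alpha[c], abs=1e-6)


def test_monte_carlo_amplitude_recovery_and_sign():
    """Noisy recovery: learning-magnitude error small, amplitude sign reliable."""
    rng = np.random.default_rng(17)
    rt0 = 1300.0
    truth = {("uni", "old"): (1000.0, 0.6), ("uni", "new"): (1100.0, 0.5)}
    mag_errors, signs = [], []
    for _ in range(200):
        data = {
            c: curve(rt0, rta, al) + rng.normal(0, 20, 8) for c, (rta, al) in truth.items()
        }
        fit = fit_exponential(data, n_starts=6)
        mag_errors.append(abs((rt0 - fit.rt_a[("uni", "old")]) - (rt0 - 1000.0)))
        amp = fit.rt_a[("uni", "new")] - fit.rt_a[("uni", "old")]
        signs.append(amp > 0)
    assert np.median(mag_errors) < 15.0
    assert np.mean(signs) >= 0.95  # true amplitude difference is 100 ms >= 60 ms


def test_cc_curve_zero_at_epoch_zero_and_amplitude():
    data = {
        ("uni", "old"): curve(1300.0, 1000.0, 0.7),
        ("uni", "new"): curve(1300.0, 1150.0, 0.7),
    }
    fit = fit_exponential(data)
    c = cc_curve(fit, "uni")
    assert c.values[0] == pytest.approx(0.0, abs=1e-6)
    assert c.amplitude == pytest.approx(150.0, rel=1e-6)
    # equal learning rates: curve(N) = amplitude * (1 - exp(-alpha N))
    expected = c.amplitude * (1.0 - np.exp(-0.7 * c.grid))
    assert np.allclose(c.values, expected, atol=1e-6)
    assert c(4.0) == pytest.approx(150.0 * (1 - np.exp(-2.8)), rel=1e-6)


def test_cc_curve_identical_cells_is_zero():
    data = {c: curve(1300.0, 1000.0, 0.5) for c in CELLS2}
    fit = fit_exponential(data)
    c = cc_curve(fit, "uni")
    assert abs(c.amplitude) < 1e-6
    assert np.allclose(c.values, 0.0, atol=1e-6)


def test_cc_curve_missing_cell_raises():
    data = {("uni", "old"): curve(1300.0, 1000.0, 0.5), ("msv", "old"): curve(1300.0, 990.0, 0.5)}
    fit = fit_exponential(data)
    with pytest.raises(KeyError):
        cc_curve(fit, "uni")


def test_amplitude_translation_invariance():
    base = {
        ("uni", "old"): curve(1300.0, 1000.0, 0.6),
        ("uni", "new"): curve(1300.0, 1120.0, 0.45),
    }
    fit0 = fit_exponential(base)
    shifted = {c: y + 500.0 for c, y in base.items()}
    fit1 = fit_exponential(shifted)
    a0 = cc_curve(fit0, "uni").amplitude
    a1 = cc_curve(fit1, "uni").amplitude
    assert a1 == pytest.approx(a0, abs=1e-5)


class TestScatterIndex:
    def test_perfect_fit_is_zero(self):
        data = {c: curve(1300.0, 1000.0, 0.5) for c in CELLS2}
        fit = fit_exponential(data)
        q = scatter_index(fit, data, cell=CELLS2[0])
        assert q.si_percent == pytest.approx(0.0, abs=1e-6)

    def test_constant_offset_case(self):
        observed = np.full(8, 1000.0)
        predicted = observed - 10.0
        q = scatter_index_from_values(predicted, observed)
        assert q.rmse == pytest.approx(10.0)
        assert q.si_percent == pytest.approx(1.0)

    def test_zero_mean_raises(self):
        with pytest.raises(ZeroDivisionError):
            scatter_index_from_values(np.zeros(4), np.zeros(4))


def _subject_epoch_table(rng, n_subjects, amp_new=120.0, noise=25.0):
    rows = []
    for s in range(n_subjects):
        for cfg, rta in (("old", 1000.0), ("new", 1000.0 + amp_new)):
            y = curve(1300.0, rta, 0.6) + rng.normal(0, noise, 8)
            for e, val in zip(range(1, 9), y):
                rows.append(
                    {
                        "subject": s,
                        "trial_type": "uni",
                        "configuration": cfg,
                        "epoch": e,
                        "rt_ms": val,
                    }
                )
    return pd.DataFrame(rows)


class TestAmplitudeCI:
    def test_degenerate_for_identical_subjects(self):
        rng = np.random.default_rng(0)
        one = _subject_epoch_table(np.random.default_rng(1), 1, noise=0.0)
        table = pd.concat(
            [one.assign(subject=s) for s in range(5)], ignore_index=True
        )
        ci = amplitude_ci(table, n_boot=120, seed=2)
        row = ci.iloc[0]
        assert row["ci_high"] - row["ci_low"] == pytest.approx(0.0, abs=1e-6)
        assert row["ci_low"] <= row["amplitude_ms"] <= row["ci_high"]

    def test_interval_orders_around_point_estimate(self):
        table = _subject_epoch_table(np.random.default_rng(3), 10)
        ci = amplitude_ci(table, n_boot=150, seed=4)
        row = ci.iloc[0]
        assert row["ci_low"] <= row["amplitude_ms"] <= row["ci_high"]
        assert row["ci_low"] < row["ci_high"]

    def test_warns_for_tiny_bootstrap(self):
        table = _subject_epoch_table(np.random.default_rng(5), 4)
        with pytest.warns(UserWarning):
            amplitude_ci(table, n_boot=50, seed=6)

    def test_null_coverage(self):
        """CI contains 0 for most replicates generated without a cueing effect."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            table = _subject_epoch_table(rng, 10, amp_new=0.0, noise=20.0)
            ci = amplitude_ci(table, n_boot=120, seed=8, n_starts=2)
            row = ci.iloc[0]
            hits += row["ci_low"] <= 0.0 <= row["ci_high"]
        assert hits / n_rep >= 0.85
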