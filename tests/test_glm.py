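import numpy as np
import pytest

from emofmri.design_io import MotionParams
from emofmri.glm import (MICROTIME_BINS, DesignMatrix, FirstLevelGLM,
                         build_model1_design, build_model2_design,
                         canonical_hrf, compute_contrast, convolve_and_sample,
                         dct_basis, dct_highpass, fit_glm, microtime_grid)
from emofmri.synthetic import (NoiseModel, SimulationConfig, _ar1_noise,
                               simulate_events, simulate_subject)


# ---------------------------------------------------------------------- HRF

def test_hrf_peak_near_five_seconds():
    hrf = canonical_hrf(0.125)
    t_peak = np.argmax(hrf.values) * 0.125
    assert abs(t_peak - 5.0) <= 0.5


def test_hrf_zero_at_origin_and_undershoot_after_peak():
    hrf = canonical_hrf(0.125)
    assert hrf.values[0] == 0.0
    assert np.argmin(hrf.values) > np.argmax(hrf.values)
    assert hrf.values.min() < 0.0


def test_hrf_positive_lobe_unit_sum():
    hrf = canonical_hrf(0.125)
    assert np.sum(hrf.values[hrf.values > 0]) == pytest.approx(1.0)


def test_hrf_rejects_bad_dt():
    with pytest.raises(ValueError):
        canonical_hrf(0.0)


# ------------------------------------------------------------------ designs

def test_model1_column_count(default_events, zero_motion):
    d = build_model1_design(default_events, zero_motion, 470, 2.0)
    assert d.k == 11  # 3 task + press + 6 motion + constant
    assert d.column_roles.count("task") == 3


def test_model2_column_count_and_centering(default_events, zero_motion):
    d = build_model2_design(default_events, zero_motion, 470, 2.0)
    assert d.k == 11  # mean + 2 modulators + press + 6 motion + constant
    # centered modulator is orthogonal to the mean column before convolution:
    # both share the same epochs, so their unconvolved correlation is the
    # correlation between 1 and the centered ratings = 0
    ratings = np.array([t.valence_rating for t in default_events], float)
    assert abs(np.mean(ratings - ratings.mean())) < 1e-12


def test_model2_constant_ratings_flagged(default_events, zero_motion):
    from dataclasses import replace

    trials = [replace(t, valence_rating=5) for t in default_events]
    from emofmri.design_io import EventTable
    ev = EventTable(trials=trials)
    d = build_model2_design(ev, zero_motion, 470, 2.0)
    col = d.matrix[:, d.column_index("valence_mod")]
    np.testing.assert_allclose(col, 0.0, atol=1e-12)
    assert any("valence" in w for w in d.warnings_)


def test_no_button_presses_flagged(zero_motion):
    from dataclasses import replace

    cfg = SimulationConfig(n_parcels=2)
    ev = simulate_events(cfg, np.random.default_rng(0))
    from emofmri.design_io import EventTable
    ev = EventTable(trials=[replace(t, button_press_times_s=()) for t in ev])
    d = build_model1_design(ev, zero_motion, 470, 2.0)
    np.testing.assert_allclose(d.matrix[:, d.column_index("press")], 0.0)
    assert any("press" in w for w in d.warnings_)


def test_convolved_column_matches_bruteforce(default_events, zero_motion):
    """The NEG design column equals direct full convolution + sampling."""
    hrf = canonical_hrf(2.0 / MICROTIME_BINS)
    d = build_model1_design(default_events, zero_motion, 470, 2.0, hrf=hrf)
    times = microtime_grid(470, 2.0)
    neural = np.zeros_like(times)
    for t in default_events:
        if t.category == "NEG":
            neural[(times >= t.onset_s)
                   & (times < t.onset_s + t.picture_duration_s)] = 1.0
    brute = np.array([
        sum(neural[i - j] * hrf.values[j]
            for j in range(min(i + 1, hrf.values.size)))
        for i in np.arange(470) * MICROTIME_BINS + MICROTIME_BINS // 2])
    np.testing.assert_allclose(d.matrix[:, d.column_index("NEG")], brute,
                               atol=1e-8)


def test_convolution_linearity(default_events, zero_motion):
    """Designs are linear in the neural signal: summed neural input gives
    the summed columns."""
    hrf = canonical_hrf(2.0 / MICROTIME_BINS)
    times = microtime_grid(470, 2.0)
    rng = np.random.default_rng(1)
    a, b = rng.normal(size=times.size), rng.normal(size=times.size)
    lhs = convolve_and_sample(a + b, hrf, 470)
    rhs = convolve_and_sample(a, hrf, 470) + convolve_and_sample(b, hrf, 470)
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


# ----------------------------------------------------------------- highpass

@pytest.mark.parametrize("phase", [0.0, 0.7, 1.57, 2.5])
def test_highpass_removes_drift_period(phase):
    """The amplitude of a 128 s drift remaining after filtering is < 5%,
    whatever its phase (measured by refitting the drift sinusoid)."""
    t = np.arange(470) * 2.0
    drift = np.sin(2 * np.pi * t / 128.0 + phase)
    filtered = dct_highpass(drift, tr_s=2.0)
    F = np.column_stack([np.sin(2 * np.pi * t / 128.0),
                         np.cos(2 * np.pi * t / 128.0)])
    c, *_ = np.linalg.lstsq(F, filtered, rcond=None)
    assert np.hypot(*c) < 0.05


def test_highpass_variance_reduction_matches_projection_rank():
    rng = np.random.default_rng(2)
    n = 470
    x = rng.normal(size=(n, 200))
    k = dct_basis(n, 2.0, 1.0 / 128.0).shape[1]
    filtered = dct_highpass(x, tr_s=2.0)
    reduction = 1.0 - filtered.var() / x.var()
    assert reduction == pytest.approx(k / n, abs=0.01)


def test_highpass_keeps_constant():
    const = np.full(470, 3.7)
    np.testing.assert_allclose(dct_highpass(const, tr_s=2.0), const,
                               atol=1e-9)


def test_highpass_rejects_cutoff_above_nyquist():
    with pytest.raises(ValueError):
        dct_highpass(np.zeros(100), tr_s=2.0, cutoff_hz=0.3)


# -------------------------------------------------------------------- fitting

def _null_design(n=470, k_extra=3, seed=0):
    rng = np.random.default_rng(seed)
    mat = np.column_stack([rng.normal(size=(n, k_extra)), np.ones(n)])
    names = [f"x{i}" for i in range(k_extra)] + ["constant"]
    roles = ["task"] * k_extra + ["constant"]
    return dct_highpass(DesignMatrix(mat, names, roles, tr_s=2.0))


def test_noise_free_recovery_is_exact(zero_motion):
    cfg = SimulationConfig(n_parcels=2, seed_neural_sd=0.0,
                           noise=NoiseModel(white_sd=0.0, drift_amplitude=0.0))
    rng = np.random.default_rng(3)
    ev = simulate_events(cfg, rng)
    ts, _ = simulate_subject(cfg, ev, "HC", rng)
    d = dct_highpass(build_model1_design(ev, zero_motion, 470, 2.0))
    fit = fit_glm(d, dct_highpass(ts).data[1])
    # planted: uniform task amplitude 1 per category, press amplitude 0.5
    for cat in ("NEG", "NEU", "POS"):
        assert fit.betas[d.column_index(cat)] == pytest.approx(1.0, abs=1e-6)
    assert fit.betas[d.column_index("press")] == pytest.approx(0.5, abs=1e-6)


def test_ar1_rho_estimated_within_band():
    nm = NoiseModel(white_sd=1.0, ar1_coefficient=0.4, drift_amplitude=0.0)
    noise = _ar1_noise(np.random.default_rng(11), (470, 10), nm)
    fit = fit_glm(_null_design(), dct_highpass(noise, tr_s=2.0))
    assert 0.3 <= fit.rho <= 0.5


def test_prewhitened_residuals_are_white():
    from emofmri.glm import _whiten

    nm = NoiseModel(white_sd=1.0, ar1_coefficient=0.4, drift_amplitude=0.0)
    noise = _ar1_noise(np.random.default_rng(13), (470, 10), nm)
    d = _null_design()
    fit = fit_glm(d, dct_highpass(noise, tr_s=2.0))
    Xw = _whiten(d.matrix[:, d.estimable()], fit.rho)
    Yw = _whiten(dct_highpass(noise, tr_s=2.0), fit.rho)
    resid = Yw - Xw @ np.linalg.lstsq(Xw, Yw, rcond=None)[0]
    r = np.mean([np.corrcoef(resid[1:, j], resid[:-1, j])[0, 1]
                 for j in range(resid.shape[1])])
    assert abs(r) < 0.1


def test_gls_with_rho_zero_equals_ols():
    rng = np.random.default_rng(4)
    d = _null_design()
    y = rng.normal(size=(470, 5))
    from emofmri.glm import _whiten

    ols = np.linalg.lstsq(d.matrix, y, rcond=None)[0]
    gls = np.linalg.lstsq(_whiten(d.matrix, 0.0), _whiten(y, 0.0), rcond=None)[0]
    np.testing.assert_allclose(ols, gls, atol=1e-12)


def test_contrast_recovery_and_identities(zero_motion):
    cfg = SimulationConfig(n_parcels=3, seed=8, effects=[])
    from emofmri.synthetic import PlantedEffect

    cfg.effects = [PlantedEffect(kind="category_amplitude", parcel_ids=(2,),
                                 group="HC", magnitude=0.7)]
    rng = np.random.default_rng(8)
    ev = simulate_events(cfg, rng)
    ts, mo = simulate_subject(cfg, ev, "HC", rng)
    d = dct_highpass(build_model1_design(ev, mo, 470, 2.0))
    res = FirstLevelGLM(dct_highpass(ts).data[2], d).fit()
    c = res.contrast({"NEG": 1.0, "NEU": -1.0}, name="dBR_N")
    assert np.mean(c.values) == pytest.approx(0.7, abs=0.25)
    zero = res.contrast(np.zeros(d.k))
    np.testing.assert_array_equal(zero.values, 0.0)


def test_contrast_on_null_data_centered_at_zero():
    rng = np.random.default_rng(9)
    d = _null_design()
    fits = fit_glm(d, dct_highpass(rng.normal(size=(470, 200)), tr_s=2.0))
    vals = compute_contrast(fits, [1.0, -1.0, 0.0, 0.0]).values
    assert abs(np.mean(vals)) < 3 * np.std(vals, ddof=1) / np.sqrt(vals.size)


def test_contrast_rejects_nonestimable_column(zero_motion, default_events):
    from dataclasses import replace
    from emofmri.design_io import EventTable

    ev = EventTable(trials=[replace(t, button_press_times_s=())
                            for t in default_events])
    d = dct_highpass(build_model1_design(ev, zero_motion, 470, 2.0))
    fit = fit_glm(d, np.random.default_rng(0).normal(size=(470, 2)))
    w = np.zeros(d.k)
    w[d.column_index("press")] = 1.0
    with pytest.raises(ValueError, match="non-estimable"):
        compute_contrast(fit, w)


def test_parameter_recovery_of_small_contrast():
    """Mean estimated dBR_N over 100 noisy parcels within 0.03 of the
    planted 0.15 (comparable to the patient-group effect scale)."""
    from emofmri.synthetic import PlantedEffect

    cfg = SimulationConfig(
        n_parcels=100, seed=15,
        effects=[PlantedEffect(kind="category_amplitude",
                               parcel_ids=tuple(range(1, 101)),
                               group="BOTH", magnitude=0.15)])
    rng = np.random.default_rng(15)
    ev = simulate_events(cfg, rng)
    ts, mo = simulate_subject(cfg, ev, "HC", rng)
    d = dct_highpass(build_model1_design(ev, mo, 470, 2.0))
    tsf = dct_highpass(ts)
    estimates = [float(np.median(
        FirstLevelGLM(tsf.data[pid], d).fit()
        .contrast({"NEG": 1.0, "NEU": -1.0}).values))
        for pid in tsf.parcel_ids]
    assert abs(np.mean(estimates) - 0.15) < 0.03
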