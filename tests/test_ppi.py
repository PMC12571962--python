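import numpy as np
import pytest

from emofmri.design_io import MotionParams, ParcelTimeSeries
from emofmri.glm import (MICROTIME_BINS, canonical_hrf, convolve_and_sample,
                         dct_highpass, microtime_grid)
from emofmri.ppi import (SeedSignal, build_ppi_design, deconvolve_bold,
                         estimate_fc_contrasts, extract_eigenvariate,
                         hrf_cutoff_frequency)
from emofmri.synthetic import (PlantedEffect, SimulationConfig,
                               simulate_events, simulate_subject)

HRF = canonical_hrf(2.0 / MICROTIME_BINS)


# ------------------------------------------------------------- eigenvariate

def test_single_voxel_parcel_identity():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(200, 1))
    ts = ParcelTimeSeries(data={1: v}, tr_s=2.0)
    seed = extract_eigenvariate(ts, 1)
    centered = v[:, 0] - v[:, 0].mean()
    scaled = centered / centered.std(ddof=1) * centered.std(ddof=1)
    np.testing.assert_allclose(seed.eigenvariate, scaled, atol=1e-9)
    assert seed.explained_variance == pytest.approx(1.0)


def test_identical_voxels_explain_everything():
    rng = np.random.default_rng(1)
    col = rng.normal(size=200)
    ts = ParcelTimeSeries(data={1: np.tile(col[:, None], (1, 8))}, tr_s=2.0)
    assert extract_eigenvariate(ts, 1).explained_variance == pytest.approx(1.0)


def test_explained_variance_matches_svd_oracle():
    rng = np.random.default_rng(2)
    arr = rng.normal(size=(150, 6)) + np.outer(rng.normal(size=150),
                                               rng.normal(size=6))
    ts = ParcelTimeSeries(data={1: arr}, tr_s=2.0)
    seed = extract_eigenvariate(ts, 1)
    s = np.linalg.svd(arr - arr.mean(axis=0), compute_uv=False)
    assert seed.explained_variance == pytest.approx(s[0] ** 2 / np.sum(s ** 2))


def test_zero_variance_parcel_rejected():
    ts = ParcelTimeSeries(data={1: np.ones((50, 3))}, tr_s=2.0)
    with pytest.raises(ValueError, match="zero variance"):
        extract_eigenvariate(ts, 1)


# ------------------------------------------------------------- deconvolution

def test_deconvolve_reconvolve_round_trip():
    """Boxcar neural signal -> BOLD -> deconvolved -> reconvolved BOLD
    agrees with the original within 5% relative RMS (noise-free)."""
    from emofmri.glm import _boxcar

    n_vol = 200
    times = microtime_grid(n_vol, 2.0)
    onsets = np.arange(10.0, 380.0, 24.0)
    neural = _boxcar(times, onsets, [6.0] * len(onsets))
    y = convolve_and_sample(neural, HRF, n_vol)
    z = deconvolve_bold(y, HRF, n_volumes=n_vol, tr_s=2.0)
    y_back = convolve_and_sample(z, HRF, n_vol)
    rel = np.sqrt(np.mean((y_back - y) ** 2) / np.mean(y ** 2))
    assert rel < 0.05


def test_deconvolve_zero_gives_zero():
    z = deconvolve_bold(np.zeros(100), HRF, tr_s=2.0)
    np.testing.assert_allclose(z, 0.0, atol=1e-12)


def test_ridge_limit_confines_estimate_to_pass_band():
    """Growing the ridge weight shrinks the estimate monotonically in norm
    and drives its content above the HRF cutoff to zero (the penalty is
    band-limited, so the sub-cutoff part survives by design)."""
    rng = np.random.default_rng(3)
    y = rng.normal(size=120)
    n_vol = y.size
    zs = {lam: deconvolve_bold(y, HRF, tr_s=2.0, regularization=lam)
          for lam in (1e-3, 1e-1, 1e1, 1e6)}
    # rebuild the DCT coordinates of each estimate (basis is orthonormal)
    import math as _math

    n_micro = n_vol * 16
    k = np.arange(n_micro)
    j = np.arange(n_vol)
    D = np.cos(_math.pi * np.outer(2 * k + 1, j) / (2 * n_micro))
    D /= np.linalg.norm(D, axis=0)
    freqs = j / (2.0 * n_micro * HRF.dt_s)
    f3 = hrf_cutoff_frequency(HRF)
    penalized = freqs > f3
    hi_energy = [float(np.sum((D.T @ zs[lam])[penalized] ** 2))
                 for lam in (1e-3, 1e-1, 1e1, 1e6)]
    assert all(a >= b - 1e-12 for a, b in zip(hi_energy, hi_energy[1:]))
    assert hi_energy[-1] < 1e-6 * hi_energy[0]


def test_hrf_cutoff_is_low_pass():
    f3 = hrf_cutoff_frequency(HRF)
    assert 0.03 < f3 < 0.15  # seconds-scale hemodynamics


# ------------------------------------------------------------------- design

def _small_ppi_setup(seed=0, effects=(), n_parcels=4, seed_parcel=3):
    cfg = SimulationConfig(n_parcels=n_parcels, seed_parcels=(seed_parcel,),
                           effects=list(effects), seed=seed)
    rng = np.random.default_rng(seed)
    ev = simulate_events(cfg, rng)
    ts, mo = simulate_subject(cfg, ev, "HC", rng)
    tsf = dct_highpass(ts)
    return cfg, ev, tsf, mo


def test_ppi_design_has_fourteen_columns():
    _, ev, tsf, mo = _small_ppi_setup()
    seed = extract_eigenvariate(tsf, 3)
    d = build_ppi_design(ev, seed, mo, 470, 2.0)
    assert d.k == 14
    assert d.column_roles.count("ppi") == 2
    assert d.column_roles.count("seed") == 1
    assert {"ppi_NEG-NEU", "ppi_POS-NEU"} <= set(d.column_names)


def test_zero_seed_gives_zero_ppi_columns():
    _, ev, tsf, mo = _small_ppi_setup()
    seed = SeedSignal(parcel_id=3, eigenvariate=np.zeros(470),
                      explained_variance=1.0)
    d = build_ppi_design(ev, seed, mo, 470, 2.0)
    for name in ("ppi_NEG-NEU", "ppi_POS-NEU"):
        np.testing.assert_allclose(d.matrix[:, d.column_index(name)], 0.0,
                                   atol=1e-12)


def test_ppi_beta_scales_inversely_with_seed_rescaling():
    """Rescaling the eigenvariate by c > 0 rescales the PPI beta by 1/c
    (the estimator is linear, so this holds to machine precision)."""
    _, ev, tsf, mo = _small_ppi_setup(seed=4)
    seed = extract_eigenvariate(tsf, 3)
    c = 2.5
    seed_scaled = SeedSignal(parcel_id=3,
                             eigenvariate=c * seed.eigenvariate,
                             explained_variance=seed.explained_variance)
    lam = 1e-3
    d1 = dct_highpass(build_ppi_design(ev, seed, mo, 470, 2.0,
                                       regularization=lam))
    d2 = dct_highpass(build_ppi_design(ev, seed_scaled, mo, 470, 2.0,
                                       regularization=lam))
    fc1 = estimate_fc_contrasts(d1, tsf, 3)
    fc2 = estimate_fc_contrasts(d2, tsf, 3)
    for pid in fc1.values:
        np.testing.assert_allclose(fc2.values[pid], fc1.values[pid] / c,
                                   rtol=1e-6, atol=1e-10)


def test_missing_category_rejected():
    from emofmri.design_io import EventTable

    _, ev, tsf, mo = _small_ppi_setup()
    seed = extract_eigenvariate(tsf, 3)
    ev_no_neg = EventTable(trials=[t for t in ev if t.category != "NEG"])
    with pytest.raises(ValueError, match="missing"):
        build_ppi_design(ev_no_neg, seed, mo, 470, 2.0)


def test_seed_excluded_from_targets():
    _, ev, tsf, mo = _small_ppi_setup(seed=6)
    seed = extract_eigenvariate(tsf, 3)
    d = dct_highpass(build_ppi_design(ev, seed, mo, 470, 2.0))
    fc = estimate_fc_contrasts(d, tsf, 3)
    assert 3 not in fc.values
    assert set(fc.values) == {1, 2, 4}


def test_left_seed_analysis_independent_of_right():
    cfg = SimulationConfig(n_parcels=6, seed_parcels=(3, 5), seed=9)
    rng = np.random.default_rng(9)
    ev = simulate_events(cfg, rng)
    ts, mo = simulate_subject(cfg, ev, "HC", rng)
    tsf = dct_highpass(ts)
    seed3 = extract_eigenvariate(tsf, 3)
    d3 = dct_highpass(build_ppi_design(ev, seed3, mo, 470, 2.0))
    fc_a = estimate_fc_contrasts(d3, tsf, 3)
    # re-running after the right-seed analysis changes nothing
    seed5 = extract_eigenvariate(tsf, 5)
    d5 = dct_highpass(build_ppi_design(ev, seed5, mo, 470, 2.0))
    estimate_fc_contrasts(d5, tsf, 5)
    fc_b = estimate_fc_contrasts(d3, tsf, 3)
    for pid in fc_a.values:
        np.testing.assert_array_equal(fc_a.values[pid], fc_b.values[pid])


def test_planted_ppi_gain_recovered_with_positive_sign():
    """Across simulated runs, a planted seed-by-condition gain of one noise
    SD yields a positive dFC estimate in the target parcel."""
    eff = PlantedEffect(kind="ppi_gain", parcel_ids=(2,), group="BOTH",
                        magnitude=1.0, seed_parcel=3)
    hits = 0
    n_sim = 20
    for s in range(n_sim):
        _, ev, tsf, mo = _small_ppi_setup(seed=100 + s, effects=[eff])
        seed = extract_eigenvariate(tsf, 3)
        d = dct_highpass(build_ppi_design(ev, seed, mo, 470, 2.0))
        fc = estimate_fc_contrasts(d, tsf, 3)
        hits += float(np.mean(fc.values[2])) > 0
    assert hits >= 19  # sign recovery in >= 95% of runs
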