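"""Psychophysiological-interaction (PPI) connectivity model.

Pipeline per seed (left or right amygdala parcel):

1. extract the seed's first eigenvariate from its high-pass-filtered voxel
   time series;
2. deconvolve the BOLD eigenvariate into a microtime "neural" estimate by
   ridge regression on a discrete-cosine basis (frequency-weighted penalty,
   the working approximation to the empirical-Bayes deconvolution of the
   classic PPI literature);
3. multiply the neural estimate with centered psychological vectors for the
   NEG-NEU and POS-NEU contrasts, reconvolve with the HRF, and assemble a
   design holding task, seed, two PPI, press, motion and constant columns
   (K = 14);
4. fit every target parcel with the same AR(1)-ReML GLM engine; the
   connectivity modulation dFC = FC_NEG - FC_NEU is the NEG-NEU PPI beta.

Forming the interaction at the neural level before convolution — rather
than multiplying BOLD signals — is the defining feature of deconvolution
PPI and matches how the synthetic generator plants its ``ppi_gain`` ground
truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .design_io import EventTable, MotionParams, ParcelTimeSeries
from .glm import (DesignMatrix, GLMFit, HRFKernel, MICROTIME_BINS,
                  canonical_hrf, convolve_and_sample, fit_glm,
                  microtime_grid, _boxcar, _common_columns)

__all__ = ["SeedSignal", "FCContrast", "extract_eigenvariate",
           "deconvolve_bold", "build_ppi_design", "estimate_fc_contrasts",
           "hrf_cutoff_frequency"]


@dataclass(frozen=True)
class SeedSignal:
    """First eigenvariate of a seed parcel, scaled to the mean voxel SD."""

    parcel_id: int
    eigenvariate: np.ndarray
    explained_variance: float

    def __post_init__(self) -> None:
        if not (0.0 < self.explained_variance <= 1.0 + 1e-12):
            raise ValueError("explained variance must lie in (0, 1]")


@dataclass
class FCContrast:
    """Per-parcel seed connectivity modulation (PPI beta per voxel)."""

    seed_id: int
    contrast: str                      # "NEG-NEU" or "POS-NEU"
    values: dict[int, np.ndarray]      # parcel id -> voxel values

    def __post_init__(self) -> None:
        if self.seed_id in self.values:
            raise ValueError("seed parcel must be excluded from targets")


def extract_eigenvariate(parcel_ts: ParcelTimeSeries, seed_id: int) -> SeedSignal:
    """First left singular vector of the centered time x voxel matrix.

    The sign is aligned to correlate positively with the parcel mean and
    the series is rescaled to the mean voxel SD, so downstream betas keep
    signal units.
    """
    arr = parcel_ts.data[seed_id]
    centered = arr - arr.mean(axis=0, keepdims=True)
    sds = centered.std(axis=0, ddof=1)
    if np.all(sds == 0.0):
        raise ValueError(f"seed parcel {seed_id} has zero variance")
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    eig = u[:, 0]
    mean_series = centered.mean(axis=1)
    if np.dot(eig, mean_series) < 0:
        eig = -eig
    eig_sd = eig.std(ddof=1)
    eig = eig * (float(sds.mean()) / eig_sd)
    explained = float(s[0] ** 2 / np.sum(s ** 2))
    return SeedSignal(parcel_id=seed_id, eigenvariate=eig,
                      explained_variance=explained)


def hrf_cutoff_frequency(hrf: HRFKernel) -> float:
    """-3 dB frequency of the HRF's amplitude response, in Hz."""
    n_fft = max(4096, 2 * hrf.values.size)
    amp = np.abs(np.fft.rfft(hrf.values, n_fft))
    freqs = np.fft.rfftfreq(n_fft, hrf.dt_s)
    half = amp[0] / math.sqrt(2.0)
    below = np.nonzero(amp < half)[0]
    return float(freqs[below[0]]) if below.size else float(freqs[-1])


def _dct_columns(n: int) -> np.ndarray:
    k = np.arange(n)
    j = np.arange(n)
    basis = np.cos(math.pi * np.outer(2 * k + 1, j) / (2 * n))
    return basis / np.linalg.norm(basis, axis=0)


def deconvolve_bold(seed_signal: SeedSignal | np.ndarray, hrf: HRFKernel,
                    n_volumes: int | None = None, tr_s: float = 2.0,
                    regularization: float | None = None) -> np.ndarray:
    """Estimate the microtime neural series driving an observed BOLD series.

    Solves ``min_z ||B z - y||^2 + lambda * z' P z`` where ``B`` convolves a
    microtime series with the HRF and samples volume midpoints, ``z`` is
    parameterized on a discrete-cosine basis with one coefficient per
    volume, and ``P`` leaves frequencies up to the HRF's -3 dB cutoff
    unpenalized and grows quadratically with the excess frequency above
    it.  The default ``lambda`` is 10% of the data-term curvature at the
    cutoff-frequency coefficient.
    """
    y = seed_signal.eigenvariate if isinstance(seed_signal, SeedSignal) else \
        np.asarray(seed_signal, dtype=float)
    n_vol = n_volumes or y.shape[0]
    if y.shape[0] != n_vol:
        raise ValueError("BOLD series length must equal n_volumes")
    n_micro = n_vol * MICROTIME_BINS
    dt = tr_s / MICROTIME_BINS
    if abs(hrf.dt_s - dt) > 1e-9:
        raise ValueError("HRF must be sampled at the run's microtime step")

    # DCT coefficients of the microtime neural series, one per volume
    k = np.arange(n_micro)
    j = np.arange(n_vol)
    D = np.cos(math.pi * np.outer(2 * k + 1, j) / (2 * n_micro))
    D /= np.linalg.norm(D, axis=0)
    freqs = j / (2.0 * n_micro * dt)

    from scipy.signal import fftconvolve
    conv = fftconvolve(D, hrf.values[:, None], axes=0)[:n_micro]
    rows = np.arange(n_vol) * MICROTIME_BINS + MICROTIME_BINS // 2
    A = conv[rows]

    f3db = hrf_cutoff_frequency(hrf)
    # frequencies the HRF passes are left untouched; above the -3 dB cutoff
    # the penalty grows quadratically with the excess frequency
    P = np.clip(freqs / f3db - 1.0, 0.0, None) ** 2
    AtA = A.T @ A
    if regularization is None:
        # anchored at 10% of the data-term curvature at the cutoff column
        j3 = int(np.argmin(np.abs(freqs - f3db)))
        regularization = 0.1 * float(AtA[j3, j3])
    lam = float(regularization)
    for attempt in range(6):
        try:
            c = np.linalg.solve(AtA + lam * np.diag(P) + 1e-12 * np.eye(n_vol),
                                A.T @ y)
            break
        except np.linalg.LinAlgError:  # pragma: no cover - pathological
            lam *= 10.0
    return D @ c


def _psych_vector(events: EventTable, times: np.ndarray,
                  plus: str, minus: str) -> np.ndarray:
    """+1/-1 condition vector at microtime, centered over modeled epochs."""
    vec = np.zeros_like(times)
    for t in events:
        if t.category in (plus, minus):
            sel = (times >= t.onset_s) & (times < t.onset_s + t.picture_duration_s)
            vec[sel] = 1.0 if t.category == plus else -1.0
    occupied = vec != 0.0
    if not occupied.any():
        raise ValueError(f"no {plus}/{minus} epochs in the event table")
    vec[occupied] -= vec[occupied].mean()
    return vec


def build_ppi_design(events: EventTable, seed_signal: SeedSignal,
                     motion: MotionParams, n_volumes: int, tr_s: float,
                     hrf: HRFKernel | None = None,
                     regularization: float | None = None) -> DesignMatrix:
    """Model 3 design: task x3, seed, PPI x2, press, motion x6, constant."""
    hrf = hrf or canonical_hrf(tr_s / MICROTIME_BINS)
    times = microtime_grid(n_volumes, tr_s)
    counts = events.category_counts()
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"categories missing from events: {missing}")

    cols, names, roles = [], [], []
    for cat in ("NEG", "NEU", "POS"):
        sub = [t for t in events if t.category == cat]
        neural = _boxcar(times, [t.onset_s for t in sub],
                         [t.picture_duration_s for t in sub])
        cols.append(convolve_and_sample(neural, hrf, n_volumes))
        names.append(cat)
        roles.append("task")

    # the observed eigenvariate enters directly; only the PPI terms use the
    # deconvolved neural estimate
    cols.append(np.asarray(seed_signal.eigenvariate, dtype=float))
    names.append(f"seed_{seed_signal.parcel_id}")
    roles.append("seed")

    z = deconvolve_bold(seed_signal, hrf, n_volumes=n_volumes, tr_s=tr_s,
                        regularization=regularization)
    for plus in ("NEG", "POS"):
        p = _psych_vector(events, times, plus, "NEU")
        cols.append(convolve_and_sample(z * p, hrf, n_volumes))
        names.append(f"ppi_{plus}-NEU")
        roles.append("ppi")

    c2, n2, r2, warn = _common_columns(events, motion, times, hrf, n_volumes)
    return DesignMatrix(np.column_stack(cols + c2), names + n2, roles + r2,
                        tr_s=tr_s, warnings_=warn)


def estimate_fc_contrasts(ppi_design: DesignMatrix,
                          parcel_ts: ParcelTimeSeries, seed_id: int,
                          contrast: str = "NEG-NEU") -> FCContrast:
    """Fit the PPI GLM in every non-seed parcel; dFC = the PPI beta."""
    col = ppi_design.column_index(f"ppi_{contrast}")
    values: dict[int, np.ndarray] = {}
    for pid in parcel_ts.parcel_ids:
        if pid == seed_id:
            continue
        fit = fit_glm(ppi_design, parcel_ts.data[pid])
        values[pid] = fit.betas[col]
    return FCContrast(seed_id=seed_id, contrast=contrast, values=values)
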