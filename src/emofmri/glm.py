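"""First-level GLM engine: HRF convolution, design construction, high-pass
filtering, AR(1)-ReML estimation and linear contrasts.

Two task models are built from the same event table:

* Model 1 ("category"): one 6 s boxcar regressor per picture category
  (NEG, NEU, POS) with uniform amplitude;
* Model 2 ("parametric"): a mean picture-period boxcar plus two
  parametrically modulated boxcars whose per-trial amplitudes are the
  subject-mean-centered valence and arousal ratings (not orthogonalized
  against each other).

Both add one stick regressor per button press, six motion regressors and a
constant.  Neural (microtime) signals are convolved with the canonical
double-gamma HRF and sampled at the middle microtime bin of each volume.
Low-frequency drifts are removed by projecting out a discrete-cosine basis
up to the cutoff (default 1/128 Hz) from data and design alike; serial
correlation is modeled as AR(1) with the coefficient estimated by
restricted maximum likelihood pooled over a parcel's voxels, followed by
generalized least squares on the prewhitened system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, special

from .design_io import EventTable, MotionParams, ValidationError

__all__ = [
    "HRFKernel", "DesignMatrix", "GLMFit", "ContrastResult",
    "canonical_hrf", "MICROTIME_BINS", "microtime_grid", "convolve_and_sample",
    "build_model1_design", "build_model2_design",
    "dct_highpass", "dct_basis",
    "fit_glm", "compute_contrast",
    "FirstLevelGLM", "GLMResults",
    "CONTRASTS_MODEL1",
]

#: microtime bins per TR used for convolution; sampling at the middle bin.
MICROTIME_BINS = 16


@dataclass(frozen=True)
class HRFKernel:
    """Sampled canonical HRF at microtime resolution ``dt_s``."""

    dt_s: float
    values: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HRF kernel contains non-finite values")


def canonical_hrf(dt_s: float, duration_s: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> HRFKernel:
    """Double-gamma canonical HRF.

    Difference of two gamma densities (peak mode ~5 s, undershoot ~15 s),
    scaled so the positive lobe sums to one — convolving a unit boxcar of
    one bin then yields a response whose positive mass equals the neural
    amplitude.
    """
    if not (0.0 < dt_s <= 1.0):
        raise ValueError("microtime step must lie in (0, 1] seconds")
    t = np.arange(0.0, duration_s, dt_s)

    def gamma_pdf(x, shape, scale):
        with np.errstate(divide="ignore"):
            logp = ((shape - 1) * np.log(x) - x / scale
                    - special.gammaln(shape) - shape * math.log(scale))
        p = np.exp(logp)
        p[x <= 0] = 0.0
        return p

    h = (gamma_pdf(t, peak_delay / peak_disp, peak_disp)
         - gamma_pdf(t, undershoot_delay / undershoot_disp, undershoot_disp) / ratio)
    h = h / np.sum(h[h > 0])
    return HRFKernel(dt_s=dt_s, values=h, duration_s=duration_s)


@dataclass
class DesignMatrix:
    """Volume-sampled regressor matrix with column roles and provenance."""

    matrix: np.ndarray                  # n_volumes x K
    column_names: list[str]
    column_roles: list[str]             # task/parametric/seed/ppi/press/motion/constant
    tr_s: float
    highpass_applied: bool = False
    highpass_cutoff_hz: float | None = None
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column names do not match matrix width")
        if self.column_roles.count("constant") != 1:
            raise ValueError("design must contain exactly one constant column")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def column_index(self, name: str) -> int:
        return self.column_names.index(name)

    def estimable(self) -> np.ndarray:
        """Columns with non-negligible variance (constant always estimable)."""
        norms = np.linalg.norm(self.matrix, axis=0)
        out = norms > 1e-12 * max(1.0, norms.max())
        out[self.column_roles.index("constant")] = True
        return out


def microtime_grid(n_volumes: int, tr_s: float) -> np.ndarray:
    """Time stamps of the microtime bins covering the run."""
    dt = tr_s / MICROTIME_BINS
    return np.arange(n_volumes * MICROTIME_BINS) * dt


def _volume_sample_rows(n_volumes: int) -> np.ndarray:
    """Microtime row index sampled for each volume (middle bin)."""
    return np.arange(n_volumes) * MICROTIME_BINS + MICROTIME_BINS // 2


def convolve_and_sample(neural: np.ndarray, hrf: HRFKernel,
                        n_volumes: int) -> np.ndarray:
    """Convolve a microtime neural signal with the HRF, sample per volume."""
    full = np.convolve(neural, hrf.values)[: neural.shape[0]]
    return full[_volume_sample_rows(n_volumes)]


def _boxcar(times: np.ndarray, onsets: Sequence[float],
            durations: Sequence[float],
            amplitudes: Sequence[float] | None = None) -> np.ndarray:
    out = np.zeros_like(times)
    amps = amplitudes if amplitudes is not None else [1.0] * len(list(onsets))
    for onset, dur, amp in zip(onsets, durations, amps):
        out[(times >= onset) & (times < onset + dur)] += amp
    return out


def _sticks(times: np.ndarray, press_times: Sequence[float]) -> np.ndarray:
    out = np.zeros_like(times)
    if len(times) < 2:
        return out
    dt = times[1] - times[0]
    for p in press_times:
        idx = int(round(p / dt))
        if 0 <= idx < len(times):
            out[idx] += 1.0
    return out


def _common_columns(events: EventTable, motion: MotionParams,
                    times: np.ndarray, hrf: HRFKernel, n_volumes: int):
    """Press sticks, motion and constant columns shared by all models."""
    press_times = [p for t in events for p in t.button_press_times_s]
    press = convolve_and_sample(_sticks(times, press_times), hrf, n_volumes)
    warnings_ = []
    if not press_times:
        warnings_.append("no button presses: press column is all zeros "
                         "and non-estimable")
    cols = [press] + [motion.values[:, j] for j in range(6)] + [np.ones(n_volumes)]
    names = ["press"] + [f"motion_{j+1}" for j in range(6)] + ["constant"]
    roles = ["press"] + ["motion"] * 6 + ["constant"]
    return cols, names, roles, warnings_


def build_model1_design(events: EventTable, motion: MotionParams,
                        n_volumes: int, tr_s: float,
                        hrf: HRFKernel | None = None) -> DesignMatrix:
    """Category model: NEG/NEU/POS 6 s boxcars + press/motion/constant."""
    if motion.n_volumes != n_volumes:
        raise ValidationError("motion parameter rows must equal n_volumes")
    hrf = hrf or canonical_hrf(tr_s / MICROTIME_BINS)
    times = microtime_grid(n_volumes, tr_s)
    cols, names, roles, warn = [], [], [], []
    counts = events.category_counts()
    for cat in ("NEG", "NEU", "POS"):
        trials = [t for t in events if t.category == cat]
        neural = _boxcar(times, [t.onset_s for t in trials],
                         [t.picture_duration_s for t in trials])
        cols.append(convolve_and_sample(neural, hrf, n_volumes))
        names.append(cat)
        roles.append("task")
        if counts[cat] == 0:
            warn.append(f"category {cat} absent: column non-estimable")
    c2, n2, r2, w2 = _common_columns(events, motion, times, hrf, n_volumes)
    return DesignMatrix(np.column_stack(cols + c2), names + n2, roles + r2,
                        tr_s=tr_s, warnings_=warn + w2)


def build_model2_design(events: EventTable, motion: MotionParams,
                        n_volumes: int, tr_s: float,
                        hrf: HRFKernel | None = None) -> DesignMatrix:
    """Parametric model: mean boxcar + centered valence/arousal modulators.

    Amplitudes are the subject's per-trial ratings centered on their run
    mean; the two modulators are built independently (no serial
    orthogonalization).
    """
    if motion.n_volumes != n_volumes:
        raise ValidationError("motion parameter rows must equal n_volumes")
    hrf = hrf or canonical_hrf(tr_s / MICROTIME_BINS)
    times = microtime_grid(n_volumes, tr_s)
    onsets = [t.onset_s for t in events]
    durations = [t.picture_duration_s for t in events]
    warn: list[str] = []

    mean_col = convolve_and_sample(_boxcar(times, onsets, durations),
                                   hrf, n_volumes)
    cols = [mean_col]
    names = ["picture_mean"]
    roles = ["task"]
    for label, ratings in (("valence", [t.valence_rating for t in events]),
                           ("arousal", [t.arousal_rating for t in events])):
        amps = np.asarray(ratings, dtype=float)
        amps = amps - amps.mean()
        if np.allclose(amps, 0.0):
            warn.append(f"constant {label} ratings: modulator column is zero")
        neural = _boxcar(times, onsets, durations, amps)
        cols.append(convolve_and_sample(neural, hrf, n_volumes))
        names.append(f"{label}_mod")
        roles.append("parametric")
    c2, n2, r2, w2 = _common_columns(events, motion, times, hrf, n_volumes)
    return DesignMatrix(np.column_stack(cols + c2), names + n2, roles + r2,
                        tr_s=tr_s, warnings_=warn + w2)


# ---------------------------------------------------------------------------
# High-pass filtering
# ---------------------------------------------------------------------------

def dct_basis(n_volumes: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal DCT-II drift columns covering frequencies up to ``cutoff_hz``.

    One basis frequency beyond the cutoff is retained so a drift at exactly
    the cutoff frequency is bracketed by basis terms on both sides;
    otherwise spectral leakage leaves a substantial fraction of such a
    drift in the filtered series.
    """
    nyquist = 0.5 / tr_s
    if cutoff_hz >= nyquist:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    n_cols = int(np.ceil(2.0 * n_volumes * tr_s * cutoff_hz)) + 1
    k = np.arange(n_volumes)
    cols = [np.cos(math.pi * j * (2 * k + 1) / (2 * n_volumes))
            for j in range(1, n_cols + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def dct_highpass(obj, tr_s: float | None = None,
                 cutoff_hz: float = 1.0 / 128.0):
    """Project the sub-cutoff DCT drift space out of data or a design.

    Accepts an array (with explicit ``tr_s``), a :class:`DesignMatrix`, or a
    :class:`ParcelTimeSeries`; returns the same kind with the residual-
    forming projection applied.  The constant column of a design is
    orthogonal to every retained drift term, so it passes unchanged.
    """
    from .design_io import ParcelTimeSeries

    if isinstance(obj, DesignMatrix):
        basis = dct_basis(obj.n_volumes, obj.tr_s, cutoff_hz)
        filtered = obj.matrix - basis @ (basis.T @ obj.matrix)
        return replace(obj, matrix=filtered, highpass_applied=True,
                       highpass_cutoff_hz=cutoff_hz)
    if isinstance(obj, ParcelTimeSeries):
        first = next(iter(obj.data.values()))
        basis = dct_basis(first.shape[0], obj.tr_s, cutoff_hz)
        data = {pid: arr - basis @ (basis.T @ arr)
                for pid, arr in obj.data.items()}
        return ParcelTimeSeries(data=data, tr_s=obj.tr_s, highpass_applied=True)
    arr = np.asarray(obj, dtype=float)
    if tr_s is None:
        raise ValueError("tr_s is required when filtering a bare array")
    series = arr[:, None] if arr.ndim == 1 else arr
    basis = dct_basis(series.shape[0], tr_s, cutoff_hz)
    out = series - basis @ (basis.T @ series)
    return out[:, 0] if arr.ndim == 1 else out


# ---------------------------------------------------------------------------
# AR(1) ReML fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    """Per-voxel GLS estimates under pooled AR(1) noise."""

    betas: np.ndarray          # K x n_voxels
    sigma2: np.ndarray         # n_voxels
    rho: float
    effective_df: float
    design: DesignMatrix
    reml_converged: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.sigma2 < 0):
            raise ValueError("negative residual variance")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


@dataclass(frozen=True)
class ContrastResult:
    """Weighted beta combination per voxel (e.g. BR_NEG - BR_NEU)."""

    weights: np.ndarray
    values: np.ndarray  # n_voxels
    name: str = ""


def _whiten(arr: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(arr)
    out[0] = arr[0] * math.sqrt(1.0 - rho ** 2)
    out[1:] = arr[1:] - rho * arr[:-1]
    return out


def _reml_neg_loglik(rho: float, X: np.ndarray, Y: np.ndarray,
                     n_eff: float) -> float:
    """Restricted log-likelihood of AR(1) rho, profiled over betas/sigma2.

    Y holds one column per voxel; voxels share rho but keep their own
    variance, so the criterion sums per-voxel terms.
    """
    n, k = X.shape
    Xw = _whiten(X, rho)
    Yw = _whiten(Y, rho)
    beta, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    rss = np.sum((Yw - Xw @ beta) ** 2, axis=0)
    rss = np.maximum(rss, 1e-300)
    sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
    if sign <= 0:
        return 1e12
    n_vox = Y.shape[1]
    # log|V| of AR(1) is -log(1-rho^2) per series
    return float((n_eff - k) * np.sum(np.log(rss / (n_eff - k)))
                 + n_vox * (-math.log(1.0 - rho ** 2)) + n_vox * logdet_xx)


def fit_glm(design: DesignMatrix, data: np.ndarray,
            require_highpass: bool = True) -> GLMFit:
    """Fit the GLM to one parcel's (n_volumes x n_voxels) data.

    AR(1) rho is estimated by ReML on the parcel's voxels jointly, then
    data and design are prewhitened and betas obtained by least squares on
    the whitened system (GLS).
    """
    Y = np.asarray(data, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design.matrix
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError("data and design disagree on n_volumes")
    if require_highpass and not design.highpass_applied:
        raise ValueError("apply dct_highpass to the design (and data) first")
    if n <= k + 10:
        raise ValueError("too few volumes for the design size")

    flags = list(design.warnings_)
    est = design.estimable()
    Xe = X[:, est]
    rank = np.linalg.matrix_rank(Xe)
    if rank < Xe.shape[1]:
        flags.append("rank-deficient design: pseudo-inverse solution")

    # drift columns already projected out: account for them in the df
    cutoff = design.highpass_cutoff_hz or 1.0 / 128.0
    n_dct = dct_basis(n, design.tr_s, cutoff).shape[1] \
        if design.highpass_applied else 0
    n_eff = n - n_dct

    converged = True
    try:
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(-0.95, 0.95), method="bounded",
            args=(Xe, Y, float(n_eff)), options={"xatol": 1e-4})
        if not res.success:
            raise RuntimeError(res.message)
        rho = float(res.x)
    except Exception:
        converged = False
        beta0, *_ = np.linalg.lstsq(Xe, Y, rcond=None)
        r0 = Y - Xe @ beta0
        num = float(np.sum(r0[1:] * r0[:-1]))
        den = float(np.sum(r0 ** 2))
        rho = num / den if den > 0 else 0.0
        rho = float(np.clip(rho, -0.95, 0.95))
        flags.append("ReML failed: lag-1 autocorrelation fallback")

    Xw = _whiten(Xe, rho)
    Yw = _whiten(Y, rho)
    if rank < Xe.shape[1]:
        beta_e = np.linalg.pinv(Xw) @ Yw
    else:
        beta_e, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    resid = Yw - Xw @ beta_e
    dof = n_eff - rank
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    betas = np.zeros((k, Y.shape[1]))
    betas[est] = beta_e
    return GLMFit(betas=betas, sigma2=sigma2, rho=rho,
                  effective_df=float(dof), design=design,
                  reml_converged=converged, flags=flags)


def compute_contrast(fit: GLMFit, weights: Sequence[float],
                     name: str = "") -> ContrastResult:
    """Per-voxel weighted sum of betas for a length-K weight vector."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.design.k,):
        raise ValueError(f"weights must have length {fit.design.k}")
    est = fit.design.estimable()
    if np.any((w != 0) & ~est):
        raise ValueError("contrast touches a non-estimable column")
    return ContrastResult(weights=w, values=w @ fit.betas, name=name)


def _named_weights(design: DesignMatrix,
                   spec: Mapping[str, float]) -> np.ndarray:
    w = np.zeros(design.k)
    for name, val in spec.items():
        w[design.column_index(name)] = val
    return w


#: standard Model-1 contrasts: per-category amplitudes and their differences
CONTRASTS_MODEL1 = {
    "BR_NEG": {"NEG": 1.0},
    "BR_NEU": {"NEU": 1.0},
    "BR_POS": {"POS": 1.0},
    "dBR_N": {"NEG": 1.0, "NEU": -1.0},
    "dBR_P": {"POS": 1.0, "NEU": -1.0},
}


class FirstLevelGLM:
    """Single-run GLM bound to one parcel's data and a design.

    A statsmodels-style model object: construct with data, call
    :meth:`fit`, inspect the returned :class:`GLMResults`.
    """

    def __init__(self, data: np.ndarray, design: DesignMatrix):
        self.data = np.asarray(data, dtype=float)
        self.design = design

    def fit(self) -> "GLMResults":
        return GLMResults(fit_glm(self.design, self.data), self)


class GLMResults:
    """Estimates, noise model and contrast access for a fitted GLM."""

    def __init__(self, fit: GLMFit, model: FirstLevelGLM):
        self._fit = fit
        self.model = model

    @property
    def betas(self) -> np.ndarray:
        return self._fit.betas

    @property
    def rho(self) -> float:
        return self._fit.rho

    @property
    def sigma2(self) -> np.ndarray:
        return self._fit.sigma2

    @property
    def effective_df(self) -> float:
        return self._fit.effective_df

    @property
    def flags(self) -> list[str]:
        return self._fit.flags

    def contrast(self, spec: Mapping[str, float] | Sequence[float],
                 name: str = "") -> ContrastResult:
        if isinstance(spec, Mapping):
            w = _named_weights(self._fit.design, spec)
        else:
            w = np.asarray(spec, dtype=float)
        return compute_contrast(self._fit, w, name=name)

    def summary(self) -> str:
        d = self._fit.design
        lines = [
            "First-level GLM (AR(1)-ReML, GLS)",
            f"  volumes: {d.n_volumes}   columns: {d.k}   rank: {d.rank}",
            f"  AR(1) rho: {self._fit.rho:+.3f}"
            f"   effective df: {self._fit.effective_df:.1f}",
            f"  mean residual variance: {float(np.mean(self._fit.sigma2)):.4g}",
            "",
            "  column            role        mean |beta|",
        ]
        for j, (nm, role) in enumerate(zip(d.column_names, d.column_roles)):
            mb = float(np.mean(np.abs(self._fit.betas[j])))
            lines.append(f"  {nm:<17s} {role:<11s} {mb:10.4f}")
        for fl in self._fit.flags:
            lines.append(f"  note: {fl}")
        return "\n".join(lines)
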