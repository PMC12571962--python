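"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: two groups of 16
subjects, 54 affective pictures (18 per valence category crossed with 27
low / 27 high arousal), 6 s picture epochs, variable rating periods up to
8 s, 10-14 s stimulus asynchrony, and 470 EPI volumes at TR = 2 s over 246
atlas parcels of (by default) 10 voxels each.

Three kinds of group effect can be planted:

* ``category_amplitude`` — extra BOLD amplitude for one picture category in
  chosen parcels of one group (detected as a dBR_N / dBR_P difference);
* ``valence_slope`` — per-rating-point modulation of the picture response
  (detected by the parametric model's slope);
* ``ppi_gain`` — seed-by-condition interaction added to target parcels at
  the neural (pre-convolution) level, the structure the deconvolution PPI
  estimator assumes.

SAM ratings follow an ordinal-probit-style model: latent = category mean +
subject offset + noise, discretized to 1..9; patient category means are
shifted toward the neutral midpoint 5 by ``patient_valence_shift`` rating
points (and high-arousal means downward by ``patient_arousal_shift``),
emulating the blunted emotional experience of the patient group.  Voxel
noise is AR(1) Gaussian plus a sinusoidal drift whose default 128 s period
is exactly what the 1/128 Hz high-pass filter removes.

Randomness descends from one root seed through ``numpy`` ``SeedSequence``
spawning, in subject order (events stream first, then noise), so a fixed
seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
from scipy import signal

from .design_io import (AROUSAL_CLASSES, CATEGORIES, GROUPS, EventTable,
                        MotionParams, ParcelTimeSeries, SubjectRecord, Trial)
from .glm import (HRFKernel, MICROTIME_BINS, canonical_hrf,
                  convolve_and_sample, microtime_grid)

__all__ = ["SimulationConfig", "PlantedEffect", "RatingModel", "NoiseModel",
           "simulate_events", "simulate_subject", "simulate_cohort",
           "iter_cohort", "cohort_manifest", "write_cohort"]

EffectKind = Literal["category_amplitude", "valence_slope", "ppi_gain"]


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth group effect injected into chosen parcels."""

    kind: EffectKind
    parcel_ids: tuple[int, ...]
    group: str                  # PATIENT, HC or BOTH
    magnitude: float            # signal units / slope per rating point / gain
    category: str = "NEG"       # for category_amplitude
    seed_parcel: int | None = None  # for ppi_gain

    def applies_to(self, group: str) -> bool:
        return self.group == "BOTH" or self.group == group


@dataclass
class RatingModel:
    """Ordinal-probit-style generative model for the 9-level SAM scales."""

    valence_means: dict[str, float] = field(
        default_factory=lambda: {"NEG": 2.5, "NEU": 5.0, "POS": 7.5})
    arousal_means: dict[str, float] = field(
        default_factory=lambda: {"LOW": 3.5, "HIGH": 6.5})
    latent_sd: float = 1.0
    subject_sd: float = 0.5
    patient_valence_shift: float = 1.5   # rating points toward the midpoint 5
    patient_arousal_shift: float = 1.0   # rating points toward low arousal

    def category_mean(self, category: str, group: str) -> float:
        mu = self.valence_means[category]
        if group == "PATIENT" and category != "NEU":
            mu += self.patient_valence_shift * (1.0 if mu < 5.0 else -1.0)
        return mu

    def arousal_mean(self, arousal_class: str, group: str) -> float:
        mu = self.arousal_means[arousal_class]
        if group == "PATIENT":
            mu -= self.patient_arousal_shift * 0.5
        return mu


@dataclass
class NoiseModel:
    white_sd: float = 1.0
    ar1_coefficient: float = 0.3
    drift_amplitude: float = 1.0
    drift_period_s: float = 128.0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise amplitudes must be nonnegative")
        if not (-1.0 < self.ar1_coefficient < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")


@dataclass
class SimulationConfig:
    """Complete description of a simulated cohort."""

    n_per_group: int = 16
    n_parcels: int = 246
    voxels_per_parcel: int = 10
    tr_s: float = 2.0
    n_volumes: int = 470
    n_trials: int = 54
    soa_range_s: tuple[float, float] = (10.0, 14.0)
    picture_duration_s: float = 6.0
    max_rating_duration_s: float = 8.0
    task_amplitude: float = 1.0          # common BOLD amplitude, all categories
    press_amplitude: float = 0.5
    seed_parcels: tuple[int, ...] = (211, 212)
    seed_neural_sd: float = 1.0          # intrinsic seed fluctuation amplitude
    seed_neural_smooth_s: float = 2.0    # Gaussian smoothing of the fluctuation
    rating_model: RatingModel = field(default_factory=RatingModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    effects: list[PlantedEffect] = field(default_factory=list)
    age_mean: float = 30.5
    age_sd: float = 8.5
    bdi2_mean: float = 4.0
    bdi2_sd: float = 4.0
    recognition_mean: float = 85.0       # percent correct
    recognition_sd: float = 6.0
    recognition_rt_mean: float = 900.0   # milliseconds
    recognition_rt_sd: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % (len(CATEGORIES) * len(AROUSAL_CLASSES)):
            raise ValueError("n_trials must divide into the category x "
                             "arousal cross")
        for eff in self.effects:
            bad = [p for p in eff.parcel_ids if not 1 <= p <= self.n_parcels]
            if bad:
                raise ValueError(f"planted effect references missing parcels {bad}")
            if eff.kind == "ppi_gain" and eff.seed_parcel not in self.seed_parcels:
                raise ValueError("ppi_gain effects must reference a seed parcel")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "rating_model" in d:
            rm = dict(d["rating_model"])
            for key in ("valence_means", "arousal_means"):
                if key in rm:
                    rm[key] = dict(rm[key])
            d["rating_model"] = RatingModel(**rm)
        if "noise" in d:
            d["noise"] = NoiseModel(**d["noise"])
        if "effects" in d:
            d["effects"] = [PlantedEffect(kind=e["kind"],
                                          parcel_ids=tuple(e["parcel_ids"]),
                                          group=e["group"],
                                          magnitude=e["magnitude"],
                                          category=e.get("category", "NEG"),
                                          seed_parcel=e.get("seed_parcel"))
                            for e in d["effects"]]
        for key in ("soa_range_s", "seed_parcels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _discretize(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(latent), 1, 9).astype(int)


def simulate_events(config: SimulationConfig, rng: np.random.Generator,
                    group: str = "HC",
                    subject_offset: float | None = None) -> EventTable:
    """One subject's randomized trial sequence with SAM ratings."""
    per_cell = config.n_trials // (len(CATEGORIES) * len(AROUSAL_CLASSES))
    cells = [(c, a) for c in CATEGORIES for a in AROUSAL_CLASSES] * per_cell
    order = rng.permutation(len(cells))
    rm = config.rating_model
    if subject_offset is None:
        subject_offset = rng.normal(0.0, rm.subject_sd)

    soa_lo, soa_hi = config.soa_range_s
    onset = 10.0
    trials = []
    for tid, idx in enumerate(order):
        cat, aro = cells[idx]
        val = _discretize(rng.normal(rm.category_mean(cat, group)
                                     + subject_offset, rm.latent_sd))
        arl = _discretize(rng.normal(rm.arousal_mean(aro, group)
                                     + subject_offset, rm.latent_sd))
        rating_onset = onset + config.picture_duration_s
        rating_dur = rng.uniform(2.0, config.max_rating_duration_s)
        presses = tuple(sorted(
            rating_onset + rating_dur * rng.uniform(0.2, 0.9, size=2)))
        trials.append(Trial(
            trial_id=tid, onset_s=onset,
            picture_duration_s=config.picture_duration_s,
            category=cat, arousal_class=aro,
            valence_rating=int(val), arousal_rating=int(arl),
            rating_onset_s=rating_onset, rating_duration_s=rating_dur,
            button_press_times_s=presses))
        onset += rng.uniform(soa_lo, soa_hi)
    events = EventTable(trials=trials)
    if events.last_offset_s > config.n_volumes * config.tr_s:
        raise ValueError("infeasible timing: events outlast the run")
    return events


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int],
               noise: NoiseModel) -> np.ndarray:
    white = rng.normal(0.0, noise.white_sd, size=shape)
    if noise.ar1_coefficient == 0.0:
        return white
    rho = noise.ar1_coefficient
    out = np.empty(shape)
    out[0] = white[0] / math.sqrt(1.0 - rho ** 2)  # stationary start
    tail, _ = signal.lfilter([1.0], [1.0, -rho], white[1:], axis=0,
                             zi=(rho * out[0])[None, :])
    out[1:] = tail
    return out


def _neural_signals(config: SimulationConfig, events: EventTable,
                    group: str, rng: np.random.Generator
                    ) -> dict[int, np.ndarray]:
    """Microtime neural signal per parcel (shared baseline + planted parts).

    Seed parcels additionally carry a smooth intrinsic neural fluctuation;
    connectivity is coupling of such fluctuations, so without it a planted
    seed-by-condition interaction would be indistinguishable from a plain
    task-amplitude change.
    """
    from scipy.ndimage import gaussian_filter1d

    from .glm import _boxcar, _sticks  # shared primitives

    times = microtime_grid(config.n_volumes, config.tr_s)
    base = np.zeros_like(times)
    cat_neural: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        sub = [t for t in events if t.category == cat]
        cat_neural[cat] = _boxcar(times, [t.onset_s for t in sub],
                                  [t.picture_duration_s for t in sub])
        base += config.task_amplitude * cat_neural[cat]
    presses = [p for t in events for p in t.button_press_times_s]
    base += config.press_amplitude * _sticks(times, presses)

    signals = {pid: base for pid in range(1, config.n_parcels + 1)}
    dt = config.tr_s / MICROTIME_BINS
    for sid in config.seed_parcels:
        if sid in signals and config.seed_neural_sd > 0:
            raw = rng.standard_normal(times.shape[0])
            smooth = gaussian_filter1d(raw, config.seed_neural_smooth_s / dt)
            sd = smooth.std()
            if sd > 0:
                signals[sid] = signals[sid] + config.seed_neural_sd * smooth / sd

    def bump(pid: int, extra: np.ndarray) -> None:
        signals[pid] = signals[pid] + extra

    valence = np.array([t.valence_rating for t in events], dtype=float)
    centered_val = valence - valence.mean()
    for eff in config.effects:
        if not eff.applies_to(group):
            continue
        if eff.kind == "category_amplitude":
            extra = eff.magnitude * cat_neural[eff.category]
            for pid in eff.parcel_ids:
                bump(pid, extra)
        elif eff.kind == "valence_slope":
            onsets = [t.onset_s for t in events]
            durs = [t.picture_duration_s for t in events]
            extra = eff.magnitude * _boxcar(times, onsets, durs, centered_val)
            for pid in eff.parcel_ids:
                bump(pid, extra)
        elif eff.kind == "ppi_gain":
            # seed-by-condition product at the neural level: the structure
            # the deconvolution PPI estimator is built to recover
            psych = cat_neural["NEG"] - cat_neural["NEU"]
            seed_neural = signals[eff.seed_parcel]
            extra = eff.magnitude * seed_neural * psych
            for pid in eff.parcel_ids:
                bump(pid, extra)
    return signals


def simulate_subject(config: SimulationConfig, events: EventTable,
                     group: str, rng: np.random.Generator,
                     hrf: HRFKernel | None = None
                     ) -> tuple[ParcelTimeSeries, MotionParams]:
    """BOLD time series for every parcel voxel of one subject."""
    hrf = hrf or canonical_hrf(config.tr_s / MICROTIME_BINS)
    neural = _neural_signals(config, events, group, rng)

    # identical neural signals share one convolution
    bold: dict[int, np.ndarray] = {}
    seen: dict[int, np.ndarray] = {}
    ids_by_signal: list[tuple[np.ndarray, list[int]]] = []
    for pid, sig in neural.items():
        for ref, ids in ids_by_signal:
            if sig is ref or (sig.shape == ref.shape and np.array_equal(sig, ref)):
                ids.append(pid)
                break
        else:
            ids_by_signal.append((sig, [pid]))
    for sig, ids in ids_by_signal:
        sampled = convolve_and_sample(sig, hrf, config.n_volumes)
        for pid in ids:
            bold[pid] = sampled

    nm = config.noise
    t = np.arange(config.n_volumes) * config.tr_s
    data = {}
    for pid in range(1, config.n_parcels + 1):
        clean = bold[pid][:, None]
        vox = np.tile(clean, (1, config.voxels_per_parcel))
        if nm.white_sd > 0:
            vox = vox + _ar1_noise(rng, vox.shape, nm)
        if nm.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * math.pi, size=config.voxels_per_parcel)
            vox = vox + nm.drift_amplitude * np.sin(
                2 * math.pi * t[:, None] / nm.drift_period_s + phase[None, :])
        data[pid] = vox
    ts = ParcelTimeSeries(data=data, tr_s=config.tr_s)
    motion = MotionParams(0.05 * rng.standard_normal((config.n_volumes, 6)))
    return ts, motion


def iter_cohort(config: SimulationConfig
                ) -> Iterator[tuple[SubjectRecord, ParcelTimeSeries,
                                    MotionParams]]:
    """Stream subjects one at a time (memory-friendly for full cohorts)."""
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(2 * config.n_per_group)
    rm = config.rating_model
    i = 0
    for group in GROUPS:
        for j in range(config.n_per_group):
            rng = np.random.default_rng(streams[i])
            subject_id = f"{'P' if group == 'PATIENT' else 'H'}{j+1:02d}"
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                18.0, 65.0))
            bdi2 = float(np.clip(rng.normal(config.bdi2_mean, config.bdi2_sd),
                                 0.0, 63.0))
            sex = j % 2
            iaps_set = "A" if j % 2 else "B"
            offset = rng.normal(0.0, rm.subject_sd)
            events = simulate_events(config, rng, group=group,
                                     subject_offset=offset)
            rec = SubjectRecord(
                subject_id=subject_id, group=group, sex=sex, age=age,
                bdi2=bdi2, iaps_set=iaps_set, events=events,
                recognition_performance=float(rng.normal(
                    config.recognition_mean, config.recognition_sd)),
                recognition_rt=float(rng.normal(
                    config.recognition_rt_mean, config.recognition_rt_sd)))
            ts, motion = simulate_subject(config, events, group, rng)
            yield rec, ts, motion
            i += 1


def simulate_cohort(config: SimulationConfig
                    ) -> list[tuple[SubjectRecord, ParcelTimeSeries,
                                    MotionParams]]:
    """Materialize the whole cohort (see :func:`iter_cohort` to stream)."""
    return list(iter_cohort(config))


def cohort_manifest(config: SimulationConfig) -> dict:
    """Ground-truth record of the planted effects, for recovery scoring."""
    return {
        "seed": config.seed,
        "n_per_group": config.n_per_group,
        "n_parcels": config.n_parcels,
        "effects": [
            {"kind": e.kind, "parcel_ids": list(e.parcel_ids),
             "group": e.group, "magnitude": e.magnitude,
             "category": e.category, "seed_parcel": e.seed_parcel}
            for e in config.effects],
    }


def write_cohort(config: SimulationConfig, out_dir: str | Path) -> None:
    """Emit events TSVs, parcel TSVs, covariates and the manifest."""
    from .design_io import write_events, write_parcel_matrix
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    covs = []
    for rec, ts, motion in iter_cohort(config):
        write_events(rec.events, out / f"{rec.subject_id}_events.tsv")
        write_parcel_matrix(ts, out / f"{rec.subject_id}_parcels.tsv")
        np.savetxt(out / f"{rec.subject_id}_motion.tsv", motion.values,
                   delimiter="\t", fmt="%.6f")
        covs.append({"subject_id": rec.subject_id, "group": rec.group,
                     "sex": rec.sex, "age": rec.age, "bdi2": rec.bdi2,
                     "iaps_set": rec.iaps_set,
                     "recognition_performance": rec.recognition_performance,
                     "recognition_rt": rec.recognition_rt})
    pd.DataFrame(covs).to_csv(out / "participants.tsv", sep="\t", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(cohort_manifest(config), indent=1))
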