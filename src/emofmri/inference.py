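"""Group-level pipeline: parcel medians, covariate adjustment, region-wise
Bayes-factor tests, the dual-threshold selection rule, and report tables.

For each endpoint (dBR_N, dBR_P, the parametric slopes, or dFC per seed)
every subject contributes the median voxel contrast per atlas parcel,
giving a subjects x parcels estimate matrix.  After covariate adjustment
(sex, age, depression severity — residualized on the pooled sample WITHOUT
a group term, so genuine group signal survives), each parcel is tested
with:

* a two-sided JZS independent-samples t-test between groups, and
* four one-sided one-sample t-tests (each group x each direction).

The dual-threshold decision rule: a parcel is a ``difference`` when the
group-difference log10 BF10 exceeds 1.0 (strong evidence), a ``similarity``
when it falls below -0.5 (at least moderate evidence for equality), and
``undecided`` otherwise; a difference parcel is *reported* only when, in
addition, at least one group shows at least moderate one-sided evidence
(log10 BF > 0.5) for its own main effect.  No multiplicity correction is
applied across the 246 parcels — the evidence thresholds themselves are the
filter, and readers should interpret single-parcel results accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anova import InclusionBFResult, rmancova_inclusion_bf
from .bayes import (DEFAULT_CAUCHY_SCALE, BFResult, grade_evidence,
                    jzs_one_sample_bf, jzs_two_sample_bf)
from .design_io import GROUPS, AtlasLabels, SubjectRecord

__all__ = [
    "ParcelEstimateMatrix", "RegionDecision",
    "extract_parcel_medians", "adjust_covariates", "test_regions",
    "GroupDifferenceModel", "RegionResults",
    "BehavioralANCOVA", "behavioral_analysis", "render_report",
]

DIFFERENCE_THRESHOLD = 1.0    # log10 BF10 for a group difference
SIMILARITY_THRESHOLD = -0.5   # log10 BF10 below which H0 is moderately favored
MAIN_EFFECT_THRESHOLD = 0.5   # one-sided main-effect evidence for reporting


@dataclass
class ParcelEstimateMatrix:
    """Subjects x parcels endpoint estimates with subject metadata."""

    values: pd.DataFrame        # index: subject_id, columns: parcel ids
    metadata: pd.DataFrame      # index: subject_id; group, sex, age, bdi2, ...
    endpoint: str = ""
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.metadata.index):
            raise ValueError("values and metadata must share the subject index")

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]


def extract_parcel_medians(contrast_maps: Mapping[str, Mapping[int, np.ndarray]],
                           metadata: pd.DataFrame,
                           endpoint: str = "") -> ParcelEstimateMatrix:
    """Median voxel contrast per parcel and subject.

    ``contrast_maps`` maps subject id to {parcel id: voxel contrast values};
    a parcel with no voxels yields a missing value.
    """
    rows = {}
    for sid, parcels in contrast_maps.items():
        rows[sid] = {pid: (float(np.median(v)) if np.size(v) else np.nan)
                     for pid, v in parcels.items()}
    values = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    values = values.loc[metadata.index]
    return ParcelEstimateMatrix(values=values, metadata=metadata,
                                endpoint=endpoint)


def adjust_covariates(matrix: ParcelEstimateMatrix,
                      covariates: Sequence[str] = ("sex", "age", "bdi2"),
                      restore_intercept: bool = True) -> ParcelEstimateMatrix:
    """Residualize each parcel on the covariates, pooled across groups.

    No group term enters the regression, so between-group signal is
    preserved in the residuals; the fitted intercept is restored by default
    to keep group means interpretable.  Collinear covariate columns are
    dropped with a warning recorded on the result's metadata.
    """
    import warnings

    meta = matrix.metadata
    cols = []
    kept = []
    for c in covariates:
        v = meta[c].to_numpy(dtype=float)
        cols.append(v - v.mean())   # centered: intercept = grand mean
        kept.append(c)
    X = np.column_stack([np.ones(len(meta))] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # drop collinear columns greedily, keeping the earlier ones
        keep = [0]
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                warnings.warn(f"covariate {covariates[j-1]!r} collinear: dropped")
        X = X[:, keep]
    Y = matrix.values.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if restore_intercept:
        resid = resid + beta[0]
    values = pd.DataFrame(resid, index=matrix.values.index,
                          columns=matrix.values.columns)
    return ParcelEstimateMatrix(values=values, metadata=meta,
                                endpoint=matrix.endpoint, adjusted=True)


@dataclass
class RegionDecision:
    """Verdict for one parcel under the dual-threshold rule."""

    parcel_id: int
    log10_bf_group_diff: float
    one_sided: dict[str, float]   # "PATIENT>0", "PATIENT<0", "HC>0", "HC<0"
    group_means: dict[str, float]
    group_sds: dict[str, float]
    verdict: str                  # difference / similarity / undecided
    reported: bool
    flags: list[str] = field(default_factory=list)

    @property
    def evidence_grade(self) -> str:
        return grade_evidence(self.log10_bf_group_diff).label


def _decide(bf_diff: float, one_sided: Mapping[str, float]) -> tuple[str, bool]:
    if bf_diff > DIFFERENCE_THRESHOLD:
        verdict = "difference"
    elif bf_diff < SIMILARITY_THRESHOLD:
        verdict = "similarity"
    else:
        verdict = "undecided"
    best_main = max(one_sided.values()) if one_sided else -math.inf
    reported = verdict == "difference" and best_main > MAIN_EFFECT_THRESHOLD
    return verdict, reported


def test_regions(matrix: ParcelEstimateMatrix,
                 r: float = DEFAULT_CAUCHY_SCALE) -> list[RegionDecision]:
    """Region-wise two-sample and post hoc one-sample Bayes-factor tests."""
    groups = matrix.groups
    out = []
    for pid in matrix.values.columns:
        col = matrix.values[pid]
        x = col[groups == "PATIENT"].to_numpy(dtype=float)
        y = col[groups == "HC"].to_numpy(dtype=float)
        flags = []
        if np.isnan(x).any() or np.isnan(y).any():
            flags.append("missing values")
            x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        means = {"PATIENT": float(np.mean(x)), "HC": float(np.mean(y))}
        sds = {"PATIENT": float(np.std(x, ddof=1)), "HC": float(np.std(y, ddof=1))}
        try:
            bf_diff = jzs_two_sample_bf(x, y, r=r).log10_bf10
            one_sided = {}
            for gname, vals in (("PATIENT", x), ("HC", y)):
                for direction, tag in (("greater", ">0"), ("less", "<0")):
                    one_sided[f"{gname}{tag}"] = jzs_one_sample_bf(
                        vals, r=r, direction=direction).log10_bf10
            verdict, reported = _decide(bf_diff, one_sided)
        except ValueError as exc:   # degenerate parcel
            flags.append(f"degenerate: {exc}")
            bf_diff, one_sided = float("nan"), {}
            verdict, reported = "undecided", False
        out.append(RegionDecision(
            parcel_id=int(pid), log10_bf_group_diff=float(bf_diff),
            one_sided=one_sided, group_means=means, group_sds=sds,
            verdict=verdict, reported=reported, flags=flags))
    return out


class GroupDifferenceModel:
    """Parcel-wise Bayesian group comparison bound to an estimate matrix."""

    def __init__(self, matrix: ParcelEstimateMatrix,
                 covariates: Sequence[str] = ("sex", "age", "bdi2"),
                 r: float = DEFAULT_CAUCHY_SCALE):
        self.matrix = matrix
        self.covariates = tuple(covariates)
        self.r = r

    def fit(self, adjust: bool = True) -> "RegionResults":
        m = self.matrix
        if adjust and not m.adjusted and self.covariates:
            m = adjust_covariates(m, self.covariates)
        return RegionResults(test_regions(m, r=self.r), m, self)


class RegionResults:
    """Decisions for every parcel plus summary/report accessors."""

    def __init__(self, decisions: list[RegionDecision],
                 matrix: ParcelEstimateMatrix, model: GroupDifferenceModel):
        self.decisions = decisions
        self.matrix = matrix
        self.model = model

    def to_frame(self, atlas: AtlasLabels | None = None) -> pd.DataFrame:
        rows = []
        for d in self.decisions:
            rows.append({
                "parcel_id": d.parcel_id,
                "region": atlas.name_of(d.parcel_id) if atlas else str(d.parcel_id),
                "log10_bf_diff": d.log10_bf_group_diff,
                "patient_gt0": d.one_sided.get("PATIENT>0", np.nan),
                "patient_lt0": d.one_sided.get("PATIENT<0", np.nan),
                "hc_gt0": d.one_sided.get("HC>0", np.nan),
                "hc_lt0": d.one_sided.get("HC<0", np.nan),
                "patient_mean": d.group_means.get("PATIENT", np.nan),
                "patient_sd": d.group_sds.get("PATIENT", np.nan),
                "hc_mean": d.group_means.get("HC", np.nan),
                "hc_sd": d.group_sds.get("HC", np.nan),
                "verdict": d.verdict,
                "reported": d.reported,
            })
        return pd.DataFrame(rows)

    def reported(self) -> list[RegionDecision]:
        return [d for d in self.decisions if d.reported]

    def summary(self, atlas: AtlasLabels | None = None) -> str:
        frame = self.to_frame(atlas)
        n = len(frame)
        counts = frame["verdict"].value_counts()
        lines = [
            f"Region-wise Bayesian group comparison — {self.matrix.endpoint or 'endpoint'}",
            f"  parcels: {n}   difference: {counts.get('difference', 0)}"
            f"   similarity: {counts.get('similarity', 0)}"
            f"   undecided: {counts.get('undecided', 0)}"
            f"   reported: {int(frame['reported'].sum())}",
        ]
        rep = frame[frame["reported"]].sort_values(
            "log10_bf_diff", key=np.abs, ascending=False)
        if len(rep):
            lines.append("")
            lines.append("  reported regions (group difference, one-sided main effects):")
            for _, r in rep.iterrows():
                lines.append(
                    f"    {r['region']:<24s} BF_diff={r['log10_bf_diff']:+.2f}"
                    f"  P>0|P<0: {r['patient_gt0']:+.2f}|{r['patient_lt0']:+.2f}"
                    f"  HC>0|HC<0: {r['hc_gt0']:+.2f}|{r['hc_lt0']:+.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Behavioral endpoints
# ---------------------------------------------------------------------------

def _ratings_long_table(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Per-subject mean valence/arousal ratings per category, long format."""
    rows = []
    for rec in subjects:
        by_cat: dict[str, list[int]] = {}
        by_aro: dict[str, list[int]] = {}
        for t in rec.events:
            by_cat.setdefault(t.category, []).append(t.valence_rating)
            by_aro.setdefault(t.arousal_class, []).append(t.arousal_rating)
        base = {"subject": rec.subject_id, "group": rec.group,
                "sex": rec.sex, "age": rec.age, "bdi2": rec.bdi2,
                "iaps_set": 0 if rec.iaps_set == "A" else 1}
        for cat, vals in by_cat.items():
            rows.append({**base, "factor": "valence", "level": cat,
                         "response": float(np.mean(vals))})
        for aro, vals in by_aro.items():
            rows.append({**base, "factor": "arousal", "level": aro,
                         "response": float(np.mean(vals))})
    return pd.DataFrame(rows)


class BehavioralANCOVA:
    """Bayesian rmANCOVA of one behavioral endpoint (group x category)."""

    def __init__(self, long_table: pd.DataFrame, *, response: str = "response",
                 within: str = "level", between: str = "group",
                 subject: str = "subject",
                 covariates: Sequence[str] = ("age", "sex", "iaps_set", "bdi2"),
                 mcmc_passes: int = 5000, seed: int | None = None):
        self.table = long_table
        self.kwargs = dict(response=response, within=within, between=between,
                           subject=subject, covariates=list(covariates),
                           mcmc_passes=mcmc_passes, seed=seed)

    def fit(self) -> InclusionBFResult:
        return rmancova_inclusion_bf(self.table, **self.kwargs)


def behavioral_analysis(subjects: Sequence[SubjectRecord],
                        mcmc_passes: int = 5000,
                        seed: int | None = None,
                        posthoc_threshold: float = 0.5) -> pd.DataFrame:
    """Table of inclusion BFs per endpoint, with gated post hoc tests.

    Endpoints: mean valence rating (by picture category) and mean arousal
    rating (by arousal class).  When the interaction inclusion BF exceeds
    ``posthoc_threshold``, one-sided two-sample tests per factor level are
    appended (direction chosen by the sample means).
    """
    long = _ratings_long_table(subjects)
    rows = []
    for factor in ("valence", "arousal"):
        sub = long[long["factor"] == factor]
        res = BehavioralANCOVA(sub, mcmc_passes=mcmc_passes, seed=seed).fit()
        row = {"endpoint": f"{factor}_rating",
               "bf_incl_category": res.log10_bf_incl["level"],
               "bf_incl_group": res.log10_bf_incl["group"],
               "bf_incl_interaction": res.log10_bf_incl["interaction"],
               "posthoc": ""}
        if row["bf_incl_interaction"] > posthoc_threshold:
            notes = []
            for level in sorted(sub["level"].unique()):
                cell = sub[sub["level"] == level]
                x = cell.loc[cell["group"] == "PATIENT", "response"].to_numpy()
                y = cell.loc[cell["group"] == "HC", "response"].to_numpy()
                direction = "greater" if x.mean() > y.mean() else "less"
                bf = jzs_two_sample_bf(x, y, direction=direction).log10_bf10
                sign = ">" if direction == "greater" else "<"
                notes.append(f"{level}: PATIENT{sign}HC {bf:+.2f}")
            row["posthoc"] = "; ".join(notes)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(decisions: Sequence[RegionDecision], atlas: AtlasLabels,
                  endpoint: str, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a TSV and a text report of the reported/similarity regions.

    Rows are ordered by descending |log10 BF_diff|; similarity regions are
    listed in their own section.
    """
    out_prefix = Path(out_prefix)
    frame_rows = []
    for d in decisions:
        frame_rows.append({
            "parcel_id": d.parcel_id, "region": atlas.name_of(d.parcel_id),
            "log10_bf_diff": d.log10_bf_group_diff,
            "patient_gt0": d.one_sided.get("PATIENT>0", np.nan),
            "patient_lt0": d.one_sided.get("PATIENT<0", np.nan),
            "hc_gt0": d.one_sided.get("HC>0", np.nan),
            "hc_lt0": d.one_sided.get("HC<0", np.nan),
            "patient_mean_sd": f"{d.group_means.get('PATIENT', np.nan):.3f} ± "
                               f"{d.group_sds.get('PATIENT', np.nan):.3f}",
            "hc_mean_sd": f"{d.group_means.get('HC', np.nan):.3f} ± "
                          f"{d.group_sds.get('HC', np.nan):.3f}",
            "verdict": d.verdict, "reported": d.reported,
        })
    columns = ["parcel_id", "region", "log10_bf_diff", "patient_gt0",
               "patient_lt0", "hc_gt0", "hc_lt0", "patient_mean_sd",
               "hc_mean_sd", "verdict", "reported"]
    frame = pd.DataFrame(frame_rows, columns=columns)
    if len(frame):
        frame = frame.reindex(frame["log10_bf_diff"].abs()
                              .sort_values(ascending=False).index)
    tsv_path = out_prefix.with_suffix(".tsv")
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.4f")

    lines = [f"Endpoint: {endpoint}", ""]
    rep = frame[frame["reported"] == True] if len(frame) else frame  # noqa: E712
    lines.append(f"Reported group differences ({len(rep)}):")
    for _, r in rep.iterrows():
        lines.append(f"  {r['region']:<28s} BF_diff={r['log10_bf_diff']:+.3f}  "
                     f"PATIENT {r['patient_mean_sd']}  HC {r['hc_mean_sd']}")
    sim = frame[frame["verdict"] == "similarity"] if len(frame) else frame
    lines.append("")
    lines.append(f"Group similarities, H0 preferred ({len(sim)}):")
    for _, r in sim.iterrows():
        lines.append(f"  {r['region']:<28s} BF_diff={r['log10_bf_diff']:+.3f}")
    txt_path = out_prefix.with_suffix(".txt")
    txt_path.write_text("\n".join(lines) + "\n")
    return tsv_path, txt_path
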