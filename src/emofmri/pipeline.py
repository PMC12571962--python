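"""End-to-end orchestration: simulate (or load) a cohort, fit the
first-level models, extract parcel medians, and run the group tests.

This is the programmatic equivalent of chaining the CLI stages; each step
delegates to the module that owns it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design_io import EventTable, MotionParams, ParcelTimeSeries, SubjectRecord
from .glm import (CONTRASTS_MODEL1, FirstLevelGLM, build_model1_design,
                  build_model2_design, dct_highpass)
from .inference import (GroupDifferenceModel, ParcelEstimateMatrix,
                        RegionResults, extract_parcel_medians)
from .ppi import build_ppi_design, estimate_fc_contrasts, extract_eigenvariate
from .synthetic import SimulationConfig, iter_cohort

__all__ = ["subject_contrast_maps", "run_group_analysis", "run_pipeline"]

#: endpoints produced by the first-level stage
MODEL1_ENDPOINTS = ("dBR_N", "dBR_P")
MODEL2_ENDPOINTS = ("slope_valence", "slope_arousal")


def subject_contrast_maps(events: EventTable, ts: ParcelTimeSeries,
                          motion: MotionParams,
                          endpoints: Sequence[str],
                          seed_ids: Sequence[int] = (),
                          ) -> dict[str, dict[int, np.ndarray]]:
    """First-level contrast maps {endpoint: {parcel: voxel values}}."""
    n_vol, tr = ts.n_volumes, ts.tr_s
    tsf = ts if ts.highpass_applied else dct_highpass(ts)
    out: dict[str, dict[int, np.ndarray]] = {e: {} for e in endpoints}

    want1 = [e for e in MODEL1_ENDPOINTS if e in endpoints]
    if want1:
        design = dct_highpass(build_model1_design(events, motion, n_vol, tr))
        for pid in tsf.parcel_ids:
            res = FirstLevelGLM(tsf.data[pid], design).fit()
            if "dBR_N" in want1:
                out["dBR_N"][pid] = res.contrast({"NEG": 1.0, "NEU": -1.0}).values
            if "dBR_P" in want1:
                out["dBR_P"][pid] = res.contrast({"POS": 1.0, "NEU": -1.0}).values

    want2 = [e for e in MODEL2_ENDPOINTS if e in endpoints]
    if want2:
        design = dct_highpass(build_model2_design(events, motion, n_vol, tr))
        for pid in tsf.parcel_ids:
            res = FirstLevelGLM(tsf.data[pid], design).fit()
            if "slope_valence" in want2:
                out["slope_valence"][pid] = res.contrast({"valence_mod": 1.0}).values
            if "slope_arousal" in want2:
                out["slope_arousal"][pid] = res.contrast({"arousal_mod": 1.0}).values

    for sid in seed_ids:
        name = f"dFC_seed{sid}"
        if name not in endpoints:
            continue
        seed = extract_eigenvariate(tsf, sid)
        design = dct_highpass(build_ppi_design(events, seed, motion, n_vol, tr))
        fc = estimate_fc_contrasts(design, tsf, sid)
        out[name] = dict(fc.values)
    return out


def run_group_analysis(contrast_maps: Mapping[str, Mapping[int, np.ndarray]],
                       metadata: pd.DataFrame, endpoint: str,
                       covariates: Sequence[str] = ("sex", "age", "bdi2"),
                       ) -> RegionResults:
    matrix = extract_parcel_medians(contrast_maps, metadata, endpoint=endpoint)
    return GroupDifferenceModel(matrix, covariates=covariates).fit()


def run_pipeline(config: SimulationConfig,
                 endpoints: Sequence[str] = ("dBR_N",),
                 covariates: Sequence[str] = ("sex", "age", "bdi2"),
                 ) -> dict[str, RegionResults]:
    """Simulate a cohort and run the full analysis for chosen endpoints.

    Endpoint names: ``dBR_N``, ``dBR_P``, ``slope_valence``,
    ``slope_arousal`` and ``dFC_seed<id>`` for each configured seed parcel.
    Subjects are streamed so only one subject's voxel data is held at once.
    """
    seed_ids = [sid for sid in config.seed_parcels
                if f"dFC_seed{sid}" in endpoints]
    per_endpoint: dict[str, dict[str, dict[int, np.ndarray]]] = \
        {e: {} for e in endpoints}
    meta_rows = []
    for rec, ts, motion in iter_cohort(config):
        maps = subject_contrast_maps(rec.events, ts, motion, endpoints,
                                     seed_ids=seed_ids)
        for e in endpoints:
            per_endpoint[e][rec.subject_id] = maps[e]
        meta_rows.append({"subject_id": rec.subject_id, "group": rec.group,
                          "sex": rec.sex, "age": rec.age, "bdi2": rec.bdi2})
    metadata = pd.DataFrame(meta_rows).set_index("subject_id")
    return {e: run_group_analysis(per_endpoint[e], metadata, e,
                                  covariates=covariates)
            for e in endpoints}
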