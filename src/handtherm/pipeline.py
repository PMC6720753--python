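"""End-to-end orchestration: sequence → preprocessing → segmentation → metrics.

Segmentation runs once on the (preprocessed) static frame and the resulting
five finger midlines are reused for every frame of the sequence — the
synthetic scene does not move, and reusing the static ROI keeps the extracted
curves strictly comparable across frames.
"""

from __future__ import annotations

import pandas as pd

from handtherm import metrics as tm
from handtherm import preprocessing as pp
from handtherm import segmentation as seg
from handtherm import synthetic as syn

__all__ = ["process_sequence", "run_cohort", "cohort_clinical_table"]


def process_sequence(sequence: syn.ThermalSequence,
                     steps=pp.DEFAULT_STEPS,
                     t_min: float = pp.DEFAULT_WINDOW[0],
                     t_max: float = pp.DEFAULT_WINDOW[1],
                     min_length: int = 10,
                     ) -> tuple[tm.DynamicMetrics, seg.SegmentationResult]:
    """Run preprocessing, segmentation and metric extraction on one sequence."""
    static = sequence.phase_frames("static")[-1]
    grey = pp.preprocess(static, steps=steps, t_min=t_min, t_max=t_max,
                         source_id="static")
    # a frame in a different thermal state backs the frame-difference fallback
    warm = sequence.phase_frames("rewarming")
    grey_next = None
    if warm:
        grey_next = pp.preprocess(warm[0], steps=steps, t_min=t_min,
                                  t_max=t_max, source_id="rewarming[0]")
    result = seg.segment_hand(grey, grey_next, min_length=min_length)
    curves, keyframes = tm.build_curves(sequence, result.rois)
    return tm.compute_metrics(curves, keyframes), result


def cohort_clinical_table(cohort: list[syn.SubjectProfile]) -> pd.DataFrame:
    """Tidy clinical covariate table, one row per subject."""
    return pd.DataFrame(
        [
            dict(subject_id=s.subject_id, group=s.group, das28=s.das28,
                 rf=s.rf, anti_ccp=s.anti_ccp, tender_joints=s.tender_joints,
                 swollen_joints=s.swollen_joints, esr=s.esr, crp=s.crp)
            for s in cohort
        ]
    )


def run_cohort(cohort: list[syn.SubjectProfile],
               geometry: syn.HandGeometry | None = None,
               config: syn.AcquisitionConfig | None = None,
               ) -> pd.DataFrame:
    """Simulate and process every subject; returns the tidy metric table
    (per-finger rows plus a hand_mean row per subject)."""
    geometry = geometry or syn.default_geometry()
    config = config or syn.AcquisitionConfig()
    frames = []
    for subject in cohort:
        sequence = syn.simulate_sequence(subject, geometry, config)
        result, _ = process_sequence(sequence)
        frames.append(result.to_frame(subject_id=subject.subject_id,
                                      group=subject.group))
    return pd.concat(frames, ignore_index=True)
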