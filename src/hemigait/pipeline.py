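"""End-to-end plumbing: trial -> filtered trial -> events -> metrics record,
and cohort-level table assembly for the statistical and clustering stages."""

from __future__ import annotations

import pandas as pd

from . import events as ev
from . import metrics as mx
from . import preprocess as pp
from .markerio import MarkerTrial, ParticipantMeta


def process_trial(
    trial: MarkerTrial,
    bin_spec="whole",
    *,
    filter_cutoff_hz: float = 6.0,
    filter_order: int = 4,
    apply_filter: bool = True,
    hip_hike_reference: str = "swing_boundary",
) -> mx.GaitMetricsRecord:
    """Filter, detect events, and compute the seven metrics for one trial."""
    if apply_filter:
        trial = pp.lowpass_filter(trial, cutoff=filter_cutoff_hz, order=filter_order)
    bin_ = pp.select_analysis_bin(trial, bin_spec)
    left = ev.detect_events(trial, "left", bin_)
    right = ev.detect_events(trial, "right", bin_)
    table = ev.build_stride_table(left, right, trial.sampling_rate)
    return mx.assemble_record(trial, table, bin_, hip_hike_reference=hip_hike_reference)


def cohort_metrics_table(cohort, **kwargs) -> tuple[pd.DataFrame, list[ParticipantMeta]]:
    """Run the pipeline over a synthetic cohort (flat list of
    (trial, truth, meta) tuples) and return the long metrics table plus the
    deduplicated metadata list."""
    rows, metas, seen = [], [], set()
    for trial, _truth, meta in cohort:
        rec = process_trial(trial, **kwargs)
        rows.append(rec.as_dict())
        if meta.participant_id not in seen:
            seen.add(meta.participant_id)
            metas.append(meta)
    return pd.DataFrame(rows), metas


def condition_table(metrics_table: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Wide per-participant table at one speed condition.

    ``condition`` is "self_selected" (each participant's slowest listed
    speed) or "fast" (their fastest).
    """
    if condition not in ("self_selected", "fast"):
        raise ValueError(f"unknown condition {condition!r}")
    pick = "idxmin" if condition == "self_selected" else "idxmax"
    idx = getattr(metrics_table.groupby("participant_id")["speed_mps"], pick)()
    wide = metrics_table.loc[idx].set_index("participant_id")
    return wide
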