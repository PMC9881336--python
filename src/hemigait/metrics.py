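"""The seven per-participant-per-speed gait metrics, plus cohort inclusion.

Spatiotemporal: step-length asymmetry (SLA), double- and single-limb support
time asymmetry (DLSTA, SLSTA) — all normalized indices |p − n| / (p + n)
between the paretic (or right, for neurotypical participants) and nonparetic
limb.  Kinematic, computed on the paretic/right limb only: peak swing knee
flexion (deg), trailing limb angle at toe-off (deg), swing circumduction (m),
and hip hiking as the swing-phase pelvic-obliquity excursion (deg).  Each
metric is the mean across the valid strides inside the analysis bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import StrideTable, EventDetectionError
from .markerio import MarkerTrial, ParticipantMeta

class MetricError(ValueError):
    pass


@dataclass
class GaitMetricsRecord:
    """Seven metrics for one participant-speed observation.

    Any metric may be None when its markers are missing; missingness is never
    imputed.  ``stride_values`` keeps the per-stride arrays for diagnostics.
    """

    participant_id: str
    group: str
    speed: float
    sla: float | None = None
    dlsta: float | None = None
    slsta: float | None = None
    knee_flex_deg: float | None = None
    tla_deg: float | None = None
    circumduction_m: float | None = None
    hip_hike_deg: float | None = None
    n_strides: int = 0
    stride_values: dict = field(default_factory=dict)
    missing_reasons: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "speed_mps": self.speed,
            "sla": self.sla,
            "dlsta": self.dlsta,
            "slsta": self.slsta,
            "knee_flex_deg": self.knee_flex_deg,
            "tla_deg": self.tla_deg,
            "circumduction_m": self.circumduction_m,
            "hip_hike_deg": self.hip_hike_deg,
            "n_strides": self.n_strides,
        }


def reference_limb(trial_or_side) -> str:
    """Paretic limb for stroke participants, right limb otherwise."""
    side = getattr(trial_or_side, "paretic_side", trial_or_side)
    return side if side in ("left", "right") else "right"


def asymmetry_index(paretic_value: float, nonparetic_value: float) -> float:
    """Normalized absolute asymmetry |p − n| / (p + n), bounded in [0, 1].

    Limb-order invariant by construction, so the paretic/right-limb
    convention cannot flip its sign.
    """
    if paretic_value <= 0 or nonparetic_value <= 0:
        raise MetricError("asymmetry_index requires positive inputs")
    return abs(paretic_value - nonparetic_value) / (paretic_value + nonparetic_value)


# ---------------------------------------------------------------------------
# spatiotemporal


def step_lengths(
    trial: MarkerTrial, stride_table: StrideTable, paretic: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-stride step lengths (paretic, nonparetic), metres.

    Step length of limb L at its foot strike is the fore-aft separation of
    L's malleolus ahead of the contralateral malleolus at that frame.
    Negative values (step-to pattern) are kept with their magnitude.
    """
    p = reference_limb(paretic if paretic is not None else trial)
    n = "right" if p == "left" else "left"
    out = {}
    for limb, contra in ((p, n), (n, p)):
        own = trial.get("lateral_malleolus", limb)[:, 0]
        other = trial.get("lateral_malleolus", contra)[:, 0]
        vals = []
        for _, s in stride_table.limb_strides(limb).iterrows():
            f = int(s.fs_frame)
            sl = own[f] - other[f]
            if not np.isfinite(sl):
                raise MetricError(f"missing contralateral malleolus at frame {f}")
            vals.append(abs(sl))
        out[limb] = np.asarray(vals)
    return out[p], out[n]


def temporal_asymmetries(
    stride_table: StrideTable, paretic: str = "right"
) -> tuple[float, float]:
    """(SLSTA, DLSTA): asymmetry of stride-mean single- and double-limb
    support durations between the paretic and nonparetic limb."""
    p = reference_limb(paretic)
    n = "right" if p == "left" else "left"
    means = {}
    for limb in (p, n):
        df = stride_table.limb_strides(limb)
        ss = df.single_support.dropna()
        ds = df.double_support.dropna()
        if len(ss) < 2 or len(ds) < 2:
            raise MetricError(f"fewer than 2 valid strides on {limb} limb")
        means[limb] = (ss.mean(), ds.mean())
    slsta = asymmetry_index(means[p][0], means[n][0])
    dlsta = asymmetry_index(means[p][1], means[n][1])
    return slsta, dlsta


# ---------------------------------------------------------------------------
# kinematic (reference limb)


def knee_angle_series(trial: MarkerTrial, limb: str) -> np.ndarray:
    """Knee flexion per frame: 180 deg minus the interior angle at the
    lateral femoral epicondyle between the thigh and shank vectors."""
    gt = trial.get("greater_trochanter", limb)
    lfe = trial.get("lateral_femoral_epicondyle", limb)
    lm = trial.get("lateral_malleolus", limb)
    u = gt - lfe
    w = lm - lfe
    cosang = np.einsum("ij,ij->i", u, w) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
    )
    interior = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - interior


def peak_swing_knee_flexion(
    trial: MarkerTrial, stride_table: StrideTable, limb: str
) -> tuple[float, np.ndarray]:
    """Mean over strides of the maximum knee flexion during swing (deg)."""
    for m in ("greater_trochanter", "lateral_femoral_epicondyle", "lateral_malleolus"):
        if not trial.has_marker(m, limb):
            raise MetricError(f"{m} missing on {limb} limb")
    angle = knee_angle_series(trial, limb)
    peaks = []
    for _, s in stride_table.limb_strides(limb).iterrows():
        seg = angle[int(s.toe_off_frame) : int(s.next_fs_frame) + 1]
        if np.isnan(seg).any():
            continue  # swing contains missing samples: stride excluded
        peaks.append(seg.max())
    if len(peaks) < 2:
        raise MetricError("fewer than 2 usable swing phases for knee flexion")
    peaks = np.asarray(peaks)
    return float(peaks.mean()), peaks


def trailing_limb_angle(
    trial: MarkerTrial, stride_table: StrideTable, limb: str
) -> tuple[float, np.ndarray]:
    """Mean trailing limb angle at toe-off (deg).

    Sagittal angle between lab vertical and the hip-to-foot line
    (greater trochanter to fifth metatarsal), positive when the foot is
    posterior to the hip.
    """
    for m in ("greater_trochanter", "fifth_metatarsal"):
        if not trial.has_marker(m, limb):
            raise MetricError(f"{m} missing on {limb} limb")
    gt = trial.get("greater_trochanter", limb)
    mt5 = trial.get("fifth_metatarsal", limb)
    vals = []
    for _, s in stride_table.limb_strides(limb).iterrows():
        f = int(s.toe_off_frame)
        dx = gt[f, 0] - mt5[f, 0]  # positive when foot posterior
        dz = gt[f, 2] - mt5[f, 2]
        if not (np.isfinite(dx) and np.isfinite(dz)):
            continue
        vals.append(math.degrees(math.atan2(dx, dz)))
    if len(vals) < 2:
        raise MetricError("fewer than 2 usable toe-offs for trailing limb angle")
    vals = np.asarray(vals)
    return float(vals.mean()), vals


def circumduction(
    trial: MarkerTrial, stride_table: StrideTable, limb: str
) -> tuple[float, np.ndarray]:
    """Mean swing-phase lateral malleolus excursion (m).

    Per stride: peak lateral (away-from-midline) displacement of the
    malleolus during swing relative to that stride's mean stance-phase
    lateral position; medial displacement floors at 0.
    """
    if not trial.has_marker("lateral_malleolus", limb):
        raise MetricError(f"lateral_malleolus missing on {limb} limb")
    y = trial.get("lateral_malleolus", limb)[:, 1]
    lat_sign = 1.0 if limb == "left" else -1.0
    vals = []
    for _, s in stride_table.limb_strides(limb).iterrows():
        stance = y[int(s.fs_frame) : int(s.toe_off_frame) + 1]
        swing = y[int(s.toe_off_frame) : int(s.next_fs_frame) + 1]
        if np.isnan(swing).any() or np.isnan(stance).all():
            continue
        ref = np.nanmean(stance)
        vals.append(max(0.0, float(np.max(lat_sign * (swing - ref)))))
    if len(vals) < 2:
        raise MetricError("fewer than 2 usable swings for circumduction")
    vals = np.asarray(vals)
    return float(vals.mean()), vals


def pelvic_obliquity_series(trial: MarkerTrial, limb: str) -> np.ndarray:
    """Frontal-plane obliquity of the inter-crest line (deg), positive when
    the ``limb``-side crest is higher."""
    own = trial.get("iliac_crest", limb)
    other = trial.get("iliac_crest", "right" if limb == "left" else "left")
    dz = own[:, 2] - other[:, 2]
    dy = np.abs(own[:, 1] - other[:, 1])
    return np.degrees(np.arctan2(dz, dy))


def hip_hiking(
    trial: MarkerTrial,
    stride_table: StrideTable,
    limb: str,
    reference: str = "swing_boundary",
) -> tuple[float, np.ndarray]:
    """Mean swing-phase hip-hike angle (deg), floored at 0.

    Per stride: peak pelvic obliquity (metric-side crest up) during the
    limb's swing minus a level reference.  ``reference`` selects the
    baseline instant: "swing_boundary" (mean of the obliquity at the
    swing-bounding toe-off and foot strike, i.e. double support, default),
    "stance_mean", or "contralateral_midstance".
    """
    for side in ("left", "right"):
        if not trial.has_marker("iliac_crest", side):
            raise MetricError(f"iliac_crest missing on {side} side")
    psi = pelvic_obliquity_series(trial, limb)
    contra = "right" if limb == "left" else "left"
    vals = []
    for _, s in stride_table.limb_strides(limb).iterrows():
        t_to, t_fs1 = int(s.toe_off_frame), int(s.next_fs_frame)
        seg = psi[t_to : t_fs1 + 1]
        if np.isnan(seg).any():
            continue
        if reference == "swing_boundary":
            ref = 0.5 * (psi[t_to] + psi[t_fs1])
        elif reference == "stance_mean":
            ref = float(np.nanmean(psi[int(s.fs_frame) : t_to + 1]))
        elif reference == "contralateral_midstance":
            cfs = stride_table.foot_strikes[contra]
            cto = stride_table.toe_offs[contra]
            prior_fs = cfs[cfs <= t_to]
            if not len(prior_fs):
                continue
            f0 = int(prior_fs[-1])
            after_to = cto[cto > f0]
            if not len(after_to):
                continue
            ref = psi[(f0 + int(after_to[0])) // 2]
        else:
            raise ValueError(f"unknown hip-hike reference {reference!r}")
        vals.append(max(0.0, float(seg.max() - ref)))
    if len(vals) < 2:
        raise MetricError("fewer than 2 usable swings for hip hiking")
    vals = np.asarray(vals)
    return float(vals.mean()), vals


# ---------------------------------------------------------------------------
# record assembly and inclusion


def assemble_record(
    trial: MarkerTrial,
    stride_table: StrideTable,
    bin: tuple[int, int] | None = None,
    *,
    hip_hike_reference: str = "swing_boundary",
) -> GaitMetricsRecord:
    """Compute all seven metrics on the strides initiated inside the bin.

    Intralimb kinematics use the paretic limb (stroke) or the right limb
    (neurotypical).  Per-metric missing markers flag that metric missing
    while the rest of the record is retained.
    """
    p = reference_limb(trial)
    n = "right" if p == "left" else "left"
    if bin is not None:
        start, end = bin
        mask = (stride_table.strides.fs_frame >= start) & (stride_table.strides.fs_frame < end)
        stride_table = StrideTable(
            sampling_rate=stride_table.sampling_rate,
            foot_strikes=stride_table.foot_strikes,
            toe_offs=stride_table.toe_offs,
            strides=stride_table.strides[mask].reset_index(drop=True),
        )
    n_valid = len(stride_table.limb_strides(p))
    if n_valid < 2:
        raise EventDetectionError("insufficient strides in analysis bin")

    rec = GaitMetricsRecord(
        participant_id=trial.participant_id,
        group=trial.group,
        speed=trial.belt_speed,
        n_strides=n_valid,
    )

    def attempt(name, fn):
        try:
            return fn()
        except MetricError as exc:
            rec.missing_reasons[name] = str(exc)
            return None

    def _sla():
        sp, sn = step_lengths(trial, stride_table, p)
        if len(sp) < 2 or len(sn) < 2:
            raise MetricError("fewer than 2 strides for step length")
        rec.stride_values["step_length_paretic"] = sp
        rec.stride_values["step_length_nonparetic"] = sn
        return asymmetry_index(float(sp.mean()), float(sn.mean()))

    rec.sla = attempt("sla", _sla)

    def _temporal():
        return temporal_asymmetries(stride_table, p)

    tmp = attempt("slsta/dlsta", _temporal)
    if tmp is not None:
        rec.slsta, rec.dlsta = tmp

    for attr, fn in (
        ("knee_flex_deg", lambda: peak_swing_knee_flexion(trial, stride_table, p)),
        ("tla_deg", lambda: trailing_limb_angle(trial, stride_table, p)),
        ("circumduction_m", lambda: circumduction(trial, stride_table, p)),
        (
            "hip_hike_deg",
            lambda: hip_hiking(trial, stride_table, p, reference=hip_hike_reference),
        ),
    ):
        res = attempt(attr, fn)
        if res is not None:
            setattr(rec, attr, res[0])
            rec.stride_values[attr] = res[1]
    return rec


def apply_inclusion_filter(
    metas: list[ParticipantMeta], min_speed: float = 0.20
) -> tuple[list[ParticipantMeta], list[tuple[ParticipantMeta, str]]]:
    """Cohort inclusion: slowest speed strictly above ``min_speed`` m/s and a
    standing calibration present.  Returns (included, excluded-with-reason)."""
    included, excluded = [], []
    for meta in metas:
        if min(meta.speeds) <= min_speed:
            excluded.append(
                (meta, f"slowest speed {min(meta.speeds):.2f} m/s not > {min_speed:.2f}")
            )
        elif not meta.has_calibration:
            excluded.append((meta, "no standing calibration"))
        else:
            included.append(meta)
    return included, excluded
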