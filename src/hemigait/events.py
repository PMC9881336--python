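"""Gait-event detection and stride segmentation from malleolus kinematics.

Foot strike and toe off are defined kinematically for treadmill walking: the
most anterior and most posterior positions of the lateral-malleolus marker's
fore-aft (X) trajectory, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .markerio import MarkerTrial


class EventDetectionError(ValueError):
    pass


def detect_events(
    trial: MarkerTrial,
    limb: str,
    bin: tuple[int, int] | None = None,
    *,
    min_prominence: float = 0.02,
    min_interval_s: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect foot-strike and toe-off frames for one limb.

    Foot strikes are local maxima and toe offs local minima of the malleolus
    fore-aft coordinate, with a minimum prominence (default 0.02 m, rejects
    marker jitter) and a minimum inter-event interval (default 0.2 s, passes
    gait down to very slow belts).  Alternation is enforced by keeping the
    more extreme of two same-type neighbours.  Frames are absolute (trial
    frame numbers), sorted.
    """
    if not trial.has_marker("lateral_malleolus", limb):
        raise EventDetectionError(f"lateral_malleolus missing on {limb} limb")
    start, end = bin if bin is not None else (0, trial.frame_count)
    x = trial.get("lateral_malleolus", limb)[start:end, 0]
    if np.isnan(x).any():
        # detect on finite samples only; gaps inside an extremum window will
        # simply not produce an event there
        x = np.where(np.isfinite(x), x, np.nanmedian(x))
    distance = max(1, int(round(min_interval_s * trial.sampling_rate)))
    peaks, _ = find_peaks(x, prominence=min_prominence, distance=distance)
    troughs, _ = find_peaks(-x, prominence=min_prominence, distance=distance)
    if len(peaks) < 2 or len(troughs) < 1:
        raise EventDetectionError("insufficient strides in analysis bin")

    events = sorted(
        [(int(f), "FS", x[f]) for f in peaks] + [(int(f), "TO", x[f]) for f in troughs]
    )
    cleaned: list[tuple[int, str, float]] = []
    for ev in events:
        if cleaned and cleaned[-1][1] == ev[1]:
            prev = cleaned[-1]
            better = (ev[2] > prev[2]) if ev[1] == "FS" else (ev[2] < prev[2])
            if better:
                cleaned[-1] = ev
        else:
            cleaned.append(ev)
    fs_frames = np.array([f for f, k, _ in cleaned if k == "FS"], dtype=int) + start
    to_frames = np.array([f for f, k, _ in cleaned if k == "TO"], dtype=int) + start
    if len(fs_frames) < 2:
        raise EventDetectionError("insufficient strides in analysis bin")
    return fs_frames, to_frames


@dataclass
class StrideTable:
    """Per-limb event frames and derived per-stride intervals.

    ``strides`` has one row per (limb, stride): frames of the initiating foot
    strike, toe off, and next foot strike; stride/stance/swing durations;
    single- and double-limb support built from contralateral events; and a
    ``flagged`` column marking strides violating event-ordering invariants
    (flagged strides are excluded from metric averages, never silently
    dropped from the table).
    """

    sampling_rate: float
    foot_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    strides: pd.DataFrame

    def limb_strides(self, limb: str, valid_only: bool = True) -> pd.DataFrame:
        df = self.strides[self.strides.limb == limb]
        return df[~df.flagged] if valid_only else df

    @property
    def n_flagged(self) -> int:
        return int(self.strides.flagged.sum())

    def to_events_csv(self, path) -> None:
        rows = []
        for limb in self.foot_strikes:
            for f in self.foot_strikes[limb]:
                rows.append((limb, "foot_strike", int(f), f / self.sampling_rate))
            for f in self.toe_offs[limb]:
                rows.append((limb, "toe_off", int(f), f / self.sampling_rate))
        pd.DataFrame(rows, columns=["limb", "event_type", "frame", "time_s"]).sort_values(
            ["limb", "frame"]
        ).to_csv(path, index=False)


def build_stride_table(
    events_left: tuple[np.ndarray, np.ndarray],
    events_right: tuple[np.ndarray, np.ndarray],
    sampling_rate: float,
) -> StrideTable:
    """Assemble the stride table from both limbs' event frames.

    Per stride of limb L (foot strike i to foot strike i+1):
    stance = toe off − foot strike, swing = next foot strike − toe off,
    single-limb support = the contralateral swing falling inside L's stance,
    leading double support = from L's foot strike to the contralateral toe
    off.  Strides whose contralateral events violate the physiological
    ordering (contralateral foot strike must fall strictly inside the
    ipsilateral stance) are flagged.
    """
    fs = {"left": np.asarray(events_left[0]), "right": np.asarray(events_right[0])}
    to = {"left": np.asarray(events_left[1]), "right": np.asarray(events_right[1])}
    for limb in ("left", "right"):
        if len(fs[limb]) < 2:
            raise EventDetectionError(f"fewer than 2 foot strikes on {limb} limb")

    dt = 1.0 / sampling_rate
    rows = []
    for limb, contra in (("left", "right"), ("right", "left")):
        for i in range(len(fs[limb]) - 1):
            t0, t1 = int(fs[limb][i]), int(fs[limb][i + 1])
            own_to = to[limb][(to[limb] > t0) & (to[limb] < t1)]
            flagged = False
            if len(own_to) != 1:
                rows.append(
                    dict(
                        limb=limb, fs_frame=t0, toe_off_frame=-1, next_fs_frame=t1,
                        stride_time=(t1 - t0) * dt, stance_time=np.nan,
                        swing_time=np.nan, single_support=np.nan,
                        double_support=np.nan, flagged=True,
                    )
                )
                continue
            t_to = int(own_to[0])
            stance, swing = (t_to - t0) * dt, (t1 - t_to) * dt

            c_fs_in = contra_fs = fs[contra][(fs[contra] > t0) & (fs[contra] < t_to)]
            if len(c_fs_in) != 1:
                flagged = True
            c_to_after = to[contra][to[contra] >= t0]
            single = double = np.nan
            if len(c_to_after):
                c_to = int(c_to_after[0])
                if c_to < t_to:
                    double = (c_to - t0) * dt
                    c_fs_next = fs[contra][fs[contra] > c_to]
                    if len(c_fs_next):
                        c_fs = int(c_fs_next[0])
                        single = (c_fs - c_to) * dt
                        if c_fs > t_to:  # contralateral swing leaks past own stance
                            flagged = True
                    else:
                        flagged = True
                else:
                    flagged = True
            else:
                flagged = True
            rows.append(
                dict(
                    limb=limb, fs_frame=t0, toe_off_frame=t_to, next_fs_frame=t1,
                    stride_time=(t1 - t0) * dt, stance_time=stance, swing_time=swing,
                    single_support=single, double_support=double, flagged=flagged,
                )
            )
    strides = pd.DataFrame(rows)
    return StrideTable(
        sampling_rate=sampling_rate,
        foot_strikes=fs,
        toe_offs=to,
        strides=strides,
    )
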