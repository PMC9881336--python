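"""Trajectory conditioning: zero-phase low-pass filtering and analysis bins."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .markerio import MarkerTrial


def _filter_series(x: np.ndarray, b: np.ndarray, a: np.ndarray, padlen: int) -> np.ndarray:
    """Forward-backward filter each finite run of a 1-D series.

    Runs shorter than the padding requirement are left unfiltered; NaN spans
    stay NaN (missingness is never interpolated here).
    """
    out = x.copy()
    finite = np.isfinite(x)
    if finite.all():
        return signal.filtfilt(b, a, x, padlen=padlen)
    edges = np.flatnonzero(np.diff(finite.astype(int)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, len(x)]
    for s, e in zip(starts, ends):
        if not finite[s]:
            continue
        if e - s > padlen:
            out[s:e] = signal.filtfilt(b, a, x[s:e], padlen=padlen)
    return out


def lowpass_filter(trial: MarkerTrial, cutoff: float = 6.0, order: int = 4) -> MarkerTrial:
    """Zero-phase Butterworth low-pass of every marker coordinate.

    ``order`` is the single-pass order (default 4th) before the dual
    forward-backward pass; endpoints are handled by odd-reflection padding of
    3 x (order + 1) samples.  Flagged-missing (NaN) spans are preserved.
    """
    fs = trial.sampling_rate
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist ({fs / 2} Hz)")
    b, a = signal.butter(order, cutoff / (fs / 2), btype="low")
    # at least 3 x order, but long enough for edge transients to decay
    # inside the reflected padding (~0.5 s at 100 Hz)
    padlen = max(3 * (max(len(a), len(b)) - 1), int(round(fs / 2)))
    filtered = {}
    for key, arr in trial.markers.items():
        cols = [_filter_series(arr[:, j], b, a, padlen) for j in range(3)]
        filtered[key] = np.column_stack(cols)
    return trial.copy_with(filtered)


def select_analysis_bin(trial: MarkerTrial, bin_spec: str | tuple = "whole") -> tuple[int, int]:
    """Half-open frame interval [start, end) for the analysis window.

    ``bin_spec`` is "whole", ("middle_seconds", n) or ("final_seconds", n).
    Strides belong to the bin iff their initiating foot strike falls inside it
    (start-inclusive) — enforced downstream by the event modules.
    """
    n = trial.frame_count
    if bin_spec == "whole":
        return (0, n)
    mode, seconds = bin_spec
    span = int(round(seconds * trial.sampling_rate))
    if span > n:
        raise ValueError(
            f"requested {seconds} s bin exceeds trial duration "
            f"({n / trial.sampling_rate:.1f} s)"
        )
    if mode == "middle_seconds":
        start = (n - span) // 2
        return (start, start + span)
    if mode == "final_seconds":
        return (n - span, n)
    raise ValueError(f"unknown bin mode {mode!r}")
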