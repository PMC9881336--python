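"""Marker-trajectory and metadata I/O.

The internal representation is :class:`MarkerTrial`: a named set of bilateral
marker time series (iliac crest, greater trochanter, lateral femoral
epicondyle, lateral malleolus, fifth metatarsal) in a right-handed lab frame
with +X anterior (direction of progression), +Y left, +Z up, units of metres.
Missing samples are explicit NaNs, never silent zeros.

Supported file formats: TRC (OpenSim dialect), long CSV, and — when the
optional ``ezc3d`` package is importable — C3D.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REQUIRED_MARKERS = (
    "iliac_crest",
    "greater_trochanter",
    "lateral_femoral_epicondyle",
    "lateral_malleolus",
    "fifth_metatarsal",
)
SIDES = ("left", "right")

#: Fixed column order of the metrics table written by :func:`write_metrics_table`.
METRICS_COLUMNS = (
    "participant_id",
    "group",
    "speed_mps",
    "sla",
    "dlsta",
    "slsta",
    "knee_flex_deg",
    "tla_deg",
    "circumduction_m",
    "hip_hike_deg",
    "n_strides",
)


class MarkerIOError(ValueError):
    """Raised for malformed or inconsistent marker/metadata files."""


@dataclass
class MarkerTrial:
    """Marker trajectories for one participant at one belt speed.

    ``markers`` maps ``(name, side)`` to an ``(n_frames, 3)`` float array in
    metres, lab frame +X anterior / +Y left / +Z up.  Missing samples are NaN.
    """

    participant_id: str
    group: str  # "stroke" | "neurotypical"
    paretic_side: str  # "left" | "right" | "none"
    belt_speed: float  # m/s
    sampling_rate: float  # Hz
    markers: dict[tuple[str, str], np.ndarray]
    frame_count: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise MarkerIOError("sampling_rate must be > 0")
        counts = {v.shape[0] for v in self.markers.values()}
        if len(counts) > 1:
            raise MarkerIOError(f"frame-count mismatch among markers: {sorted(counts)}")
        if counts:
            n = counts.pop()
            if self.frame_count and self.frame_count != n:
                raise MarkerIOError("frame_count disagrees with marker arrays")
            self.frame_count = n
        for key, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise MarkerIOError(f"marker {key} is not an (n, 3) array")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.frame_count) / self.sampling_rate

    def has_marker(self, name: str, side: str) -> bool:
        """True when the marker exists and is not entirely missing."""
        arr = self.markers.get((name, side))
        return arr is not None and bool(np.isfinite(arr).any())

    def get(self, name: str, side: str) -> np.ndarray:
        arr = self.markers.get((name, side))
        if arr is None:
            raise KeyError(f"marker ({name}, {side}) absent from trial")
        return arr

    def copy_with(self, markers: dict[tuple[str, str], np.ndarray]) -> "MarkerTrial":
        return MarkerTrial(
            participant_id=self.participant_id,
            group=self.group,
            paretic_side=self.paretic_side,
            belt_speed=self.belt_speed,
            sampling_rate=self.sampling_rate,
            markers=markers,
        )


@dataclass
class ParticipantMeta:
    participant_id: str
    group: str
    paretic_side: str
    age: float
    speeds: list[float]
    le_fugl_meyer: int | None = None
    device: str = "none"
    has_calibration: bool = True

    def __post_init__(self) -> None:
        if not self.speeds:
            raise MarkerIOError(f"{self.participant_id}: empty speed list")
        if any(s <= 0 for s in self.speeds):
            raise MarkerIOError(f"{self.participant_id}: non-positive speed")
        if self.le_fugl_meyer is not None and not (0 <= self.le_fugl_meyer <= 34):
            raise MarkerIOError(
                f"{self.participant_id}: LE Fugl-Meyer {self.le_fugl_meyer} outside 0-34"
            )


# ---------------------------------------------------------------------------
# axis remapping


def axis_matrix(axis_map: Mapping[str, str] | None) -> np.ndarray:
    """Build the 3x3 signed-permutation matrix for an axis map.

    ``axis_map`` maps internal axes to signed source axes, e.g.
    ``{"x": "y", "y": "-x", "z": "z"}`` means internal X is source Y.
    The result is orthonormal by construction (permutation with signs).
    """
    if axis_map is None:
        return np.eye(3)
    idx = {"x": 0, "y": 1, "z": 2}
    mat = np.zeros((3, 3))
    for internal, src in axis_map.items():
        src = src.strip().lower()
        sign = -1.0 if src.startswith("-") else 1.0
        mat[idx[internal.lower()], idx[src.lstrip("+-")]] = sign
    if not np.allclose(mat @ mat.T, np.eye(3)):
        raise MarkerIOError(f"axis_map {dict(axis_map)} is not a signed permutation")
    return mat


def _remap(arr: np.ndarray, mat: np.ndarray, scale: float) -> np.ndarray:
    return (arr * scale) @ mat.T


# ---------------------------------------------------------------------------
# TRC


def write_trc(trial: MarkerTrial, path: str | Path) -> None:
    """Write an OpenSim-dialect TRC file (units m, lab frame +X anterior/+Y left/+Z up)."""
    path = Path(path)
    keys = sorted(trial.markers)
    names = [f"{name}_{side[0].upper()}" for name, side in keys]
    n, fs = trial.frame_count, trial.sampling_rate
    with path.open("w", newline="") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write(
            "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
            "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n"
        )
        fh.write(f"{fs:g}\t{fs:g}\t{n}\t{len(keys)}\tm\t{fs:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        coords = "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(keys) + 1))
        fh.write(f"\t\t{coords}\n")
        data = np.column_stack([trial.markers[k] for k in keys])
        t = trial.time
        for i in range(n):
            row = "\t".join("" if not np.isfinite(v) else f"{v:.9f}" for v in data[i])
            fh.write(f"{i + 1}\t{t[i]:.6f}\t{row}\n")


def _parse_trc(path: Path) -> tuple[float, str, dict[str, np.ndarray]]:
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise MarkerIOError(f"{path}: truncated TRC file")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    fs = float(header["DataRate"])
    units = header.get("Units", "m").strip().lower()
    names = [s for s in lines[3].split("\t")[2:] if s.strip()]
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")[2:]
        rows.append([float(c) if c.strip() else np.nan for c in cells])
    width = 3 * len(names)
    data = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        data[i, : min(len(r), width)] = r[:width]
    series = {nm: data[:, 3 * i : 3 * i + 3] for i, nm in enumerate(names)}
    return fs, units, series


# ---------------------------------------------------------------------------
# long CSV


def write_long_csv(trial: MarkerTrial, path: str | Path) -> None:
    """Long CSV: trial_id, time_s, marker, side, x, y, z (units m, +X anterior/+Y left/+Z up)."""
    records = []
    t = trial.time
    for (name, side), arr in sorted(trial.markers.items()):
        df = pd.DataFrame(
            {
                "trial_id": trial.participant_id,
                "time_s": t,
                "marker": name,
                "side": side,
                "x": arr[:, 0],
                "y": arr[:, 1],
                "z": arr[:, 2],
            }
        )
        records.append(df)
    pd.concat(records, ignore_index=True).to_csv(path, index=False, float_format="%.9f")


def _parse_long_csv(path: Path) -> tuple[float, dict[str, np.ndarray]]:
    df = pd.read_csv(path)
    required = {"time_s", "marker", "side", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise MarkerIOError(f"{path}: long CSV missing columns {required - set(df.columns)}")
    times = np.sort(df["time_s"].unique())
    if len(times) < 2:
        raise MarkerIOError(f"{path}: fewer than 2 frames")
    fs = 1.0 / np.median(np.diff(times))
    series: dict[str, np.ndarray] = {}
    counts = set()
    for (name, side), grp in df.groupby(["marker", "side"], sort=True):
        grp = grp.sort_values("time_s")
        arr = grp[["x", "y", "z"]].to_numpy(float)
        series[f"{name}_{side[0].upper()}"] = arr
        counts.add(arr.shape[0])
    if len(counts) > 1:
        raise MarkerIOError(f"{path}: frame-count mismatch among markers")
    return fs, series


# ---------------------------------------------------------------------------
# public readers


def _default_name_map(raw_names: Iterable[str]) -> dict[str, tuple[str, str]]:
    """Map raw marker labels like ``lateral_malleolus_L`` to (name, side)."""
    out = {}
    for raw in raw_names:
        low = raw.strip().lower()
        for side, suffixes in (("left", ("_l", "_left")), ("right", ("_r", "_right"))):
            for suf in suffixes:
                if low.endswith(suf):
                    out[raw] = (low[: -len(suf)], side)
                    break
    return out


def read_trial(
    path: str | Path,
    format: str | None = None,
    *,
    axis_map: Mapping[str, str] | None = None,
    marker_name_map: Mapping[str, tuple[str, str]] | None = None,
    participant_id: str = "",
    group: str = "neurotypical",
    paretic_side: str = "none",
    belt_speed: float = float("nan"),
) -> MarkerTrial:
    """Read a marker trial from TRC, long CSV or C3D into the internal frame.

    ``axis_map`` maps internal axes to signed source axes; ``marker_name_map``
    maps raw labels to ``(canonical_name, side)`` pairs.  Units are converted
    to metres when the file header declares mm.  Missing samples stay NaN.
    """
    path = Path(path)
    if not path.exists():
        raise MarkerIOError(f"no such file: {path}")
    if format is None:
        format = {".trc": "trc", ".csv": "csv", ".c3d": "c3d"}.get(path.suffix.lower(), "trc")

    if format == "trc":
        fs, units, series = _parse_trc(path)
        scale = 0.001 if units == "mm" else 1.0
    elif format == "csv":
        fs, series = _parse_long_csv(path)
        scale = 1.0
    elif format == "c3d":
        fs, units, series = _read_c3d(path)
        scale = 0.001 if units == "mm" else 1.0
    else:
        raise MarkerIOError(f"unsupported format {format!r}")

    mat = axis_matrix(axis_map)
    name_map = dict(marker_name_map) if marker_name_map else _default_name_map(series)
    markers: dict[tuple[str, str], np.ndarray] = {}
    for raw, arr in series.items():
        key = name_map.get(raw)
        if key is None:
            continue
        markers[key] = _remap(arr, mat, scale)

    present = {name for (name, _side) in markers}
    if not set(REQUIRED_MARKERS).issubset(present):
        missing = set(REQUIRED_MARKERS) - present
        raise MarkerIOError(f"{path}: required markers absent after mapping: {sorted(missing)}")

    return MarkerTrial(
        participant_id=participant_id or path.stem,
        group=group,
        paretic_side=paretic_side,
        belt_speed=belt_speed,
        sampling_rate=fs,
        markers=markers,
    )


def _read_c3d(path: Path) -> tuple[float, str, dict[str, np.ndarray]]:
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise MarkerIOError(
            "C3D support requires the optional 'ezc3d' package; "
            "convert to TRC or long CSV, or install hemigait[c3d]"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = c3d["parameters"]["POINT"]["LABELS"]["value"]
    units = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["m"])[0]
    fs = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    series = {lbl: pts[:3, i, :].T.astype(float) for i, lbl in enumerate(labels)}
    return fs, units.lower(), series


# ---------------------------------------------------------------------------
# metadata


def read_metadata(path: str | Path) -> list[ParticipantMeta]:
    """Read a participant metadata CSV.

    Required columns: participant_id, group, paretic_side, age; speeds are
    collected from ``speed_1..speed_k`` columns (empty or "-"/"–" cells mean a
    missing speed).  Optional: le_fugl_meyer, device, has_calibration.
    """
    df = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    required = {"participant_id", "group", "paretic_side", "age"}
    if not required.issubset(df.columns):
        raise MarkerIOError(f"metadata missing columns {required - set(df.columns)}")
    speed_cols = sorted(
        (c for c in df.columns if c.startswith("speed_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not speed_cols:
        raise MarkerIOError("metadata has no speed_* columns")
    if df["participant_id"].duplicated().any():
        dupes = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
        raise MarkerIOError(f"duplicate participant_id: {dupes}")

    metas = []
    for _, row in df.iterrows():
        speeds = []
        for c in speed_cols:
            cell = str(row[c]).strip()
            if cell in ("", "-", "–", "nan", "NA"):
                continue
            speeds.append(float(cell))
        fm_cell = str(row.get("le_fugl_meyer", "")).strip()
        fm = int(float(fm_cell)) if fm_cell not in ("", "nan", "NA") else None
        calib = str(row.get("has_calibration", "true")).strip().lower() not in ("false", "0", "no")
        metas.append(
            ParticipantMeta(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]).strip().lower(),
                paretic_side=str(row["paretic_side"]).strip().lower(),
                age=float(row["age"]),
                speeds=speeds,
                le_fugl_meyer=fm,
                device=str(row.get("device", "none")) or "none",
                has_calibration=calib,
            )
        )
    return metas


def stroke_table_path() -> Path:
    """Path to the bundled 28-participant post-stroke demographics table."""
    return Path(__file__).parent / "data" / "stroke_table1.csv"


# ---------------------------------------------------------------------------
# metrics table


def write_metrics_table(records, path: str | Path) -> None:
    """Write GaitMetricsRecords as a long CSV, one row per participant x speed.

    Missing metrics become empty cells.  Duplicate (participant, speed) rows
    are rejected.
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "speed_mps": rec.speed,
                "sla": rec.sla,
                "dlsta": rec.dlsta,
                "slsta": rec.slsta,
                "knee_flex_deg": rec.knee_flex_deg,
                "tla_deg": rec.tla_deg,
                "circumduction_m": rec.circumduction_m,
                "hip_hike_deg": rec.hip_hike_deg,
                "n_strides": rec.n_strides,
            }
        )
    df = pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
    if len(df) and df.duplicated(subset=["participant_id", "speed_mps"]).any():
        raise MarkerIOError("duplicate (participant, speed) rows in metrics table")
    df.to_csv(path, index=False, float_format="%.12g")


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(METRICS_COLUMNS) - set(df.columns)
    if missing:
        raise MarkerIOError(f"metrics table missing columns {sorted(missing)}")
    return df[list(METRICS_COLUMNS)]


def load_lab_config(path: str | Path) -> dict:
    """Load a per-lab YAML config naming axis_map and marker_name_map."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "marker_name_map" in cfg:
        cfg["marker_name_map"] = {
            raw: (v["name"], v["side"]) if isinstance(v, dict) else tuple(v)
            for raw, v in cfg["marker_name_map"].items()
        }
    return cfg
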