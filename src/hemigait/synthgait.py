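"""Synthetic treadmill-gait generator with closed-form ground truth.

The generator produces bilateral marker trajectories (iliac crest, greater
trochanter, lateral femoral epicondyle, lateral malleolus, fifth metatarsal)
for one participant walking on a treadmill, together with the exact gait-event
times and the seven gait-metric values implied by the parameters.  Every
downstream stage (filtering, event detection, metric computation, group
statistics, clustering) is therefore testable against known truth without any
real motion-capture data.

Kinematic construction
----------------------
The body stays stationary over the belt (+X anterior, +Y left, +Z up).  Each
lateral malleolus translates rearward at the belt speed during stance and
advances with a half-sinusoid velocity profile during swing, so foot strike
and toe off are exactly the anterior and posterior extrema of its fore-aft
trajectory.  The thigh and shank form a planar two-link chain hung from a
fixed hip: the knee-flexion profile is prescribed (zero in stance, half-sine
bump peaking at ``knee_flexion_peak`` in swing) and the hip angle is solved
per frame so the chain's ankle matches the prescribed fore-aft trajectory.
Circumduction is a lateral half-sine excursion of the swing ankle; hip hiking
is a frontal-plane pelvic-obliquity bump during the ipsilateral swing; the
trailing limb angle is realized exactly at toe-off by the placement of the
fifth-metatarsal marker on the foot segment.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .markerio import MarkerTrial, ParticipantMeta

DEG = math.pi / 180.0

METRIC_NAMES = (
    "sla",
    "dlsta",
    "slsta",
    "knee_flex_deg",
    "tla_deg",
    "circumduction_m",
    "hip_hike_deg",
)


class GaitParamError(ValueError):
    """Non-physiological or inconsistent generator parameters."""


@dataclass
class GaitParams:
    """Parameters of one synthetic participant-speed trial.

    ``stride_time`` may be None, in which case it is derived from the
    treadmill constraint ``step_length_left + step_length_right =
    belt_speed * stride_time`` (body stationary over the belt).  An explicit
    stride_time inconsistent with that constraint is rejected.
    """

    belt_speed: float = 1.0  # m/s
    stride_time: float | None = None  # s; None = derived
    stance_fraction_left: float = 0.62
    stance_fraction_right: float = 0.62
    step_length_left: float = 0.55  # m
    step_length_right: float = 0.55  # m
    knee_flexion_peak_left: float = 60.0  # deg
    knee_flexion_peak_right: float = 60.0  # deg
    hip_hike_amp_left: float = 2.0  # deg
    hip_hike_amp_right: float = 2.0  # deg
    circumduction_amp_left: float = 0.01  # m
    circumduction_amp_right: float = 0.01  # m
    tla_peak_left: float = 20.0  # deg
    tla_peak_right: float = 20.0  # deg
    thigh_length: float = 0.41  # m
    shank_length: float = 0.43  # m
    foot_length: float = 0.25  # m
    pelvis_width: float = 0.30  # m
    sampling_rate: float = 100.0  # Hz
    noise_sd: float = 0.0  # m
    n_strides: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("stance_fraction_left", "stance_fraction_right"):
            v = getattr(self, name)
            if not 0.5 < v < 0.9:
                raise GaitParamError(f"{name}={v} outside physiological (0.5, 0.9)")
        for name in (
            "belt_speed",
            "step_length_left",
            "step_length_right",
            "thigh_length",
            "shank_length",
            "foot_length",
            "pelvis_width",
        ):
            if getattr(self, name) <= 0:
                raise GaitParamError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise GaitParamError("noise_sd must be >= 0")
        if self.sampling_rate < 50:
            raise GaitParamError("sampling_rate must be >= 50 Hz")
        if self.n_strides < 2:
            raise GaitParamError("n_strides must be >= 2")
        derived = (self.step_length_left + self.step_length_right) / self.belt_speed
        if self.stride_time is None:
            self.stride_time = derived
        elif abs(self.stride_time - derived) > 1e-6 * derived:
            raise GaitParamError(
                f"stride_time={self.stride_time} inconsistent with treadmill "
                f"constraint (step_length_left + step_length_right)/belt_speed={derived:.4f}"
            )
        if self.stride_time <= 0:
            raise GaitParamError("stride_time must be > 0")
        leg = self.thigh_length + self.shank_length
        if max(self.step_length_left, self.step_length_right) > 1.5 * leg:
            raise GaitParamError(
                "step length exceeds 1.5 x leg length: non-physiological combination"
            )

    @property
    def leg_length(self) -> float:
        return self.thigh_length + self.shank_length


@dataclass
class SyntheticGroundTruth:
    """Exact event times and metric values a correct pipeline must recover."""

    foot_strikes: dict[str, list[float]]  # side -> times (s)
    toe_offs: dict[str, list[float]]
    true_metrics: dict[str, float]  # seven metrics, reference (paretic/right) limb
    params: GaitParams

    def event_frames(self, side: str, kind: str, sampling_rate: float) -> np.ndarray:
        times = self.foot_strikes[side] if kind == "foot_strike" else self.toe_offs[side]
        return np.rint(np.asarray(times) * sampling_rate).astype(int)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "foot_strikes": self.foot_strikes,
            "toe_offs": self.toe_offs,
            "true_metrics": self.true_metrics,
            "params": asdict(self.params),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def true_metrics_from_params(params: GaitParams, ref_side: str) -> dict[str, float]:
    """Closed-form metric values implied by the generator parameters.

    ``ref_side`` is the paretic (or right, for neurotypical) limb used for the
    intralimb metrics and as the "paretic" argument of the asymmetry indices.
    """
    other = "right" if ref_side == "left" else "left"
    p = params

    def side(name, s):
        return getattr(p, f"{name}_{s}")

    sl_p, sl_n = side("step_length", ref_side), side("step_length", other)
    s_p, s_n = side("stance_fraction", ref_side), side("stance_fraction", other)
    T = p.stride_time
    # single-limb support of a limb = contralateral swing duration
    sls_p, sls_n = (1 - s_n) * T, (1 - s_p) * T
    # leading double support of a limb = own FS to contralateral TO
    dls_p, dls_n = (s_n - 0.5) * T, (s_p - 0.5) * T

    def index(a, b):
        return abs(a - b) / (a + b)

    return {
        "sla": index(sl_p, sl_n),
        "dlsta": index(dls_p, dls_n),
        "slsta": index(sls_p, sls_n),
        "knee_flex_deg": side("knee_flexion_peak", ref_side),
        "tla_deg": side("tla_peak", ref_side),
        "circumduction_m": side("circumduction_amp", ref_side),
        "hip_hike_deg": side("hip_hike_amp", ref_side),
    }


def _solve_hip_angle(dx: np.ndarray, knee: np.ndarray, lt: float, ls: float) -> np.ndarray:
    """Solve l_t sin(a) + l_s sin(a - knee) = dx for the hip angle a (rad)."""
    reach = np.sqrt(lt**2 + ls**2 + 2 * lt * ls * np.cos(knee))
    if np.any(np.abs(dx) > 0.995 * reach):
        raise GaitParamError(
            "ankle fore-aft excursion unreachable by the leg chain "
            "(step length too large for segment lengths)"
        )
    alpha = np.arcsin(np.clip(dx / reach, -0.995, 0.995))
    for _ in range(60):
        f = lt * np.sin(alpha) + ls * np.sin(alpha - knee) - dx
        fp = lt * np.cos(alpha) + ls * np.cos(alpha - knee)
        step = f / np.where(np.abs(fp) < 1e-6, 1e-6, fp)
        alpha = alpha - np.clip(step, -0.2, 0.2)
        if np.max(np.abs(f)) < 1e-12:
            break
    if np.max(np.abs(lt * np.sin(alpha) + ls * np.sin(alpha - knee) - dx)) > 1e-8:
        raise GaitParamError("leg-chain inverse kinematics did not converge")
    return alpha


def generate_trial(
    params: GaitParams,
    *,
    participant_id: str = "synthetic",
    group: str = "neurotypical",
    paretic_side: str = "none",
) -> tuple[MarkerTrial, SyntheticGroundTruth]:
    """Generate one treadmill trial and its exact ground truth.

    Timeline: left foot strikes at ``t_off + k*T``, right foot strikes half a
    stride later; stance lasts ``stance_fraction * T`` per limb.  The lead-in
    offset keeps the first events away from the record boundary.
    """
    p = params
    T, v, fs = p.stride_time, p.belt_speed, p.sampling_rate
    lt, ls, leg = p.thigh_length, p.shank_length, p.leg_length
    t_off = 0.25 * T
    duration = t_off + (p.n_strides + 0.6) * T
    t = np.arange(round(duration * fs)) / fs
    rng = np.random.default_rng(p.seed)

    # foot-strike fore-aft positions realizing the requested step lengths
    dsl = (p.step_length_left - p.step_length_right) / 2.0
    c = v * T * (p.stance_fraction_left + p.stance_fraction_right) / 4.0
    x_fs = {"left": c + dsl / 2.0, "right": c - dsl / 2.0}
    phase_off = {"left": 0.0, "right": 0.5 * T}
    hip_y = {"left": +p.pelvis_width / 2.0, "right": -p.pelvis_width / 2.0}
    lat_sign = {"left": +1.0, "right": -1.0}
    hip_z = leg  # straight vertical leg would touch z = 0

    markers: dict[tuple[str, str], np.ndarray] = {}
    swing_bump: dict[str, np.ndarray] = {}
    foot_strikes: dict[str, list[float]] = {}
    toe_offs: dict[str, list[float]] = {}

    for side in ("left", "right"):
        s = getattr(p, f"stance_fraction_{side}")
        kappa_peak = getattr(p, f"knee_flexion_peak_{side}") * DEG
        circ = getattr(p, f"circumduction_amp_{side}")
        tla = getattr(p, f"tla_peak_{side}") * DEG
        d_st, d_sw = s * T, (1 - s) * T
        amp = v * s * T

        phase = np.mod(t - t_off - phase_off[side], T)
        in_stance = phase < d_st
        tau = np.where(in_stance, 0.0, phase - d_st)  # time into swing
        ankle_x = np.where(
            in_stance,
            x_fs[side] - v * phase,
            (x_fs[side] - amp) + amp * 0.5 * (1 - np.cos(np.pi * tau / d_sw)),
        )
        bump = np.where(in_stance, 0.0, np.sin(np.pi * tau / d_sw))
        swing_bump[side] = bump
        ankle_y = hip_y[side] + lat_sign[side] * circ * bump
        knee_flex = kappa_peak * bump

        alpha = _solve_hip_angle(ankle_x, knee_flex, lt, ls)
        knee_x = lt * np.sin(alpha)
        knee_z = hip_z - lt * np.cos(alpha)
        ankle_z = knee_z - ls * np.cos(alpha - knee_flex)

        # fifth metatarsal rides rigidly with the ankle; its fore-aft offset is
        # chosen so the hip-to-MT5 line makes exactly tla_peak with vertical at
        # toe-off (law of the trailing-limb-angle definition)
        h_f = 0.05  # MT5 sits slightly below the malleolus
        x_to = x_fs[side] - amp
        alpha_to = math.asin(max(-0.995, min(0.995, x_to / leg)))
        az_to = hip_z - leg * math.cos(alpha_to)
        f_x = -x_to - math.tan(tla) * (hip_z - az_to + h_f)
        if not -0.5 * p.foot_length <= f_x <= 2.0 * p.foot_length:
            raise GaitParamError(
                f"tla_peak_{side}={tla / DEG:.1f} deg incompatible with limb geometry "
                f"(implied MT5 fore-aft offset {f_x:.3f} m)"
            )

        nfrm = len(t)
        sidekey = side
        markers[("greater_trochanter", sidekey)] = np.column_stack(
            [np.zeros(nfrm), np.full(nfrm, hip_y[side]), np.full(nfrm, hip_z)]
        )
        markers[("lateral_femoral_epicondyle", sidekey)] = np.column_stack(
            [knee_x, np.full(nfrm, hip_y[side]), knee_z]
        )
        markers[("lateral_malleolus", sidekey)] = np.column_stack([ankle_x, ankle_y, ankle_z])
        markers[("fifth_metatarsal", sidekey)] = np.column_stack(
            [ankle_x + f_x, ankle_y, ankle_z - h_f]
        )

        fs_times, to_times = [], []
        k = 0
        while True:
            t_fs = t_off + phase_off[side] + k * T
            if t_fs >= duration - 1.5 / fs:
                break
            fs_times.append(t_fs)
            t_to = t_fs + d_st
            if t_to < duration - 1.5 / fs:
                to_times.append(t_to)
            k += 1
        foot_strikes[side], toe_offs[side] = fs_times, to_times

    # pelvic obliquity: swing-side crest rises by the hip-hike amplitude
    psi = (
        p.hip_hike_amp_left * DEG * swing_bump["left"]
        - p.hip_hike_amp_right * DEG * swing_bump["right"]
    )
    w2 = p.pelvis_width / 2.0
    crest_z0 = hip_z + 0.15
    nfrm = len(t)
    markers[("iliac_crest", "left")] = np.column_stack(
        [np.zeros(nfrm), w2 * np.cos(psi), crest_z0 + w2 * np.sin(psi)]
    )
    markers[("iliac_crest", "right")] = np.column_stack(
        [np.zeros(nfrm), -w2 * np.cos(psi), crest_z0 - w2 * np.sin(psi)]
    )

    if p.noise_sd > 0:
        for key in markers:
            markers[key] = markers[key] + rng.normal(0.0, p.noise_sd, markers[key].shape)

    trial = MarkerTrial(
        participant_id=participant_id,
        group=group,
        paretic_side=paretic_side,
        belt_speed=v,
        sampling_rate=fs,
        markers=markers,
    )
    ref_side = paretic_side if paretic_side in ("left", "right") else "right"
    truth = SyntheticGroundTruth(
        foot_strikes=foot_strikes,
        toe_offs=toe_offs,
        true_metrics=true_metrics_from_params(p, ref_side),
        params=p,
    )
    return trial, truth


def _tla_cap(
    v: float, T: float, stance: dict[str, float], sl: dict[str, float],
    side: str, leg: float, h_f: float = 0.05, margin: float = 0.10,
) -> float:
    """Geometric upper bound (deg) on the realizable trailing limb angle.

    At toe-off the ankle sits at its most posterior point; a slow belt leaves
    it too far forward to realize a large hip-to-foot angle without pushing
    the fifth-metatarsal marker behind the heel.
    """
    amp = v * stance[side] * T
    c = v * T * (stance["left"] + stance["right"]) / 4.0
    dsl = (sl["left"] - sl["right"]) / 2.0
    x_to = c + (dsl / 2.0 if side == "left" else -dsl / 2.0) - amp
    alpha_to = math.asin(max(-0.995, min(0.995, x_to / leg)))
    tan_max = (-x_to + margin) / (leg * math.cos(alpha_to) + h_f)
    return math.degrees(math.atan(max(0.05, tan_max))) * 0.95


def sample_params(
    rng: np.random.Generator,
    belt_speed: float | None = None,
    *,
    noise_sd: float = 0.0,
    n_strides: int = 12,
    grid_aligned: bool = False,
) -> GaitParams:
    """Draw a random physiologically consistent parameter set.

    Belt speed spans the treadmill range 0.2-1.4 m/s unless given.  The
    trailing-limb-angle draw is capped by the geometric bound implied by the
    stance excursion at that speed (slow belts leave the foot too far forward
    at toe-off to realize a large TLA).

    ``grid_aligned`` snaps the stride period (to a multiple of four frames)
    and the stance durations onto the sampling grid, so every ground-truth
    event coincides exactly with a sample.  Recovery sweeps use this to make
    the oracle comparison measure algorithmic correctness rather than
    sub-sample timing resolution; event-detection sweeps leave it off so the
    within-one-frame tolerance is exercised on off-grid events.
    """
    fs = 100.0
    v = float(belt_speed) if belt_speed is not None else float(rng.uniform(0.2, 1.4))
    stride_time = float(np.clip(1.15 * v**-0.42, 0.85, 2.4))
    sla = float(rng.uniform(0.0, 0.25))
    st_asym = float(rng.uniform(0.0, 0.10))
    sides = rng.permutation(["left", "right"])
    stance = {sides[0]: 0.63 - st_asym / 2, sides[1]: 0.63 + st_asym / 2}
    if grid_aligned:
        n_frames = max(84, int(round(stride_time * fs / 4)) * 4)
        stride_time = n_frames / fs
        stance = {k: round(s * n_frames) / n_frames for k, s in stance.items()}
    sl_sum = v * stride_time
    sl = {sides[0]: sl_sum * (1 + sla) / 2, sides[1]: sl_sum * (1 - sla) / 2}
    lt, ls, leg = 0.41, 0.43, 0.84

    # geometric TLA cap at the more restrictive (slower-excursion) limb
    tla_hi = min(
        30.0,
        _tla_cap(v, stride_time, stance, sl, "left", leg),
        _tla_cap(v, stride_time, stance, sl, "right", leg),
    )
    tla_lo = min(4.0, tla_hi * 0.5)

    return GaitParams(
        belt_speed=v,
        stride_time=None,
        stance_fraction_left=stance["left"],
        stance_fraction_right=stance["right"],
        step_length_left=sl["left"],
        step_length_right=sl["right"],
        knee_flexion_peak_left=float(rng.uniform(25, 70)),
        knee_flexion_peak_right=float(rng.uniform(25, 70)),
        hip_hike_amp_left=float(rng.uniform(0.3, 9.0)),
        hip_hike_amp_right=float(rng.uniform(0.3, 9.0)),
        circumduction_amp_left=float(rng.uniform(0.001, 0.06)),
        circumduction_amp_right=float(rng.uniform(0.001, 0.06)),
        tla_peak_left=float(rng.uniform(tla_lo, tla_hi)),
        tla_peak_right=float(rng.uniform(tla_lo, tla_hi)),
        thigh_length=lt,
        shank_length=ls,
        sampling_rate=100.0,
        noise_sd=noise_sd,
        n_strides=n_strides,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class GroupProfile:
    """Distribution of participant-level gait parameters for one group.

    Each ``(mean, sd)`` pair describes between-participant variation at the
    self-selected speed; ``*_slope`` terms are deterministic per-group changes
    per m/s of belt speed above self-selected (signs follow the impairment
    directions reported for treadmill walking post-stroke vs neurotypical).
    ``impairment_sd`` spreads a latent severity factor that co-varies the
    stroke-typical deviations and drives the synthetic Fugl-Meyer score.
    """

    name: str = "neurotypical"
    speed_ss: tuple[float, float] = (1.0, 0.12)
    speed_increment: float = 0.15  # m/s between the four speeds
    sla: tuple[float, float] = (0.02, 0.01)
    stance_asym: tuple[float, float] = (0.006, 0.004)
    knee_flex: tuple[float, float] = (58.0, 3.0)
    tla: tuple[float, float] = (21.0, 2.0)
    hip_hike: tuple[float, float] = (1.5, 0.7)
    circumduction: tuple[float, float] = (0.006, 0.003)
    sla_slope: float = -0.02
    stance_asym_slope: float = -0.01
    knee_slope: float = 12.0
    tla_slope: float = 9.6
    hip_hike_slope: float = -0.8
    circ_slope: float = 0.004
    impairment_sd: float = 0.0
    noise_sd: float = 0.001
    n_strides: int = 25

    def __post_init__(self) -> None:
        for fname in ("speed_ss", "sla", "stance_asym", "knee_flex", "tla", "hip_hike", "circumduction"):
            if getattr(self, fname)[1] < 0:
                raise GaitParamError(f"{fname} sd must be >= 0")
        if self.impairment_sd < 0:
            raise GaitParamError("impairment_sd must be >= 0")


NEUROTYPICAL_PROFILE = GroupProfile()

#: Hemiparetic profile: heterogeneous severity (latent impairment factor) with
#: larger asymmetries, reduced knee flexion and trailing limb angle, increased
#: hip hiking and circumduction; speed slopes follow the directions observed
#: in treadmill studies of post-stroke gait (step-length asymmetry and TLA
#: deficits shrink with speed, temporal asymmetries and hip hiking grow).
STROKE_PROFILE = GroupProfile(
    name="stroke",
    speed_ss=(0.62, 0.18),
    speed_increment=0.15,
    sla=(0.13, 0.035),
    stance_asym=(0.055, 0.015),
    knee_flex=(42.0, 5.0),
    tla=(14.0, 2.5),
    hip_hike=(6.5, 1.5),
    circumduction=(0.035, 0.008),
    sla_slope=-0.13,
    stance_asym_slope=0.05,
    knee_slope=4.0,
    tla_slope=11.9,
    hip_hike_slope=0.8,
    circ_slope=-0.001,
    impairment_sd=0.45,
)


def well_separated_profiles(
    separation_sd: float = 3.0, divergent_speed: bool = False
) -> tuple[GroupProfile, GroupProfile]:
    """Two homogeneous profiles whose metric means differ by at least
    ``separation_sd`` pooled standard deviations on every metric axis.

    Used for recovery experiments where the cluster structure must be known.
    With ``divergent_speed`` the stroke group's deviations all grow with belt
    speed (relative to the neurotypical slopes), so the groups separate
    further at the fast condition.
    """
    base_nt = GroupProfile(
        name="neurotypical",
        sla=(0.02, 0.012),
        stance_asym=(0.006, 0.005),
        knee_flex=(58.0, 2.5),
        tla=(21.0, 1.8),
        hip_hike=(1.5, 0.7),
        circumduction=(0.006, 0.003),
        impairment_sd=0.0,
    )
    s = separation_sd

    def shift(mean_sd, pooled_like, direction):
        mean, sd = mean_sd
        return (mean + direction * s * pooled_like, sd)

    base_st = GroupProfile(
        name="stroke",
        speed_ss=(0.62, 0.15),
        sla=shift(base_nt.sla, 0.02, +1),
        stance_asym=shift(base_nt.stance_asym, 0.012, +1),
        knee_flex=shift(base_nt.knee_flex, 3.5, -1),
        tla=shift(base_nt.tla, 2.2, -1),
        hip_hike=shift(base_nt.hip_hike, 1.2, +1),
        circumduction=shift(base_nt.circumduction, 0.006, +1),
        sla_slope=0.06 if divergent_speed else -0.10,
        stance_asym_slope=0.05,
        knee_slope=2.0 if divergent_speed else 4.0,
        tla_slope=4.0 if divergent_speed else 11.9,
        hip_hike_slope=2.0 if divergent_speed else 0.8,
        circ_slope=0.02 if divergent_speed else -0.001,
        impairment_sd=0.0,
    )
    return base_nt, base_st


def _draw_participant_params(
    profile: GroupProfile, rng: np.random.Generator
) -> tuple[dict, float]:
    """Draw participant-level parameter set (at self-selected speed) and the
    latent impairment factor (0 for a fully neurotypical draw)."""
    u = float(np.clip(rng.normal(1.0, profile.impairment_sd), 0.05, 2.2)) if profile.impairment_sd > 0 else 0.0
    scale = u if u > 0 else 1.0

    def draw(mean_sd, lo=None, hi=None, severity=False):
        mean, sd = mean_sd
        val = rng.normal(mean * (scale if severity else 1.0), sd)
        if lo is not None:
            val = max(lo, val)
        if hi is not None:
            val = min(hi, val)
        return float(val)

    severity = profile.impairment_sd > 0
    base = {
        "speed_ss": draw(profile.speed_ss, lo=0.25),
        "sla": draw(profile.sla, lo=0.002, hi=0.45, severity=severity),
        "stance_asym": draw(profile.stance_asym, lo=0.001, hi=0.18, severity=severity),
        "knee_flex": draw(
            (profile.knee_flex[0] if not severity else 58.0 - (58.0 - profile.knee_flex[0]) * scale,
             profile.knee_flex[1]),
            lo=15.0, hi=75.0,
        ),
        "tla": draw(
            (profile.tla[0] if not severity else 21.0 - (21.0 - profile.tla[0]) * scale,
             profile.tla[1]),
            lo=4.0, hi=32.0,
        ),
        "hip_hike": draw(profile.hip_hike, lo=0.1, hi=14.0, severity=severity),
        "circumduction": draw(profile.circumduction, lo=0.0005, hi=0.09, severity=severity),
    }
    return base, u


def _params_at_speed(
    base: dict, profile: GroupProfile, speed: float, noise_sd: float,
    paretic: str, seed: int, n_strides: int,
) -> GaitParams:
    dv = speed - base["speed_ss"]
    sla = float(np.clip(base["sla"] + profile.sla_slope * dv, 0.002, 0.45))
    st_asym = float(np.clip(base["stance_asym"] + profile.stance_asym_slope * dv, 0.001, 0.18))
    knee = float(np.clip(base["knee_flex"] + profile.knee_slope * dv, 12.0, 78.0))
    tla = float(np.clip(base["tla"] + profile.tla_slope * dv, 3.0, 33.0))
    hh = float(np.clip(base["hip_hike"] + profile.hip_hike_slope * dv, 0.05, 15.0))
    circ = float(np.clip(base["circumduction"] + profile.circ_slope * dv, 0.0003, 0.10))

    # cadence grows with speed: stride time shrinks as a power law
    stride_time = float(np.clip(1.15 * (speed / 1.0) ** (-0.42), 0.85, 2.4))
    sl_sum = speed * stride_time
    other = "right" if paretic == "left" else "left"
    sl = {paretic: sl_sum * (1 + sla) / 2.0, other: sl_sum * (1 - sla) / 2.0}
    s_base = 0.63
    stance = {paretic: s_base - st_asym / 2.0, other: s_base + st_asym / 2.0}
    hip_hike = {paretic: hh, other: min(hh, 1.5)}
    circd = {paretic: circ, other: min(circ, 0.008)}
    # contralateral intralimb kinematics stay near neurotypical values
    knee_d = {paretic: knee, other: max(knee, 55.0)}
    leg = 0.41 + 0.43
    cap = {
        s: min(33.0, _tla_cap(speed, stride_time, stance, sl, s, leg))
        for s in ("left", "right")
    }
    tla_d = {paretic: tla, other: max(tla, 20.0)}
    tla_d = {s: float(np.clip(tla_d[s], 3.0, cap[s])) for s in ("left", "right")}

    return GaitParams(
        belt_speed=speed,
        stride_time=None,
        stance_fraction_left=stance["left"],
        stance_fraction_right=stance["right"],
        step_length_left=sl["left"],
        step_length_right=sl["right"],
        knee_flexion_peak_left=knee_d["left"],
        knee_flexion_peak_right=knee_d["right"],
        hip_hike_amp_left=hip_hike["left"],
        hip_hike_amp_right=hip_hike["right"],
        circumduction_amp_left=circd["left"],
        circumduction_amp_right=circd["right"],
        tla_peak_left=tla_d["left"],
        tla_peak_right=tla_d["right"],
        sampling_rate=100.0,
        noise_sd=noise_sd,
        n_strides=n_strides,
        seed=seed,
    )


def generate_cohort(
    n_per_group: int,
    group_profiles: tuple[GroupProfile, GroupProfile] = (NEUROTYPICAL_PROFILE, STROKE_PROFILE),
    seed: int = 0,
    *,
    n_speeds: int = 4,
    noise_sd: float | None = None,
    n_strides: int | None = None,
) -> list[tuple[MarkerTrial, SyntheticGroundTruth, ParticipantMeta]]:
    """Generate a two-group cohort walking at multiple belt speeds.

    Returns a flat list of (trial, ground truth, metadata) tuples; each
    participant contributes ``n_speeds`` trials, metadata repeated.  Synthetic
    Fugl-Meyer scores (stroke group only) are anticorrelated with the latent
    impairment factor.  Fully reproducible: participant ``i`` uses the
    substream ``(seed, i)``, so excluding one participant leaves the others
    bit-identical.
    """
    if n_per_group < 1:
        raise GaitParamError("n_per_group must be >= 1")
    out = []
    pidx = 0
    for profile in group_profiles:
        group = "stroke" if profile.name == "stroke" else "neurotypical"
        for j in range(n_per_group):
            rng = np.random.default_rng(np.random.SeedSequence([seed, pidx]))
            base, u = _draw_participant_params(profile, rng)
            paretic = ("left", "right")[int(rng.integers(2))] if group == "stroke" else "none"
            ref = paretic if paretic != "none" else "right"
            speeds = [
                round(base["speed_ss"] + k * profile.speed_increment, 3)
                for k in range(n_speeds)
            ]
            fm = None
            if group == "stroke":
                fm = int(np.clip(round(34 - 11.5 * u + rng.normal(0, 1.5)), 0, 34))
            meta = ParticipantMeta(
                participant_id=f"{'S' if group == 'stroke' else 'N'}{pidx:03d}",
                group=group,
                paretic_side=paretic,
                age=float(np.clip(rng.normal(62, 9), 35, 85)),
                speeds=speeds,
                le_fugl_meyer=fm,
                has_calibration=True,
            )
            ns = n_strides if n_strides is not None else profile.n_strides
            nsd = noise_sd if noise_sd is not None else profile.noise_sd
            for k, speed in enumerate(speeds):
                params = _params_at_speed(
                    base, profile, speed, nsd, ref,
                    seed=int(rng.integers(0, 2**31 - 1)), n_strides=ns,
                )
                trial, truth = generate_trial(
                    params,
                    participant_id=meta.participant_id,
                    group=group,
                    paretic_side=paretic,
                )
                out.append((trial, truth, meta))
            pidx += 1
    return out
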