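"""Marker-trajectory kinematics: gait events, time-distance parameters,
joint/trunk/pelvis angle curves, and ranges of motion.

Conventions
-----------
Lab frame: x = progression, y = mediolateral (left positive), z = vertical.
Heel strikes and toe-offs are the maxima and minima of the *limb angle*, the
sagittal-plane angle between the vertical through the greater trochanter and
the trochanter-to-lateral-malleolus vector (0 deg with the malleolus
vertically below the trochanter; positive with the limb in front of the
vertical).  A gait cycle is the interval between two successive heel strikes
of the same leg; each cycle's angle curves are time-normalized to 101
samples by piecewise-cubic interpolation.  RoM = max - min over the cycle.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks
from scipy.spatial.transform import Rotation

__all__ = [
    "MARKER_NAMES",
    "MarkerTrajectorySet",
    "GaitEvents",
    "InsufficientStridesError",
    "limb_angle",
    "detect_gait_events",
    "segment_cycles",
    "time_distance_params",
    "joint_angles",
    "rom",
    "extract_features",
]

#: Canonical marker set: C7, sacrum, and bilateral acromion, ASIS, greater
#: trochanter, lateral femoral condyle, fibula head, lateral malleolus and
#: metatarsal head.
MARKER_NAMES: tuple[str, ...] = ("c7", "sacrum") + tuple(
    f"{s}_{m}"
    for s in ("l", "r")
    for m in ("acromion", "asis", "trochanter", "knee", "fibula_head", "malleolus", "metatarsal")
)

#: Angle curve names produced by :func:`joint_angles`.
ANGLE_NAMES: tuple[str, ...] = (
    "hip",
    "knee",
    "ankle",
    "trunk_lateral_bending",
    "trunk_flexion_extension",
    "trunk_rotation",
    "pelvis_obliquity",
    "pelvis_rotation",
    "pelvis_tilt",
)


class InsufficientStridesError(ValueError):
    """Raised when a trial contains fewer than two detectable strides."""


@dataclass
class MarkerTrajectorySet:
    """Time-indexed 3-D positions (metres) of named markers for one trial."""

    rate: float
    markers: dict[str, np.ndarray]

    def __post_init__(self):
        lengths = {m.shape[0] for m in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError("all marker arrays must have the same frame count")
        for name, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r} must be Fx3")
            if np.isnan(arr).any():
                raise ValueError(f"marker {name!r} contains NaN")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise KeyError(f"missing marker {name!r}") from None

    def filtered(self, cutoff_hz: float = 6.0, order: int = 4) -> "MarkerTrajectorySet":
        """Zero-phase low-pass Butterworth copy (effective order ``order``,
        applied forward-backward)."""
        nyq = self.rate / 2.0
        if cutoff_hz >= nyq:
            return MarkerTrajectorySet(self.rate, {k: v.copy() for k, v in self.markers.items()})
        b, a = butter(order // 2, cutoff_hz / nyq)
        out = {k: filtfilt(b, a, v, axis=0) for k, v in self.markers.items()}
        return MarkerTrajectorySet(self.rate, out)

    # -- plain-text interchange --------------------------------------------
    def to_csv(self, path) -> None:
        """Write ``time,<marker>_x,<marker>_y,<marker>_z,...`` with the
        sampling rate in a ``# rate_hz=`` comment line."""
        t = np.arange(self.n_frames) / self.rate
        cols = {"time": t}
        for name in sorted(self.markers):
            for j, ax in enumerate("xyz"):
                cols[f"{name}_{ax}"] = self.markers[name][:, j]
        df = pd.DataFrame(cols)
        buf = io.StringIO()
        buf.write(f"# rate_hz={self.rate:g}\n")
        df.to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "MarkerTrajectorySet":
        rate = None
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#") and "rate_hz=" in first:
                rate = float(first.split("rate_hz=")[1].strip())
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        if rate is None:
            t = df["time"].to_numpy()
            rate = 1.0 / np.median(np.diff(t))
        names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
        markers = {
            n: np.column_stack([df[f"{n}_{ax}"].to_numpy(float) for ax in "xyz"])
            for n in names
        }
        return cls(rate=rate, markers=markers)


@dataclass
class GaitEvents:
    """Heel-strike and toe-off frame indices of one limb (sorted,
    alternating)."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self):
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)


def limb_angle(trochanter: np.ndarray, malleolus: np.ndarray) -> np.ndarray:
    """Signed sagittal-plane limb angle in degrees, per frame.

    0 deg with the malleolus vertically below the trochanter; positive with
    the limb in front of the vertical (flexion), negative behind.
    """
    trochanter = np.asarray(trochanter, dtype=float)
    malleolus = np.asarray(malleolus, dtype=float)
    if trochanter.shape != malleolus.shape:
        raise ValueError("trochanter and malleolus must have equal shapes")
    d = malleolus - trochanter
    norm = np.hypot(d[:, 0], d[:, 2])
    bad = np.nonzero(norm < 1e-9)[0]
    if bad.size:
        raise ValueError(f"coincident trochanter/malleolus markers at frame {bad[0]}")
    return np.degrees(np.arctan2(d[:, 0], -d[:, 2]))


def _sagittal_angle(proximal: np.ndarray, distal: np.ndarray) -> np.ndarray:
    """Sagittal angle from vertical of the proximal->distal segment."""
    d = distal - proximal
    return np.degrees(np.arctan2(d[:, 0], -d[:, 2]))


def _smooth(series: np.ndarray, rate: float, cutoff_hz: float = 6.0) -> np.ndarray:
    nyq = rate / 2.0
    if cutoff_hz >= nyq or series.size < 15:
        return series
    b, a = butter(2, cutoff_hz / nyq)
    return filtfilt(b, a, series)


def detect_gait_events(
    angle: np.ndarray, rate: float, smooth: bool = True
) -> GaitEvents:
    """Detect heel strikes (limb-angle maxima) and toe-offs (minima).

    The series is low-pass smoothed before peak picking; strict alternation
    is enforced by discarding the lesser of two consecutive same-type
    extrema.  At flat extrema the first frame of the plateau is used.
    """
    s = np.asarray(angle, dtype=float)
    if smooth:
        s = _smooth(s, rate)
    amp = s.max() - s.min()
    if amp < 1e-9:
        raise InsufficientStridesError("constant limb-angle series: no strides found")
    # Plateau tie-break: take the first frame of a flat extremum.
    maxima, props = find_peaks(s, prominence=0.1 * amp, plateau_size=(None, None))
    maxima = props["left_edges"]
    minima, props = find_peaks(-s, prominence=0.1 * amp, plateau_size=(None, None))
    minima = props["left_edges"]
    if len(maxima) < 2:
        raise InsufficientStridesError(
            f"insufficient strides: {len(maxima)} heel strike(s) detected"
        )
    events = sorted(
        [(f, "hs") for f in maxima] + [(f, "to") for f in minima]
    )
    kept: list[tuple[int, str]] = []
    for frame, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (s[frame] > s[prev]) if kind == "hs" else (s[frame] < s[prev])
            if better:
                kept[-1] = (frame, kind)
        else:
            kept.append((frame, kind))
    hs = np.array([f for f, k in kept if k == "hs"], dtype=int)
    to = np.array([f for f, k in kept if k == "to"], dtype=int)
    if len(hs) < 2:
        raise InsufficientStridesError(
            f"insufficient strides: {len(hs)} heel strike(s) after alternation"
        )
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def segment_cycles(events: GaitEvents) -> list[tuple[int, int]]:
    """Gait cycles as consecutive same-limb heel-strike pairs."""
    hs = events.heel_strikes
    return [(int(hs[i]), int(hs[i + 1])) for i in range(len(hs) - 1)]


def detect_all_events(mts: MarkerTrajectorySet, smooth: bool = True) -> dict[str, GaitEvents]:
    """Left/right gait events from the trochanter/malleolus markers."""
    out = {}
    for side in ("l", "r"):
        ang = limb_angle(mts[f"{side}_trochanter"], mts[f"{side}_malleolus"])
        out[side] = detect_gait_events(ang, mts.rate, smooth=smooth)
    return out


def limb_length(mts: MarkerTrajectorySet, side: str = "l") -> float:
    """Mean trochanter-to-lateral-malleolus distance over the trial."""
    d = mts[f"{side}_malleolus"] - mts[f"{side}_trochanter"]
    return float(np.linalg.norm(d, axis=1).mean())


def _first_between(arr: np.ndarray, lo: int, hi: int) -> int | None:
    inside = arr[(arr > lo) & (arr < hi)]
    return int(inside[0]) if inside.size else None


def time_distance_params(
    mts: MarkerTrajectorySet,
    events: dict[str, GaitEvents],
    limb_len: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-stride time-distance parameters and their subject average.

    Per cycle (same-limb heel strike to heel strike): walking speed from the
    sacrum progression distance over the cycle duration; cadence in steps/s;
    step length/width from the progression/mediolateral distance between the
    contralateral and ipsilateral malleoli at their respective heel strikes,
    normalized to limb length; stride length likewise over the full cycle;
    stance% from the ipsilateral toe-off; double supports from the bilateral
    event interleaving.  Cycles lacking contralateral events have their step
    metrics set to NaN (flagged absent); the subject average skips them.
    """
    if limb_len <= 0:
        raise ValueError("limb length must be > 0")
    fs = mts.rate
    sac_x = mts["sacrum"][:, 0]
    rows = []
    for side in ("l", "r"):
        other = "r" if side == "l" else "l"
        mal = mts[f"{side}_malleolus"]
        mal_c = mts[f"{other}_malleolus"]
        for hs0, hs1 in segment_cycles(events[side]):
            T = (hs1 - hs0) / fs
            row = {
                "side": side,
                "start_frame": hs0,
                "gait_speed": (sac_x[hs1] - sac_x[hs0]) / T,
                "cadence": 2.0 / T,
                "stride_length": (mal[hs1, 0] - mal[hs0, 0]) / limb_len,
            }
            to_i = _first_between(events[side].toe_offs, hs0, hs1)
            if to_i is not None:
                row["stance_duration"] = 100.0 * (to_i - hs0) / (hs1 - hs0)
                row["swing_duration"] = 100.0 - row["stance_duration"]
            hs_c = _first_between(events[other].heel_strikes, hs0, hs1)
            if hs_c is not None:
                row["step_length"] = (mal_c[hs_c, 0] - mal[hs0, 0]) / limb_len
                row["step_width"] = abs(mal_c[hs_c, 1] - mal[hs0, 1]) / limb_len
                to_c = _first_between(events[other].toe_offs, hs0, hs_c)
                if to_c is not None:
                    row["double_support_1"] = 100.0 * (to_c - hs0) / (hs1 - hs0)
                if to_i is not None and to_i > hs_c:
                    row["double_support_2"] = 100.0 * (to_i - hs_c) / (hs1 - hs0)
            rows.append(row)
    per_stride = pd.DataFrame(rows)
    value_cols = [c for c in per_stride.columns if c not in ("side", "start_frame")]
    return per_stride, per_stride[value_cols].mean()


def _orthonormal_frame(x0: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """Right-handed frames (F,3,3) from approximate forward (x) and left (y)
    directions; y is kept exact, x orthogonalized against it."""
    y = y0 / np.linalg.norm(y0, axis=1, keepdims=True)
    x = x0 - np.sum(x0 * y, axis=1, keepdims=True) * y
    x = x / np.linalg.norm(x, axis=1, keepdims=True)
    z = np.cross(x, y)
    return np.stack([x, y, z], axis=2)


def _frame_from_zy(z0: np.ndarray, y0: np.ndarray) -> np.ndarray:
    y = y0 / np.linalg.norm(y0, axis=1, keepdims=True)
    z = z0 - np.sum(z0 * y, axis=1, keepdims=True) * y
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=2)


def _euler_zxy(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rotation, frontal, sagittal) plane angles in degrees from rotation
    matrices, intrinsic Z-X-Y decomposition."""
    ang = Rotation.from_matrix(R).as_euler("ZXY", degrees=True)
    return ang[:, 0], ang[:, 1], ang[:, 2]


def _resample_101(series: np.ndarray, start: int, end: int) -> np.ndarray:
    """Piecewise-cubic time normalization of one cycle to 101 samples."""
    seg = series[start : end + 1]
    x = np.linspace(0.0, 1.0, seg.size)
    if seg.size < 4:
        return np.interp(np.linspace(0, 1, 101), x, seg)
    return CubicSpline(x, seg)(np.linspace(0.0, 1.0, 101))


def joint_angles(
    mts: MarkerTrajectorySet,
    events: dict[str, GaitEvents],
) -> dict[str, list[np.ndarray]]:
    """Per-cycle 101-sample angle curves (degrees).

    Simplified segment frames: the pelvis from the ASIS pair and sacrum, the
    trunk from C7 and the acromia expressed relative to the pelvis, and the
    thigh/shank/foot from their marker pairs.  Sagittal hip/knee/ankle are
    inter-segment angles; pelvis and trunk orientations are decomposed into
    transverse (rotation), frontal (obliquity / lateral bending) and
    sagittal (tilt / flexion-extension) plane angles.  Hip/knee/ankle curves
    pool both limbs' cycles; trunk and pelvis curves use the left limb's
    cycles.
    """
    for m in MARKER_NAMES:
        if m not in mts.markers:
            raise KeyError(f"missing marker {m!r}")

    mid_asis = (mts["l_asis"] + mts["r_asis"]) / 2
    R_pel = _orthonormal_frame(mid_asis - mts["sacrum"], mts["l_asis"] - mts["r_asis"])
    pel_rot, pel_obl, pel_tilt = _euler_zxy(R_pel)

    mid_acr = (mts["l_acromion"] + mts["r_acromion"]) / 2
    R_trunk = _frame_from_zy(mts["c7"] - mid_acr, mts["l_acromion"] - mts["r_acromion"])
    R_rel = np.einsum("fij,fik->fjk", R_pel, R_trunk)  # pelvis^T . trunk
    trk_rot, trk_lat, trk_fe = _euler_zxy(R_rel)

    trial_curves: dict[str, dict[str, np.ndarray]] = {
        "pelvis_rotation": {"l": pel_rot},
        "pelvis_obliquity": {"l": pel_obl},
        "pelvis_tilt": {"l": pel_tilt},
        "trunk_rotation": {"l": trk_rot},
        "trunk_lateral_bending": {"l": trk_lat},
        "trunk_flexion_extension": {"l": trk_fe},
        "hip": {},
        "knee": {},
        "ankle": {},
    }
    for side in ("l", "r"):
        a_thigh = _sagittal_angle(mts[f"{side}_trochanter"], mts[f"{side}_knee"])
        a_shank = _sagittal_angle(mts[f"{side}_knee"], mts[f"{side}_malleolus"])
        a_foot = _sagittal_angle(mts[f"{side}_malleolus"], mts[f"{side}_metatarsal"])
        trial_curves["hip"][side] = a_thigh
        trial_curves["knee"][side] = a_thigh - a_shank
        trial_curves["ankle"][side] = a_shank + 90.0 - a_foot

    out: dict[str, list[np.ndarray]] = {name: [] for name in ANGLE_NAMES}
    for name, per_side in trial_curves.items():
        for side, series in per_side.items():
            for hs0, hs1 in segment_cycles(events[side]):
                out[name].append(_resample_101(series, hs0, hs1))
    return out


def rom(curve: np.ndarray) -> float:
    """Range of motion: max - min of an angle curve (degrees)."""
    curve = np.asarray(curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty curve")
    return float(curve.max() - curve.min())


def subject_roms(curves: dict[str, list[np.ndarray]]) -> dict[str, float]:
    """Per-angle subject RoM: mean of per-cycle RoMs."""
    return {
        name: float(np.mean([rom(c) for c in cycles]))
        for name, cycles in curves.items()
        if cycles
    }


def extract_features(
    mts: MarkerTrajectorySet,
    filter_cutoff_hz: float | None = 6.0,
) -> dict[str, float]:
    """Full per-trial feature extraction: the 18 canonical gait features.

    Markers are low-pass filtered (zero-phase Butterworth), events detected
    from the limb angle, time-distance parameters averaged over strides, and
    RoMs averaged over cycles.
    """
    work = mts.filtered(filter_cutoff_hz) if filter_cutoff_hz else mts
    events = detect_all_events(work, smooth=False)
    ll = float(np.mean([limb_length(work, s) for s in ("l", "r")]))
    _, td_mean = time_distance_params(work, events, ll)
    curves = joint_angles(work, events)
    roms = subject_roms(curves)
    feats = dict(td_mean)
    feats.pop("start_frame", None)
    for angle, feat in (
        ("hip", "rom_hip"),
        ("knee", "rom_knee"),
        ("ankle", "rom_ankle"),
        ("trunk_lateral_bending", "trunk_lateral_bending"),
        ("trunk_flexion_extension", "trunk_flexion_extension"),
        ("trunk_rotation", "trunk_rotation"),
        ("pelvis_obliquity", "pelvis_obliquity"),
        ("pelvis_rotation", "pelvis_rotation"),
        ("pelvis_tilt", "pelvis_tilt"),
    ):
        if angle in roms:
            feats[feat] = roms[angle]
    return {k: float(v) for k, v in feats.items()}
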