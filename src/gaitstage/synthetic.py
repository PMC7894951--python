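"""Synthetic gait cohorts and marker-level walking trials with ground truth.

Two generators:

* :func:`generate_feature_cohort` draws per-subject 18-feature vectors from
  group-wise multivariate normals parameterized (by default) with the
  published healthy/patient population means and SDs, with a documented
  monotone decline of speed and RoMs across Hoehn-Yahr stages 1-4.
* :func:`generate_marker_walk` builds a planar-dominant forward-kinematic
  walker (pelvis -> hip -> knee -> ankle -> foot, plus trunk/pelvis marker
  clusters) driven by prescribed periodic joint waveforms, and returns the
  marker trajectories together with exact ground-truth gait events and the
  RoMs implied by the waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .features import (
    CANONICAL_FEATURES,
    GROUP_LABELS,
    PHASE_FEATURES,
    ROM_FEATURES,
)
from .kinematics import MarkerTrajectorySet

__all__ = [
    "POPULATION",
    "CohortSpec",
    "GroupSpec",
    "FourierWaveform",
    "GaitProfile",
    "WalkGroundTruth",
    "default_cohort_spec",
    "default_gait_profile",
    "generate_feature_cohort",
    "generate_marker_walk",
]

KMH_TO_MS = 1.0 / 3.6

#: Published population mean +- SD per feature: (PwPD mean, PwPD sd, HS mean,
#: HS sd).  Speeds converted from km/h to m/s; everything else as printed.
POPULATION: dict[str, tuple[float, float, float, float]] = {
    "gait_speed": (2.87 * KMH_TO_MS, 1.07 * KMH_TO_MS, 3.18 * KMH_TO_MS, 0.91 * KMH_TO_MS),
    "stance_duration": (65.66, 3.49, 65.54, 3.13),
    "swing_duration": (34.34, 3.49, 34.46, 3.13),
    "double_support_1": (15.74, 3.68, 15.40, 3.16),
    "double_support_2": (15.48, 3.42, 15.50, 3.20),
    "step_length": (0.68, 0.14, 0.77, 0.10),
    "step_width": (0.30, 0.05, 0.28, 0.05),
    "stride_length": (1.19, 0.32, 1.43, 0.23),
    "cadence": (0.89, 0.22, 0.77, 0.15),
    "rom_hip": (32.97, 11.89, 37.38, 5.23),
    "rom_knee": (52.28, 9.39, 60.09, 10.62),
    "rom_ankle": (24.19, 7.26, 32.00, 12.05),
    "trunk_lateral_bending": (3.31, 2.05, 4.05, 1.66),
    "trunk_flexion_extension": (2.84, 1.10, 5.99, 2.45),
    "trunk_rotation": (8.64, 5.05, 14.36, 11.12),
    "pelvis_obliquity": (4.82, 3.37, 5.77, 2.06),
    "pelvis_rotation": (11.20, 8.55, 16.48, 13.26),
    "pelvis_tilt": (67.78, 21.98, 84.25, 24.43),
}

#: Group sizes of the study cohort (67 controls; 20/17/27/12 per H-Y stage).
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "HS": 67,
    "HY1": 20,
    "HY2": 17,
    "HY3": 27,
    "HY4": 12,
}

#: Features given a stage-graded monotone decline (speed and all RoMs).
STAGE_RAMP_FEATURES: tuple[str, ...] = ("gait_speed",) + ROM_FEATURES


@dataclass
class GroupSpec:
    """Sampling parameters of one cohort group."""

    label: str
    n: int
    mean: np.ndarray
    sd: np.ndarray
    correlation: np.ndarray

    def validate(self, n_features: int) -> None:
        if self.label not in GROUP_LABELS:
            raise ValueError(f"invalid group label {self.label!r}")
        if self.n < 1:
            raise ValueError(f"group {self.label}: n must be >= 1")
        mean = np.asarray(self.mean, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        corr = np.asarray(self.correlation, dtype=float)
        if mean.shape != (n_features,) or sd.shape != (n_features,):
            raise ValueError(f"group {self.label}: mean/sd must have length {n_features}")
        if (sd < 0).any():
            raise ValueError(f"group {self.label}: sd must be >= 0")
        if corr.shape != (n_features, n_features):
            raise ValueError(f"group {self.label}: correlation must be {n_features}x{n_features}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ValueError(f"group {self.label}: correlation not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ValueError(f"group {self.label}: correlation diagonal must be 1")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError(f"group {self.label}: correlation not positive semi-definite")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort: one :class:`GroupSpec` per group
    over the canonical 18-feature space, plus a sampling seed."""

    groups: list[GroupSpec]
    feature_names: tuple[str, ...] = CANONICAL_FEATURES
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if not self.groups:
            raise ValueError("cohort spec has no groups")
        for g in self.groups:
            g.validate(len(self.feature_names))
        return self

    def group(self, label: str) -> GroupSpec:
        for g in self.groups:
            if g.label == label:
                return g
        raise KeyError(label)

    def to_yaml(self, path) -> None:
        doc = {
            "seed": int(self.seed),
            "feature_names": list(self.feature_names),
            "groups": [
                {
                    "label": g.label,
                    "n": int(g.n),
                    "mean": np.asarray(g.mean, dtype=float).tolist(),
                    "sd": np.asarray(g.sd, dtype=float).tolist(),
                    "correlation": np.asarray(g.correlation, dtype=float).tolist(),
                }
                for g in self.groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        groups = [
            GroupSpec(
                label=g["label"],
                n=g["n"],
                mean=np.asarray(g["mean"], dtype=float),
                sd=np.asarray(g["sd"], dtype=float),
                correlation=np.asarray(g["correlation"], dtype=float),
            )
            for g in doc["groups"]
        ]
        return cls(
            groups=groups,
            feature_names=tuple(doc["feature_names"]),
            seed=doc.get("seed", 0),
        ).validate()


def _default_correlation(rho: float = 0.3) -> np.ndarray:
    """Exchangeable correlation rho among the nine RoMs, 0 elsewhere."""
    p = len(CANONICAL_FEATURES)
    corr = np.eye(p)
    rom_idx = [CANONICAL_FEATURES.index(f) for f in ROM_FEATURES]
    for i in rom_idx:
        for j in rom_idx:
            if i != j:
                corr[i, j] = rho
    return corr


def default_cohort_spec(
    group_sizes: dict[str, int] | None = None,
    rho: float = 0.3,
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec with published population parameters and a stage ramp.

    The healthy group uses the HS means/SDs; stage means for speed and the
    RoMs decline linearly from HY1 (midpoint of the HS and pooled-patient
    means) to HY4 (pooled-patient mean minus one pooled SD); all other
    features sit at the pooled-patient mean for every stage.  Stage SDs equal
    the pooled-patient SDs.
    """
    sizes = dict(DEFAULT_GROUP_SIZES)
    if group_sizes:
        sizes.update(group_sizes)
    corr = _default_correlation(rho)

    pd_mean = np.array([POPULATION[f][0] for f in CANONICAL_FEATURES])
    pd_sd = np.array([POPULATION[f][1] for f in CANONICAL_FEATURES])
    hs_mean = np.array([POPULATION[f][2] for f in CANONICAL_FEATURES])
    hs_sd = np.array([POPULATION[f][3] for f in CANONICAL_FEATURES])

    ramp = np.array([f in STAGE_RAMP_FEATURES for f in CANONICAL_FEATURES])
    hy1 = np.where(ramp, 0.5 * (hs_mean + pd_mean), pd_mean)
    hy4 = np.where(ramp, pd_mean - pd_sd, pd_mean)

    groups = [GroupSpec("HS", sizes["HS"], hs_mean, hs_sd, corr)]
    for k, label in enumerate(("HY1", "HY2", "HY3", "HY4")):
        mean = hy1 + (k / 3.0) * (hy4 - hy1)
        groups.append(GroupSpec(label, sizes[label], mean, pd_sd.copy(), corr))
    return CohortSpec(groups=groups, seed=seed).validate()


def generate_feature_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a feature table from a cohort spec.

    Each group is sampled from N(mean, diag(sd) . correlation . diag(sd));
    gait-cycle phase features are clipped to [0, 100].  Reproducible
    bit-for-bit under a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    counter = 0
    for g in spec.groups:
        sd = np.asarray(g.sd, dtype=float)
        cov = np.outer(sd, sd) * np.asarray(g.correlation, dtype=float)
        X = rng.multivariate_normal(
            np.asarray(g.mean, dtype=float), cov, size=g.n, method="eigh"
        )
        df = pd.DataFrame(X, columns=list(spec.feature_names))
        for f in PHASE_FEATURES:
            if f in df.columns:
                df[f] = df[f].clip(0.0, 100.0)
        df.insert(0, "label", g.label)
        df.insert(0, "subject", [f"{g.label}_{counter + i:03d}" for i in range(g.n)])
        counter += g.n
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Marker-level walking trials
# ---------------------------------------------------------------------------


@dataclass
class FourierWaveform:
    """Periodic waveform a0 + sum_k (a_k cos(2 pi k phi) + b_k sin(2 pi k phi)),
    with phi the stride phase in [0, 1)."""

    mean: float = 0.0
    cos: tuple[float, ...] = ()
    sin: tuple[float, ...] = ()

    def __call__(self, phase: np.ndarray) -> np.ndarray:
        phase = np.asarray(phase, dtype=float)
        out = np.full(phase.shape, self.mean)
        for k, a in enumerate(self.cos, start=1):
            out = out + a * np.cos(2 * np.pi * k * phase)
        for k, b in enumerate(self.sin, start=1):
            out = out + b * np.sin(2 * np.pi * k * phase)
        return out

    @property
    def is_constant(self) -> bool:
        return not any(self.cos) and not any(self.sin)


def _default_waveforms() -> dict[str, FourierWaveform]:
    """Joint waveforms of the default walker (degrees).

    The limb-angle waveform's second harmonic skews the crest-to-trough
    spacing so stance occupies ~60% of the cycle; amplitudes are in the range
    of comfortable adult walking.
    """
    return {
        # Sagittal angle of the trochanter->malleolus vector from vertical.
        "limb_angle": FourierWaveform(2.0, (20.0, 0.0), (0.0, -4.0)),
        # Knee flexion: small stance bump, large swing peak.
        "knee_flexion": FourierWaveform(27.0, (-12.0, -13.0), (8.0, 3.0)),
        # Ankle dorsi(+)/plantar(-)flexion.
        "ankle_dorsiflexion": FourierWaveform(2.0, (-5.0, -6.0), (6.0, 0.0)),
        "pelvis_tilt": FourierWaveform(10.0, (0.0, 2.0), ()),
        "pelvis_obliquity": FourierWaveform(0.0, (0.0,), (2.5,)),
        "pelvis_rotation": FourierWaveform(0.0, (5.0,), ()),
        "trunk_flexion_extension": FourierWaveform(5.0, (0.0, 1.5), ()),
        "trunk_lateral_bending": FourierWaveform(0.0, (0.0,), (-2.0,)),
        "trunk_rotation": FourierWaveform(0.0, (-5.0,), ()),
    }


@dataclass
class GaitProfile:
    """Parameters of one synthetic walking trial.

    cadence is in strides/s (steps/s is twice that); speed in m/s; segment
    lengths in metres; marker noise is isotropic Gaussian, sd in metres
    (default 1 mm, a typical optoelectronic noise floor).
    """

    cadence: float = 0.9
    speed: float = 1.1
    n_strides: int = 6
    sampling_rate: float = 340.0
    noise_sd: float = 0.001
    thigh: float = 0.42
    shank: float = 0.43
    foot: float = 0.20
    hip_offset: float = 0.09  # mediolateral hip-to-midline distance
    pelvis_depth: float = 0.24
    pelvis_width: float = 0.25
    trunk_height: float = 0.48
    shoulder_width: float = 0.35
    waveforms: dict[str, FourierWaveform] = field(default_factory=_default_waveforms)

    def validate(self) -> "GaitProfile":
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.n_strides < 2:
            raise ValueError("need at least 2 strides")
        for name in ("thigh", "shank", "foot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name!r} must be > 0")
        if self.cadence <= 0:
            raise ValueError("cadence must be > 0")
        return self


def default_gait_profile(**overrides) -> GaitProfile:
    return replace(GaitProfile(), **overrides).validate()


@dataclass
class WalkGroundTruth:
    """Exact events and stride parameters implied by the prescribed waveforms."""

    heel_strikes: dict[str, np.ndarray]  # side -> frame indices
    toe_offs: dict[str, np.ndarray]
    speed: float
    cadence_steps: float  # steps/s
    stride_time: float  # s
    stance_pct: float
    swing_pct: float
    roms: dict[str, float]  # angle name -> degrees


class WalkGenerationError(ValueError):
    pass


def _limb_phase_extrema(wave: FourierWaveform, n_grid: int = 20001):
    """Phase of the (unique) max and min of one period; error if the waveform
    has more than one extremum of each type per cycle."""
    phi = np.linspace(0.0, 1.0, n_grid, endpoint=False)
    v = wave(phi)
    d = np.diff(np.concatenate([v, v[:1]]))
    sign = np.sign(d)
    sign[sign == 0] = 1
    flips = np.nonzero(sign != np.roll(sign, 1))[0]
    if len(flips) != 2:
        raise WalkGenerationError(
            "limb-angle waveform must have exactly one maximum and one "
            f"minimum per cycle (found {len(flips)} extrema)"
        )
    return phi[np.argmax(v)], phi[np.argmin(v)]


def _euler_matrix(rotation, obliquity, tilt) -> np.ndarray:
    """Orientation from transverse/frontal/sagittal plane angles (degrees),
    composed intrinsically as Rz(rotation) Rx(obliquity) Ry(tilt)."""
    ang = np.stack([rotation, obliquity, tilt], axis=-1)
    return Rotation.from_euler("ZXY", ang, degrees=True).as_matrix()


def generate_marker_walk(
    profile: GaitProfile, seed: int | None = 0
) -> tuple[MarkerTrajectorySet, WalkGroundTruth]:
    """Simulate one walking trial and return markers plus ground truth.

    Lab frame: x = progression, y = mediolateral (left positive),
    z = vertical.  The legs move in the sagittal plane, driven by the
    prescribed limb-angle and knee/ankle waveforms (the thigh angle is solved
    so that the trochanter->malleolus angle equals the limb-angle waveform
    exactly); pelvis and trunk marker clusters carry the prescribed
    rotational waveforms.  The right leg is half a stride out of phase.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    wf = profile.waveforms
    fs = profile.sampling_rate
    duration = profile.n_strides / profile.cadence
    F = int(round(duration * fs)) + 1
    t = np.arange(F) / fs

    leg_len = profile.thigh + profile.shank
    hip_z = leg_len + 0.08  # ankle-joint height above floor
    pelvis_origin = np.stack(
        [profile.speed * t, np.zeros(F), np.full(F, hip_z)], axis=1
    )

    # --- pelvis / trunk clusters -------------------------------------------
    phase_l = profile.cadence * t
    R_pel = _euler_matrix(
        wf["pelvis_rotation"](phase_l),
        wf["pelvis_obliquity"](phase_l),
        wf["pelvis_tilt"](phase_l),
    )
    R_trunk_rel = _euler_matrix(
        wf["trunk_rotation"](phase_l),
        wf["trunk_lateral_bending"](phase_l),
        wf["trunk_flexion_extension"](phase_l),
    )
    R_trunk = R_pel @ R_trunk_rel

    def place(R, local, origin):
        return origin + R @ np.asarray(local, dtype=float)

    hw, hd = profile.pelvis_width / 2, profile.pelvis_depth / 2
    markers: dict[str, np.ndarray] = {
        "l_asis": place(R_pel, [hd, hw, 0.05], pelvis_origin),
        "r_asis": place(R_pel, [hd, -hw, 0.05], pelvis_origin),
        "sacrum": place(R_pel, [-hd, 0.0, 0.05], pelvis_origin),
    }
    sw = profile.shoulder_width / 2
    markers["c7"] = place(R_trunk, [0.0, 0.0, profile.trunk_height], pelvis_origin)
    markers["l_acromion"] = place(R_trunk, [0.0, sw, profile.trunk_height - 0.08], pelvis_origin)
    markers["r_acromion"] = place(R_trunk, [0.0, -sw, profile.trunk_height - 0.08], pelvis_origin)

    # --- legs ---------------------------------------------------------------
    # The hip joints translate with the pelvis but, for planarity, do not
    # rotate with it; the limb angle seen from the markers then equals the
    # prescribed waveform exactly.
    limb_wave, knee_wave, ankle_wave = (
        wf["limb_angle"],
        wf["knee_flexion"],
        wf["ankle_dorsiflexion"],
    )

    hip_roms = []
    for side, y_sign, offset in (("l", 1.0, 0.0), ("r", -1.0, 0.5)):
        phase = profile.cadence * t + offset
        theta = np.deg2rad(limb_wave(phase))
        phi_k = np.deg2rad(knee_wave(phase))
        psi = np.deg2rad(ankle_wave(phase))
        # thigh angle alpha such that trochanter->malleolus angle == theta
        beta = np.arctan2(
            profile.shank * np.sin(phi_k),
            profile.thigh + profile.shank * np.cos(phi_k),
        )
        alpha = theta + beta
        hip_roms.append(np.rad2deg(alpha.max() - alpha.min()))

        def sagit(angle):
            return np.stack(
                [np.sin(angle), np.zeros_like(angle), -np.cos(angle)], axis=1
            )

        hip = pelvis_origin + np.array([0.0, y_sign * profile.hip_offset, 0.0])
        knee = hip + profile.thigh * sagit(alpha)
        a_shank = alpha - phi_k
        ankle = knee + profile.shank * sagit(a_shank)
        gamma = a_shank + np.pi / 2 - psi
        meta = ankle + profile.foot * sagit(gamma)
        markers[f"{side}_trochanter"] = hip
        markers[f"{side}_knee"] = knee
        markers[f"{side}_fibula_head"] = knee + 0.08 * sagit(a_shank)
        markers[f"{side}_malleolus"] = ankle
        markers[f"{side}_metatarsal"] = meta

    if profile.noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, profile.noise_sd, size=markers[name].shape
            )

    # --- ground truth -------------------------------------------------------
    heel_strikes: dict[str, np.ndarray] = {}
    toe_offs: dict[str, np.ndarray] = {}
    if limb_wave.is_constant:
        heel_strikes = {"l": np.array([], int), "r": np.array([], int)}
        toe_offs = {"l": np.array([], int), "r": np.array([], int)}
        stance_pct = math.nan
    else:
        p_max, p_min = _limb_phase_extrema(limb_wave)
        stance_pct = ((p_min - p_max) % 1.0) * 100.0
        for side, offset in (("l", 0.0), ("r", 0.5)):
            for name, p_ext in (("hs", p_max), ("to", p_min)):
                # times where frac(c t + offset) == p_ext
                k = np.arange(-1, profile.n_strides + 2)
                times = (k + ((p_ext - offset) % 1.0)) / profile.cadence
                times = times[(times >= 0) & (times <= duration)]
                frames = np.unique(np.round(times * fs).astype(int))
                frames = frames[frames < F]
                if name == "hs":
                    heel_strikes[side] = frames
                else:
                    toe_offs[side] = frames

    grid = np.linspace(0.0, 1.0, 4001, endpoint=False)

    def wrom(w):
        v = w(grid)
        return float(v.max() - v.min())

    roms = {
        "limb_angle": wrom(limb_wave),
        "hip": float(np.mean(hip_roms)),
        "knee": wrom(knee_wave),
        "ankle": wrom(ankle_wave),
        "pelvis_tilt": wrom(wf["pelvis_tilt"]),
        "pelvis_obliquity": wrom(wf["pelvis_obliquity"]),
        "pelvis_rotation": wrom(wf["pelvis_rotation"]),
        "trunk_flexion_extension": wrom(wf["trunk_flexion_extension"]),
        "trunk_lateral_bending": wrom(wf["trunk_lateral_bending"]),
        "trunk_rotation": wrom(wf["trunk_rotation"]),
    }

    truth = WalkGroundTruth(
        heel_strikes=heel_strikes,
        toe_offs=toe_offs,
        speed=profile.speed,
        cadence_steps=2.0 * profile.cadence,
        stride_time=1.0 / profile.cadence,
        stance_pct=stance_pct,
        swing_pct=100.0 - stance_pct,
        roms=roms,
    )
    return MarkerTrajectorySet(rate=fs, markers=markers), truth
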