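"""Gait feature tables, speed matching, and PCA-based feature pooling.

The feature universe is the 18 per-subject gait variables used throughout the
pipeline: nine spatio-temporal (time-distance) parameters and nine ranges of
motion (RoMs).  Walking speed is in m/s, cadence in steps/s, phase durations
in % of the gait cycle, step/stride geometry normalized to limb length
(dimensionless), and RoMs in degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

#: Canonical ordering of the 18 gait features.
CANONICAL_FEATURES: tuple[str, ...] = (
    "gait_speed",
    "stance_duration",
    "swing_duration",
    "double_support_1",
    "double_support_2",
    "step_length",
    "step_width",
    "stride_length",
    "cadence",
    "rom_hip",
    "rom_knee",
    "rom_ankle",
    "trunk_lateral_bending",
    "trunk_flexion_extension",
    "trunk_rotation",
    "pelvis_obliquity",
    "pelvis_rotation",
    "pelvis_tilt",
)

#: Human-readable labels for reports.
FEATURE_LABELS: dict[str, str] = {
    "gait_speed": "Gait speed (m/s)",
    "stance_duration": "Stance duration (% gait cycle)",
    "swing_duration": "Swing duration (% gait cycle)",
    "double_support_1": "1st double support (% gait cycle)",
    "double_support_2": "2nd double support (% gait cycle)",
    "step_length": "Step length (/limb length)",
    "step_width": "Step width (/limb length)",
    "stride_length": "Stride length (/limb length)",
    "cadence": "Cadence (step/s)",
    "rom_hip": "RoM Hip",
    "rom_knee": "RoM Knee",
    "rom_ankle": "RoM Ankle",
    "trunk_lateral_bending": "Trunk lateral bending",
    "trunk_flexion_extension": "Trunk flexion-extension",
    "trunk_rotation": "Trunk rotation",
    "pelvis_obliquity": "Pelvis obliquity",
    "pelvis_rotation": "Pelvis rotation",
    "pelvis_tilt": "Pelvis tilt",
}

#: Features bounded to [0, 100] by construction (percent of gait cycle).
PHASE_FEATURES: tuple[str, ...] = (
    "stance_duration",
    "swing_duration",
    "double_support_1",
    "double_support_2",
)

#: Valid group labels: healthy subjects and Hoehn-Yahr stages 1-4.
GROUP_LABELS: tuple[str, ...] = ("HS", "HY1", "HY2", "HY3", "HY4")

#: The nine RoM features (used for the default correlation structure).
ROM_FEATURES: tuple[str, ...] = CANONICAL_FEATURES[9:]


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a feature table: a ``label`` column with valid group labels,
    canonical feature columns, and no missing values."""
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    bad = set(table["label"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"invalid group labels: {sorted(bad)}")
    feats = [c for c in table.columns if c not in ("label", "subject")]
    unknown = set(feats) - set(CANONICAL_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature columns: {sorted(unknown)}")
    if table[feats].isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table, in canonical order."""
    return [c for c in CANONICAL_FEATURES if c in table.columns]


def read_feature_csv(path) -> pd.DataFrame:
    """Read a ``subject,label,<feature...>`` CSV and validate it."""
    return validate_feature_table(pd.read_csv(path))


def write_feature_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def speed_match(
    hc_trials: pd.DataFrame | np.ndarray,
    pd_speeds: np.ndarray,
) -> pd.DataFrame:
    """Retain healthy-control trials whose speed falls in the closed interval
    ``[mean(pd) - sd(pd), mean(pd) + sd(pd)]`` of the patient speeds.

    Parameters
    ----------
    hc_trials
        Either an array of per-trial speeds or a DataFrame with columns
        ``subject`` and ``speed`` (one row per trial).
    pd_speeds
        Per-subject walking speeds of the patient group (sample SD, ddof=1).

    Returns
    -------
    DataFrame of retained trials with a ``retained`` boolean column dropped;
    subjects whose trials are all rejected are excluded with a warning.
    """
    pd_speeds = np.asarray(pd_speeds, dtype=float)
    if pd_speeds.size == 0:
        raise ValueError("patient speed set is empty")
    if isinstance(hc_trials, pd.DataFrame):
        trials = hc_trials.copy()
        if "speed" not in trials.columns:
            raise ValueError("hc_trials DataFrame needs a 'speed' column")
    else:
        arr = np.asarray(hc_trials, dtype=float)
        if arr.size == 0:
            raise ValueError("healthy-control trial set is empty")
        trials = pd.DataFrame({"subject": 0, "speed": arr})
    mean = pd_speeds.mean()
    sd = pd_speeds.std(ddof=1) if pd_speeds.size > 1 else 0.0
    lo, hi = mean - sd, mean + sd
    keep = (trials["speed"] >= lo) & (trials["speed"] <= hi)
    if "subject" in trials.columns:
        for subj, grp in trials.groupby("subject"):
            if not keep[grp.index].any():
                warnings.warn(
                    f"subject {subj!r}: all trials outside speed window "
                    f"[{lo:.3f}, {hi:.3f}]; subject excluded",
                    stacklevel=2,
                )
    return trials[keep].reset_index(drop=True)


@dataclass
class PCASelection:
    """Result of PCA-thresholded feature pooling."""

    features: list[str]
    n_components: int
    explained_variance_ratio: np.ndarray = field(repr=False)
    loadings: np.ndarray = field(repr=False)  # (n_components, n_features)
    threshold: float = 0.98


def pca_select(
    table: pd.DataFrame,
    threshold: float = 0.98,
    features: list[str] | None = None,
) -> PCASelection:
    """Select a feature pool by PCA on z-scored features.

    Components are retained until the cumulative explained variance reaches
    ``threshold``; for each retained component (in variance order) the
    original feature with the largest absolute loading is picked, skipping
    features already selected.

    Raises
    ------
    ValueError
        If fewer than 2 rows, threshold outside (0, 1], or a feature column
        is constant (z-score undefined).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    feats = features if features is not None else feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA selection needs at least 2 subjects")
    sd = X.std(axis=0, ddof=1)
    const = [f for f, s in zip(feats, sd) if s == 0]
    if const:
        raise ValueError(f"constant feature column(s): {const}")
    Z = (X - X.mean(axis=0)) / sd

    pca = PCA()
    pca.fit(Z)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), threshold - 1e-12) + 1)
    k = min(k, len(evr))

    selected: list[str] = []
    for comp in pca.components_[:k]:
        for idx in np.argsort(-np.abs(comp)):
            if feats[idx] not in selected:
                selected.append(feats[idx])
                break
    return PCASelection(
        features=selected,
        n_components=k,
        explained_variance_ratio=evr,
        loadings=pca.components_[:k],
        threshold=threshold,
    )
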