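"""Repeated-training protocol: splits, confusion matrices, performance P,
per-class sensitivity/specificity, and the L x N two-way ANOVA.

Each of the six network topologies is trained ``reps`` times on fresh
stratified 80/10/10 train/validation/test splits; per repetition a
row-normalized confusion matrix is computed on the test split, the mean
matrix is the average of the per-repetition percentage matrices, and the
performance statistic P is the mean of the diagonal of that mean matrix
(100% = no misclassification).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .ann import (
    Network,
    NetworkTopology,
    TrainConfig,
    build_topologies,
    init_network,
    one_hot,
    predict_class,
    train_lm,
)

__all__ = [
    "ProtocolConfig",
    "ConfusionSummary",
    "ProtocolResult",
    "split_data",
    "confusion_counts",
    "confusion_matrix_pct",
    "sens_spec",
    "performance",
    "run_protocol",
    "anova_topology_effects",
]


def split_data(
    n: int,
    labels: np.ndarray,
    val_frac: float = 0.1,
    test_frac: float = 0.1,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, class-stratified train/validation/test indices.

    Within each class the indices are shuffled and ``round(frac * n_c)``
    (at least 1 when the class has >= 3 members) go to each held-out split.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length mismatch")
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        rng.shuffle(idx)
        n_c = idx.size
        if n_c < 3:
            warnings.warn(
                f"class {cls!r} has only {n_c} member(s); "
                "stratified split is degenerate (all to training)",
                stacklevel=2,
            )
            train.extend(idx)
            continue
        n_val = max(1, round(val_frac * n_c))
        n_test = max(1, round(test_frac * n_c))
        if n_val + n_test >= n_c:
            raise ValueError(f"class {cls!r}: not enough members to split")
        val.extend(idx[:n_val])
        test.extend(idx[n_val : n_val + n_test])
        train.extend(idx[n_val + n_test :])
    return (
        np.sort(np.asarray(train, int)),
        np.sort(np.asarray(val, int)),
        np.sort(np.asarray(test, int)),
    )


def confusion_counts(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """Raw count matrix, entry (i, j) = # of true-i samples predicted j."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for v in (y_true, y_pred):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError("labels outside [0, n_classes)")
    M = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(M, (y_true, y_pred), 1)
    return M


def confusion_matrix_pct(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> np.ndarray:
    """Row-normalized percentage confusion matrix; a row with no true
    samples is left as zeros (flagged by summing to 0, not 100)."""
    M = confusion_counts(y_true, y_pred, n_classes).astype(float)
    totals = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * M / totals, 0.0)
    return pct


def performance(mean_matrix_pct: np.ndarray) -> float:
    """Performance P: mean of the diagonal of the row-normalized mean
    confusion matrix, in %."""
    return float(np.mean(np.diag(mean_matrix_pct)))


def sens_spec(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest sensitivity and specificity per class, in %.

    Zero denominators yield NaN (flagged undefined).
    """
    counts = np.asarray(counts, dtype=float)
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = counts.sum() - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.where(tp + fn > 0, 100.0 * tp / (tp + fn), np.nan)
        sp = np.where(tn + fp > 0, 100.0 * tn / (tn + fp), np.nan)
    return se, sp


@dataclass
class ConfusionSummary:
    """Mean row-normalized confusion matrix with P and per-class Se/Sp."""

    n_classes: int
    mean_matrix: np.ndarray  # row-normalized, %
    per_rep_matrices: list[np.ndarray] = field(repr=False)
    performance: float = 0.0
    sensitivity: np.ndarray | None = None  # per class, mean over reps, %
    specificity: np.ndarray | None = None


@dataclass
class ProtocolConfig:
    """Configuration of the repeated-training protocol."""

    reps: int = 10
    val_frac: float = 0.1
    test_frac: float = 0.1
    seed: int = 0
    max_iter: int = 1000
    mse_floor: float = 1e-6
    max_val_fails: int = 6
    topologies: list[NetworkTopology] | None = None  # default: the 6-grid


@dataclass
class ProtocolResult:
    """Per-(topology, repetition) records and per-topology aggregates."""

    records: pd.DataFrame  # L, N, rep, P, Se_mean, Sp_mean, stop_reason
    summaries: dict[tuple[int, int], ConfusionSummary]
    classes: list
    config: ProtocolConfig

    @property
    def per_rep_P(self) -> np.ndarray:
        """All per-repetition P values (topologies x reps flattened)."""
        return self.records["P"].to_numpy()

    @property
    def mean_P(self) -> float:
        return float(self.records["P"].mean())

    def topology_table(self) -> pd.DataFrame:
        rows = []
        for (L, N), summ in self.summaries.items():
            sub = self.records[(self.records["L"] == L) & (self.records["N"] == N)]
            rows.append(
                {
                    "L": L,
                    "N": N,
                    "P_mean_matrix": summ.performance,
                    "P_mean": sub["P"].mean(),
                    "P_sd": sub["P"].std(ddof=1),
                    "Se_mean": sub["Se_mean"].mean(),
                    "Se_sd": sub["Se_mean"].std(ddof=1),
                    "Sp_mean": sub["Sp_mean"].mean(),
                    "Sp_sd": sub["Sp_mean"].std(ddof=1),
                }
            )
        return pd.DataFrame(rows)


def _zscore_train(X_train, *others):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((X - mu) / sd for X in (X_train, *others))


def run_protocol(
    table: pd.DataFrame,
    features: list[str],
    label_col: str = "label",
    config: ProtocolConfig | None = None,
) -> ProtocolResult:
    """Run the repeated multi-topology training protocol.

    For each topology and repetition: a fresh stratified split, inputs
    z-scored with training-split statistics, Levenberg-Marquardt training
    with early stopping, and a test-split confusion matrix.  A repetition
    that fails numerically is recorded (NaN row) rather than fatal.
    """
    cfg = config or ProtocolConfig()
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    X_all = table[list(features)].to_numpy(dtype=float)
    classes = sorted(table[label_col].unique())
    y_all = np.asarray([classes.index(v) for v in table[label_col]])
    n_classes = len(classes)
    topos = cfg.topologies or build_topologies(len(features), n_classes)

    ss = np.random.SeedSequence(cfg.seed)
    records = []
    summaries: dict[tuple[int, int], ConfusionSummary] = {}
    for topo in topos:
        rep_matrices, rep_counts = [], []
        for rep in range(cfg.reps):
            child = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(topo.n_hidden_layers, topo.n1, rep)
            )
            split_seed, init_seed = child.spawn(2)
            row = {"L": topo.n_hidden_layers, "N": topo.n1, "rep": rep}
            try:
                tr, va, te = split_data(
                    len(y_all), y_all, cfg.val_frac, cfg.test_frac, split_seed
                )
                Xtr, Xva, Xte = _zscore_train(X_all[tr], X_all[va], X_all[te])
                net = init_network(topo, np.random.default_rng(init_seed))
                trained = train_lm(
                    net,
                    Xtr,
                    one_hot(y_all[tr], n_classes),
                    Xva,
                    one_hot(y_all[va], n_classes),
                    TrainConfig(
                        max_iter=cfg.max_iter,
                        mse_floor=cfg.mse_floor,
                        max_val_fails=cfg.max_val_fails,
                    ),
                )
                y_pred = predict_class(trained.network, Xte)
                counts = confusion_counts(y_all[te], y_pred, n_classes)
                pct = confusion_matrix_pct(y_all[te], y_pred, n_classes)
                se, sp = sens_spec(counts)
                rep_matrices.append(pct)
                rep_counts.append(counts)
                row.update(
                    P=performance(pct),
                    Se_mean=float(np.nanmean(se)),
                    Sp_mean=float(np.nanmean(sp)),
                    stop_reason=trained.stop_reason,
                    n_iterations=trained.n_iterations,
                )
            except (np.linalg.LinAlgError, FloatingPointError) as exc:  # pragma: no cover
                warnings.warn(f"repetition failed: {exc}", stacklevel=2)
                row.update(P=np.nan, Se_mean=np.nan, Sp_mean=np.nan, stop_reason="error")
            records.append(row)
        if rep_matrices:
            mean_matrix = np.mean(rep_matrices, axis=0)
            total_counts = np.sum(rep_counts, axis=0)
            se, sp = sens_spec(total_counts)
            summaries[(topo.n_hidden_layers, topo.n1)] = ConfusionSummary(
                n_classes=n_classes,
                mean_matrix=mean_matrix,
                per_rep_matrices=rep_matrices,
                performance=performance(mean_matrix),
                sensitivity=se,
                specificity=sp,
            )
    return ProtocolResult(
        records=pd.DataFrame(records),
        summaries=summaries,
        classes=classes,
        config=cfg,
    )


def anova_topology_effects(
    result: ProtocolResult, responses: tuple[str, ...] = ("P", "Se_mean", "Sp_mean")
) -> dict[str, dict[str, tuple[float, float]]]:
    """Two-way fixed-effects ANOVA with hidden-layer count (L) and
    first-layer width (N) as factors, run separately per response.

    Returns ``{response: {"L": (F, p), "N": (F, p), "L:N": (F, p)}}``.  The
    interaction is dropped when any cell has fewer than 2 repetitions; zero
    within-cell variance is flagged with NaN statistics.
    """
    df = result.records.dropna(subset=["P"]).copy()
    cell_sizes = df.groupby(["L", "N"]).size()
    include_interaction = bool((cell_sizes >= 2).all())
    if not include_interaction:
        warnings.warn(
            "some (L, N) cells have < 2 repetitions; interaction term dropped",
            stacklevel=2,
        )
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for resp in responses:
        if df.groupby(["L", "N"])[resp].var(ddof=1).fillna(0).eq(0).all():
            out[resp] = {
                "L": (np.nan, np.nan),
                "N": (np.nan, np.nan),
                "L:N": (np.nan, np.nan),
            }
            continue
        formula = (
            f"{resp} ~ C(L) + C(N)"
            + (" + C(L):C(N)" if include_interaction else "")
        )
        model = smf.ols(formula, data=df).fit()
        tab = sm.stats.anova_lm(model, typ=2)
        res: dict[str, tuple[float, float]] = {}
        for factor, key in (("C(L)", "L"), ("C(N)", "N"), ("C(L):C(N)", "L:N")):
            if factor in tab.index:
                res[key] = (float(tab.loc[factor, "F"]), float(tab.loc[factor, "PR(>F)"]))
        out[resp] = res
    return out


def bonferroni_posthoc(
    result: ProtocolResult, factor: str = "L", response: str = "P"
) -> pd.DataFrame:
    """Pairwise t-tests between factor levels with Bonferroni correction."""
    df = result.records.dropna(subset=[response])
    levels = sorted(df[factor].unique())
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    rows = []
    for a, b in pairs:
        xa = df.loc[df[factor] == a, response]
        xb = df.loc[df[factor] == b, response]
        t, p = stats.ttest_ind(xa, xb)
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "t": t,
                "p_raw": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
            }
        )
    return pd.DataFrame(rows)
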