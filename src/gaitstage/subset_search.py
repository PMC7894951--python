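"""Exhaustive minimal-feature-subset search with an equivalence stopping rule.

Starting from all two-feature combinations of the feature pool and growing
one size at a time, every combination is run through the repeated-training
protocol; the search stops at the first subset size containing at least one
subset whose performance is statistically indistinguishable from the full
pool's and whose mean P is within a non-inferiority margin of it.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import ProtocolConfig, ProtocolResult, run_protocol

__all__ = ["SubsetSearchReport", "search_min_subset", "SearchBudgetError"]


class SearchBudgetError(RuntimeError):
    """Raised when the combinatorial budget is exceeded; reduce the pool or
    raise the budget."""


def _combo_seed(master_seed: int, combo: tuple[str, ...]) -> int:
    """Stable per-combination seed: master seed + CRC32 of the feature names,
    so adding combinations does not shift others' randomness."""
    h = zlib.crc32(",".join(combo).encode())
    return int((master_seed + h) % (2**31))


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value; two identical degenerate samples
    (zero variance, equal means) count as indistinguishable (p = 1)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.var(a) < 1e-12 and np.var(b) < 1e-12:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


@dataclass
class SubsetSearchReport:
    """Outcome of the exhaustive search."""

    full_pool: tuple[str, ...]
    full_result: ProtocolResult
    records: pd.DataFrame  # size, features, mean_P, p_value, equivalent
    equivalent_subsets: list[tuple[str, ...]]  # at stopping size, best first
    stopping_size: int | None
    n_combinations_visited: int

    @property
    def minimal_subset(self) -> tuple[str, ...] | None:
        return self.equivalent_subsets[0] if self.equivalent_subsets else None


def search_min_subset(
    table: pd.DataFrame,
    pool: list[str],
    protocol_config: ProtocolConfig | None = None,
    alpha: float = 0.05,
    margin: float = 2.0,
    label_col: str = "label",
    max_size: int | None = None,
    budget: int = 5000,
) -> SubsetSearchReport:
    """Exhaustively search for the minimal equivalent feature subset.

    A subset is *equivalent* to the full pool when a two-sided Welch t-test
    between its per-repetition P values (all topologies x repetitions) and
    the full pool's is non-significant at ``alpha`` AND its mean P is no
    more than ``margin`` percentage points below the full pool's.  Setting
    ``alpha <= 0`` disables equivalence entirely (the search visits every
    size and returns the pool itself); a bare non-significant t-test without
    the margin would accept underpowered garbage, hence the two-part rule.

    Randomness policy: the full pool and every combination derive their
    protocol seed from the master seed plus a hash of the feature names.
    """
    cfg = protocol_config or ProtocolConfig()
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError("feature pool must have >= 2 features")
    max_size = max_size or len(pool)

    full_cfg = replace(cfg, seed=_combo_seed(cfg.seed, tuple(pool)))
    full_result = run_protocol(table, pool, label_col=label_col, config=full_cfg)
    full_P = full_result.per_rep_P
    full_mean = float(np.nanmean(full_P))

    records = []
    visited = 0
    stopping_size = None
    equivalents: list[tuple[str, tuple[str, ...], float]] = []
    for k in range(2, max_size + 1):
        n_k = sum(1 for _ in itertools.combinations(pool, k))
        if visited + n_k > budget:
            raise SearchBudgetError(
                f"size-{k} search needs {n_k} more combinations "
                f"(visited {visited}, budget {budget}); reduce the pool or "
                "raise the budget"
            )
        found_at_k = []
        for combo in itertools.combinations(pool, k):
            visited += 1
            sub_cfg = replace(cfg, seed=_combo_seed(cfg.seed, combo))
            res = run_protocol(table, list(combo), label_col=label_col, config=sub_cfg)
            sub_P = res.per_rep_P
            p_val = _welch_p(sub_P, full_P)
            sub_mean = float(np.nanmean(sub_P))
            equivalent = (
                alpha > 0
                and p_val >= alpha
                and sub_mean >= full_mean - margin
            )
            records.append(
                {
                    "size": k,
                    "features": ",".join(combo),
                    "mean_P": sub_mean,
                    "p_value": p_val,
                    "equivalent": equivalent,
                }
            )
            if equivalent:
                found_at_k.append((combo, sub_mean))
        if found_at_k:
            stopping_size = k
            found_at_k.sort(key=lambda t: -t[1])
            equivalents = found_at_k
            break

    if stopping_size is None:
        equivalent_subsets = [tuple(pool)]
    else:
        equivalent_subsets = [c for c, _ in equivalents]
    return SubsetSearchReport(
        full_pool=tuple(pool),
        full_result=full_result,
        records=pd.DataFrame(records),
        equivalent_subsets=equivalent_subsets,
        stopping_size=stopping_size,
        n_combinations_visited=visited,
    )
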