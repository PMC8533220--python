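"""Per-feature ROC screening between prognostic groups with Wilcoxon confirmation.

Each aligned m/z feature is scored by the area under the ROC curve (AUC)
between feature-positive and feature-negative pixels, in the Mann-Whitney
form::

    AUC = [#(x+ > x-) + 0.5 * #(x+ = x-)] / (n+ * n-)

with the feature-positive group as the positive class, so AUC > 0.5 means the
peptide intensity is increased in positive tissue.  Features outside the AUC
dead zone (below ``auc_low`` = 0.4 or above ``auc_high`` = 0.6) are confirmed
by a two-sided Wilcoxon rank-sum test and kept when p < ``alpha`` = 0.001.

When the two groups differ in size by more than ~10%, at most
``max_spectra_per_group`` (default 1500) spectra per group are subsampled
without replacement, seeded, before screening.

No multiple-testing correction is applied by default (the raw p < 0.001 rule
is screened across a few hundred features); Benjamini-Hochberg is available
as an option.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .peakalign import Datacube

__all__ = [
    "ScreenConfig",
    "DiscriminativeFeature",
    "balance_spectra",
    "auc_per_feature",
    "wilcoxon_rank_sum",
    "select_discriminative",
    "screen_feature",
]


@dataclass
class ScreenConfig:
    """Thresholds and balancing rules for the ROC/Wilcoxon screen."""

    auc_low: float = 0.4
    auc_high: float = 0.6
    alpha: float = 0.001
    max_spectra_per_group: int = 1500
    balance_tolerance: float = 0.10  # "approximately the same" group size
    bh_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.auc_low < 0.5 < self.auc_high <= 1):
            raise ValueError("need 0 <= auc_low < 0.5 < auc_high <= 1")


@dataclass
class DiscriminativeFeature:
    """A selected m/z with its AUC, Wilcoxon p, direction and prognostic feature."""

    mz: float
    auc: float
    p_value: float
    direction: str  # "up" if auc > 0.5 else "down"
    feature: str | None = None

    def __post_init__(self) -> None:
        expected = "up" if self.auc > 0.5 else "down"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with AUC {self.auc}"
            )


def balance_spectra(
    group_a: np.ndarray, group_b: np.ndarray, cfg: ScreenConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample two groups of pixel rows to comparable, capped sizes.

    If the larger group exceeds the smaller by more than
    ``balance_tolerance`` (10%), ``min(max_spectra_per_group, group size)``
    rows are drawn per group without replacement, seeded; otherwise the groups
    pass through unchanged.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    larger, smaller = max(a.size, b.size), min(a.size, b.size)
    if larger <= smaller * (1 + cfg.balance_tolerance):
        return a, b
    rng = np.random.default_rng(cfg.seed)
    cap = cfg.max_spectra_per_group
    a_out = np.sort(rng.choice(a, size=min(cap, a.size), replace=False))
    b_out = np.sort(rng.choice(b, size=min(cap, b.size), replace=False))
    return a_out, b_out


def _auc_columns(X: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Mann-Whitney AUC per column of X; ``positive`` is a boolean row mask."""
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(X, axis=0)
    r_pos = ranks[positive].sum(axis=0)
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def auc_per_feature(cube: Datacube, labels: np.ndarray) -> list[tuple[float, float]]:
    """AUC of every aligned feature, positive class = feature-positive rows."""
    positive = np.asarray(labels, dtype=bool)
    if len(positive) != cube.n_pixels:
        raise ValueError("labels length must match pixel count")
    aucs = _auc_columns(cube.matrix, positive)
    return list(zip(cube.feature_mzs.tolist(), aucs.tolist()))


def _exact_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation two-sided rank-sum p, valid with ties.

    Enumerates all C(n, n_a) label splits of the pooled sample and counts
    those whose rank-sum deviates from its permutation mean by at least the
    observed deviation.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n = len(a), len(pooled)
    mu = n_a * (n + 1) / 2.0
    obs_dev = abs(float(ranks[:n_a].sum()) - mu)
    count = total = 0
    for comb in itertools.combinations(ranks.tolist(), n_a):
        total += 1
        if abs(sum(comb) - mu) >= obs_dev - 1e-9:
            count += 1
    return count / total


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact permutation null when the pooled size is <= 20 (valid with ties);
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.size + b.size <= 20:
        return _exact_two_sided(a, b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def select_discriminative(
    screen: list[tuple[float, float, float]],
    cfg: ScreenConfig,
    feature: str | None = None,
) -> list[DiscriminativeFeature]:
    """Apply the combined AUC + p filter to (mz, auc, p) screening records.

    Keeps entries with (auc < auc_low or auc > auc_high) and p < alpha;
    optionally Benjamini-Hochberg adjusts the p-values first.  The result is
    sorted by |auc - 0.5| descending (most discriminative first).
    """
    records = [(float(mz), float(auc), float(p)) for mz, auc, p in screen]
    if cfg.bh_correction and records:
        ps = np.array([p for _, _, p in records])
        order = np.argsort(ps)
        adj = np.empty_like(ps)
        m = len(ps)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, ps[i] * m / (rank_pos + 1))
            adj[i] = running
        records = [(mz, auc, adj[i]) for i, (mz, auc, _) in enumerate(records)]
    kept = [
        DiscriminativeFeature(
            mz=mz,
            auc=auc,
            p_value=p,
            direction="up" if auc > 0.5 else "down",
            feature=feature,
        )
        for mz, auc, p in records
        if (auc < cfg.auc_low or auc > cfg.auc_high) and p < cfg.alpha
    ]
    kept.sort(key=lambda d: (-abs(d.auc - 0.5), d.mz))
    return kept


def screen_feature(
    cube: Datacube,
    positive_mask: np.ndarray,
    labeled_mask: np.ndarray,
    cfg: ScreenConfig,
    feature: str | None = None,
) -> tuple[list[DiscriminativeFeature], pd.DataFrame]:
    """Full per-feature screen: balance, AUC, Wilcoxon on gate-passers, select.

    Returns the selected discriminative features and the complete screening
    table (one row per aligned m/z with auc, p where computed, and kept flag).
    The Wilcoxon test is run only on features passing the AUC gate, matching
    the screen's two-stage design; other features keep p = NaN.
    """
    positive = np.asarray(positive_mask, dtype=bool)
    labeled = np.asarray(labeled_mask, dtype=bool)
    rows_pos = np.flatnonzero(labeled & positive)
    rows_neg = np.flatnonzero(labeled & ~positive)
    if rows_pos.size == 0 or rows_neg.size == 0:
        raise ValueError(f"feature {feature!r}: one group has no labeled pixels")
    rows_pos, rows_neg = balance_spectra(rows_pos, rows_neg, cfg)
    rows = np.concatenate([rows_pos, rows_neg])
    X = cube.matrix[rows]
    is_pos = np.zeros(rows.size, dtype=bool)
    is_pos[: rows_pos.size] = True
    aucs = _auc_columns(X, is_pos)

    ps = np.full(cube.n_features, np.nan)
    gate = (aucs < cfg.auc_low) | (aucs > cfg.auc_high)
    for j in np.flatnonzero(gate):
        ps[j] = wilcoxon_rank_sum(X[is_pos, j], X[~is_pos, j])
    records = [
        (cube.feature_mzs[j], aucs[j], ps[j] if gate[j] else 1.0)
        for j in range(cube.n_features)
    ]
    selected = select_discriminative(records, cfg, feature=feature)
    kept_mzs = {d.mz for d in selected}
    table = pd.DataFrame(
        {
            "feature": feature,
            "mz": cube.feature_mzs,
            "auc": aucs,
            "p_value": ps,
            "direction": np.where(aucs > 0.5, "up", "down"),
            "kept": [mz in kept_mzs for mz in cube.feature_mzs],
        }
    )
    return selected, table
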