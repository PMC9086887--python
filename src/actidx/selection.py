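"""Stability selection with randomized L1-penalized logistic regression.

The selector repeatedly subsamples participants, fits an L1-penalized
logistic model whose penalty strength is jittered per subsample, and scores
each feature by its *selection frequency* — the fraction of subsamples in
which it received a nonzero coefficient. Features are ranked by frequency
(ties broken by mean absolute coefficient, then by column order) and the
top k (default 20) are retained. This subsample-and-count scheme yields a
far more stable feature set than a single sparse fit.

Standardization (z-score; constant columns mapped to 0) is computed once on
the full matrix before subsampling; the -1 missing-data sentinel
standardizes like any other value, consistent with a pipeline in which
imputation precedes selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .sensor_io import UsageError

POSITIVE_CLASS = "ADHD"


@dataclass(frozen=True)
class SelectionConfig:
    n_subsamples: int = 200
    subsample_fraction: float = 0.75
    base_c: float = 0.25  # inverse L1 penalty strength
    c_jitter: tuple[float, float] = (0.5, 2.0)  # multiplicative, log-uniform
    k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsamples < 1:
            raise UsageError("n_subsamples must be >= 1")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise UsageError("subsample_fraction must be in (0, 1]")
        if self.k < 1:
            raise UsageError("k must be >= 1")
        lo, hi = self.c_jitter
        if not (0 < lo <= hi):
            raise UsageError("c_jitter must satisfy 0 < lo <= hi")


@dataclass
class SelectionResult:
    """Per-feature selection frequencies and the resulting ranking."""

    frequencies: pd.Series  # index = feature names, original column order
    mean_abs_coef: pd.Series
    rank: list[str]  # all features, most stable first
    retained: list[str]  # first min(k, n_features) of rank

    def to_frame(self) -> pd.DataFrame:
        order = {name: i + 1 for i, name in enumerate(self.rank)}
        return pd.DataFrame(
            {
                "feature": list(self.frequencies.index),
                "frequency": self.frequencies.to_numpy(),
                "rank": [order[f] for f in self.frequencies.index],
                "retained": [f in set(self.retained) for f in self.frequencies.index],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _standardize(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    z = (values - mean) / std
    z[:, values.std(axis=0) < 1e-12] = 0.0
    return z


def stability_scores(
    matrix: pd.DataFrame, labels: pd.Series | np.ndarray, config: SelectionConfig
) -> SelectionResult:
    """Score every feature by L1-logistic selection frequency.

    ``matrix`` is participants x features; ``labels`` the group per
    participant. Subsamples are stratified by class (each class contributes
    ``round(fraction * n_class)``, at least 2) so every sparse fit sees both
    groups. Deterministic given ``config.seed``; rows are canonicalized by
    participant id so results do not depend on row order.
    """
    # canonical row order: sort by participant id
    order = np.argsort(np.asarray(matrix.index, dtype=object), kind="stable")
    matrix = matrix.iloc[order]
    y = (np.asarray(labels)[order] == POSITIVE_CLASS).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise UsageError("labels contain a single class")
    if min((y == c).sum() for c in classes) < 2:
        raise UsageError("need at least 2 participants per class")

    z = _standardize(matrix.to_numpy(dtype=float))
    n, p = z.shape
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    n_pos = max(2, int(round(config.subsample_fraction * idx_pos.size)))
    n_neg = max(2, int(round(config.subsample_fraction * idx_neg.size)))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subsamples)
    hits = np.zeros(p)
    coef_sum = np.zeros(p)
    log_lo, log_hi = np.log(config.c_jitter[0]), np.log(config.c_jitter[1])
    for b in range(config.n_subsamples):
        rng = np.random.default_rng(seeds[b])
        rows = np.concatenate(
            [
                rng.choice(idx_pos, size=min(n_pos, idx_pos.size), replace=False),
                rng.choice(idx_neg, size=min(n_neg, idx_neg.size), replace=False),
            ]
        )
        c_b = config.base_c * float(np.exp(rng.uniform(log_lo, log_hi)))
        model = LogisticRegression(
            l1_ratio=1.0, C=c_b, solver="liblinear", max_iter=1000,
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(z[rows], y[rows])
        coef = np.abs(model.coef_.ravel())
        hits += coef > 1e-8
        coef_sum += coef

    freq = hits / config.n_subsamples
    mean_abs = coef_sum / config.n_subsamples
    names = list(matrix.columns)
    # rank: frequency desc, mean |coef| desc, column index asc
    order_idx = sorted(range(p), key=lambda j: (-freq[j], -mean_abs[j], j))
    rank = [names[j] for j in order_idx]
    result = SelectionResult(
        frequencies=pd.Series(freq, index=names, name="frequency"),
        mean_abs_coef=pd.Series(mean_abs, index=names, name="mean_abs_coef"),
        rank=rank,
        retained=rank[: min(config.k, p)],
    )
    return result


def select_top_k(result: SelectionResult, k: int = 20) -> list[str]:
    """First min(k, n_features) names of the stability ranking."""
    if k < 1:
        raise UsageError("k must be >= 1")
    return result.rank[: min(k, len(result.rank))]
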