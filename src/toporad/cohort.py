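"""Cohort handling: event-balanced train/test splitting, z-score
normalization, and SMOTE augmentation for censored survival data.

The split stratifies jointly on the two event indicators (LRR, DM) and
redraws until a two-sided Mann-Whitney U test finds no significant
difference (p > 0.05) between the partitions' time distributions for both
endpoints.  Augmentation synthesizes patients by k-nearest-neighbor
interpolation within each event class, interpolating times with the same
mixing coefficient as the features, so event proportions are preserved
exactly and original patients are retained verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "AugmentationConfig",
    "stratified_split",
    "zscore_fit_apply",
    "smote_augment",
    "ZScoreNormalizer",
    "SurvivalSMOTE",
]


@dataclass(frozen=True)
class AugmentationConfig:
    """SMOTE multiplication factor and neighborhood size."""

    factor: int = 4
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def _mw_p(a: np.ndarray, b: np.ndarray) -> float:
    if len(np.unique(np.concatenate([a, b]))) == 1:
        return 1.0
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def _allocate(counts: np.ndarray, n_train: int, total: int) -> np.ndarray:
    """Largest-remainder allocation of per-stratum training counts summing
    exactly to n_train; among remainder placements the one with the
    smallest deviation from exact proportionality wins."""
    exact = counts * n_train / total
    base = np.floor(exact).astype(int)
    rem = n_train - base.sum()
    frac = exact - base
    order = np.argsort(-frac, kind="stable")
    alloc = base.copy()
    alloc[order[:rem]] += 1
    return alloc


def stratified_split(
    records: pd.DataFrame,
    n_train: int,
    n_test: int,
    seed: int = 0,
    *,
    event_cols: tuple[str, ...] = ("event_lrr", "event_dm"),
    time_cols: tuple[str, ...] = ("time_lrr", "time_dm"),
    alpha: float = 0.05,
    max_draws: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Event-balanced split with a Mann-Whitney time-distribution check.

    Patients are stratified jointly on the event indicators; candidate
    splits are redrawn (up to ``max_draws``) until both endpoints' observed
    time distributions do not differ significantly between partitions.
    Returns (train, test, n_draws_used).
    """
    if n_train + n_test != len(records):
        raise ValueError("n_train + n_test must equal the cohort size")
    if n_train < 1 or n_test < 1:
        raise ValueError("both partitions must be non-empty")
    present_events = [c for c in event_cols if c in records.columns]
    present_times = [c for c in time_cols if c in records.columns]
    if not present_events:
        raise ValueError(f"no event columns among {event_cols}")
    strata = records.groupby(list(present_events), sort=True).indices
    keys = sorted(strata.keys())
    counts = np.array([len(strata[k]) for k in keys])
    alloc = _allocate(counts, n_train, len(records))
    if np.any(alloc > counts):
        raise ValueError("stratum too small for the requested split")

    rng = np.random.default_rng(seed)
    for draw in range(1, max_draws + 1):
        train_idx: list[int] = []
        for k, a in zip(keys, alloc):
            members = np.asarray(strata[k])
            chosen = rng.choice(members, size=a, replace=False)
            train_idx.extend(chosen.tolist())
        train_mask = np.zeros(len(records), dtype=bool)
        train_mask[train_idx] = True
        train = records.iloc[np.sort(train_idx)]
        test = records.iloc[np.sort(np.flatnonzero(~train_mask))]
        ps = [
            _mw_p(train[c].to_numpy(float), test[c].to_numpy(float)) for c in present_times
        ]
        if all(p > alpha for p in ps):
            return train, test, draw
    raise RuntimeError(
        f"no balanced split found in {max_draws} draws (last p-values: {ps})"
    )


class ZScoreNormalizer(BaseEstimator, TransformerMixin):
    """Column-wise z-scoring with reference statistics.

    Fitted attributes: ``mean_``, ``scale_`` (population SD), and
    ``constant_columns_`` flagging zero-variance features, whose normalized
    values are defined as 0.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        self.constant_columns_ = list(X.columns[self.scale_ == 0])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [c for c in X.columns if c not in self.mean_.index]
        if missing:
            raise ValueError(f"columns not seen in reference: {missing[:5]}")
        mu = self.mean_[X.columns]
        sd = self.scale_[X.columns].replace(0.0, 1.0)
        out = (X - mu) / sd
        const = [c for c in self.constant_columns_ if c in X.columns]
        if const:
            out[const] = 0.0
        return out


def zscore_fit_apply(table: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Normalize ``table`` with mean/SD estimated on ``reference``."""
    return ZScoreNormalizer().fit(reference).transform(table)


class SurvivalSMOTE(BaseEstimator):
    """SMOTE adapted to censored survival data.

    Synthetic patients are drawn within each event class: pick an original
    patient x, one of its k nearest same-class neighbors x_nn, and
    u ~ Uniform(0, 1); the synthetic feature vector is x + u (x_nn - x),
    the synthetic time interpolates the parents' times with the same u, and
    the event flag is the shared class label.  Exactly (factor - 1) * n_c
    synthetics per class keep event proportions unchanged; originals are
    retained verbatim.
    """

    def __init__(self, factor: int = 4, k_neighbors: int = 5, random_state: int = 0):
        self.factor = factor
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(
        self, X: pd.DataFrame, times: np.ndarray, events: np.ndarray
    ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
        cfg = AugmentationConfig(self.factor, self.k_neighbors, self.random_state)
        X = pd.DataFrame(X)
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if not (len(X) == len(times) == len(events)):
            raise ValueError("X, times and events must be aligned")
        rng = np.random.default_rng(cfg.seed)
        new_rows, new_times, new_events, new_ids = [], [], [], []
        for cls in sorted(np.unique(events)):
            members = np.flatnonzero(events == cls)
            n_syn = (cfg.factor - 1) * len(members)
            if n_syn == 0:
                continue
            if len(members) < 2:
                raise ValueError(f"event class {cls} too small for SMOTE (n={len(members)})")
            k = min(cfg.k_neighbors, len(members) - 1)
            Xc = X.iloc[members].to_numpy(dtype=float)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, neigh = nn.kneighbors(Xc)
            for j in range(n_syn):
                i = int(rng.integers(0, len(members)))
                # neighbors exclude the point itself (first column)
                m = int(rng.integers(1, k + 1))
                p = neigh[i, m]
                u = float(rng.uniform())
                row = Xc[i] + u * (Xc[p] - Xc[i])
                t = times[members[i]] + u * (times[members[p]] - times[members[i]])
                new_rows.append(row)
                new_times.append(t)
                new_events.append(cls)
                new_ids.append(f"{X.index[members[i]]}_s{j}")
        if new_rows:
            synth = pd.DataFrame(np.array(new_rows), columns=X.columns, index=new_ids)
            X_out = pd.concat([X, synth])
            t_out = np.concatenate([times, np.array(new_times)])
            e_out = np.concatenate([events, np.array(new_events, dtype=int)])
        else:
            X_out, t_out, e_out = X.copy(), times.copy(), events.copy()
        return X_out, t_out, e_out


def smote_augment(
    table: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    cfg: AugmentationConfig = AugmentationConfig(),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Functional wrapper over :class:`SurvivalSMOTE`."""
    return SurvivalSMOTE(cfg.factor, cfg.k_neighbors, cfg.seed).fit_resample(
        table, times, events
    )
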