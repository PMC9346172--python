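"""Radiomics signature construction and robustness-driven optimization.

The signature pipeline, per hyperparameter grid point (requantization
window R, kernel K, stride S) and elastic-net blending alpha:

1. z-score the training feature table and SMOTE-augment it;
2. split the augmented cohort into equal training/validation subdatasets;
3. rank features by how often the elastic-net-penalized Cox model
   (Cox-net) assigns them a nonzero coefficient along the regularization
   path, keeping the top <= 7 "significant" features;
4. for every non-empty subset, refit an unpenalized Cox proportional
   hazards model (Efron ties) on the training subdataset, compute radiomics
   scores (the linear predictor sum beta_i x_i) for both subdatasets,
   stratify both by the training-subdataset median, and record the nLPC of
   each;
5. combine the two nLPCs into a robustness index (RI; harmonic mean by
   default) and keep the subset/grid point with the maximum RI.

Validation always reuses the training-subdataset coefficients and median —
there is no refitting leak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.base import BaseEstimator

from .cohort import SurvivalSMOTE, ZScoreNormalizer
from .evaluate import evaluate_stratification

__all__ = [
    "CoxnetConfig",
    "SignatureModel",
    "OptimizationRecord",
    "OptimizationResult",
    "SignatureSkipped",
    "NoFeaturesSelectedError",
    "coxnet_significant_features",
    "enumerate_signatures",
    "fit_cphm",
    "radiomics_score",
    "robustness_index",
    "optimize_signature",
    "SignatureOptimizer",
]


class SignatureSkipped(Exception):
    """A candidate signature could not be fit (collinearity/non-convergence)."""


class NoFeaturesSelectedError(Exception):
    """Cox-net never assigned a nonzero coefficient to any feature."""


@dataclass(frozen=True)
class CoxnetConfig:
    """Elastic-net blending alpha and regularization-path layout."""

    alpha: float = 0.5
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    max_significant: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.max_significant < 1:
            raise ValueError("max_significant must be >= 1")


@dataclass(frozen=True)
class SignatureModel:
    """Selected features, unpenalized Cox coefficients and the training
    median score used for risk stratification."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    training_median_score: float
    endpoint: str = ""

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if not 1 <= len(self.feature_names) <= 7:
            raise ValueError("signature must contain 1..7 features")
        if len(self.feature_names) != coef.size or not np.all(np.isfinite(coef)):
            raise ValueError("coefficients must be finite and match the features")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    def score(self, table: pd.DataFrame) -> np.ndarray:
        return radiomics_score(table, self)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "training_median_score": self.training_median_score,
            "endpoint": self.endpoint,
        }


def _surv_y(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    return np.array(
        list(zip(np.asarray(events, bool), np.asarray(times, float))),
        dtype=[("event", "?"), ("time", "<f8")],
    )


def coxnet_significant_features(
    table: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    cfg: CoxnetConfig = CoxnetConfig(),
) -> list[str]:
    """Rank features by Cox-net selection frequency along the lambda path.

    Frequency = number of path points with a nonzero coefficient; ties are
    broken by the maximum |coefficient| over the path, then by column
    order.  Returns the top ``max_significant`` features with frequency > 0.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    events = np.asarray(events, int)
    if events.sum() < 2:
        raise ValueError("need at least 2 events for Cox-net selection")
    X = table.to_numpy(dtype=float)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=cfg.alpha,
        n_alphas=cfg.n_lambdas,
        alpha_min_ratio=cfg.lambda_min_ratio,
        fit_baseline_model=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, _surv_y(times, events))
    coefs = model.coef_  # (n_features, n_path)
    freq = (coefs != 0).sum(axis=1)
    if freq.max() == 0:
        raise NoFeaturesSelectedError(
            f"no nonzero Cox-net coefficients over {coefs.shape[1]} path points "
            f"(alpha={cfg.alpha}, n={len(table)}, events={int(events.sum())})"
        )
    max_abs = np.abs(coefs).max(axis=1)
    order = np.lexsort((np.arange(len(freq)), -max_abs, -freq))
    cols = list(table.columns)
    return [cols[i] for i in order[: cfg.max_significant] if freq[i] > 0]


def enumerate_signatures(top_features: Sequence[str]) -> list[tuple[str, ...]]:
    """All non-empty subsets of the significant features, smallest first."""
    if not 1 <= len(top_features) <= 7:
        raise ValueError("expected 1..7 significant features")
    subsets: list[tuple[str, ...]] = []
    for r in range(1, len(top_features) + 1):
        subsets.extend(combinations(top_features, r))
    return subsets


def fit_cphm(table: pd.DataFrame, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Unpenalized Cox partial-likelihood fit (Efron ties) of a signature.

    Raises :class:`SignatureSkipped` on rank deficiency or non-convergence
    rather than returning silent garbage.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[1] > 7:
        raise ValueError("signature larger than 7 features")
    events = np.asarray(events, int)
    if events.sum() < X.shape[1] + 1:
        raise SignatureSkipped("too few events for the signature size")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SignatureSkipped("collinear signature design")
    df = table.copy()
    df["__T"] = np.asarray(times, float)
    df["__E"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="__T", event_col="__E")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise SignatureSkipped(f"CPHM did not converge: {exc}") from exc
    beta = cph.params_[list(table.columns)].to_numpy(dtype=float)
    if not np.all(np.isfinite(beta)):
        raise SignatureSkipped("non-finite coefficients")
    return beta


def radiomics_score(x, model: SignatureModel) -> np.ndarray:
    """Linear predictor sum beta_i x_i of a fitted signature."""
    if isinstance(x, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in x.columns]
        if missing:
            raise KeyError(f"missing signature features: {missing}")
        X = x[list(model.feature_names)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != len(model.feature_names):
            raise ValueError("feature count mismatch")
    return X @ model.coefficients


def robustness_index(nlpc_train: float, nlpc_val: float, strategy: str = "harmonic") -> float:
    """Combine training and validation nLPCs into a robustness index.

    The default harmonic mean 2TV/(T+V) rewards jointly high and similar
    values and is 0 whenever either nLPC is 0 (overfit penalized).
    """
    if nlpc_train < 0 or nlpc_val < 0:
        raise ValueError("nLPC inputs must be >= 0")
    if strategy == "harmonic":
        s = nlpc_train + nlpc_val
        return 0.0 if s == 0 else 2.0 * nlpc_train * nlpc_val / s
    if strategy == "min":
        return float(min(nlpc_train, nlpc_val))
    if strategy == "mean":
        return 0.5 * (nlpc_train + nlpc_val)
    raise ValueError(f"unknown RI strategy {strategy!r}")


@dataclass(frozen=True)
class OptimizationRecord:
    """One evaluated (grid point, alpha, signature) combination."""

    grid_point: tuple
    alpha: float
    signature: tuple[str, ...]
    nlpc_train: float
    nlpc_val: float
    ri: float
    coefficients: tuple[float, ...] = ()
    median_score: float = float("nan")


@dataclass
class OptimizationResult:
    """Winning record plus the exhaustive evaluation ledger."""

    best: OptimizationRecord
    ledger: pd.DataFrame
    skips: list[dict] = field(default_factory=list)
    normalizer: ZScoreNormalizer | None = None
    significant_features: tuple[str, ...] = ()

    def build_model(self, train_table: pd.DataFrame, endpoint: str = "") -> SignatureModel:
        """Signature model for test-set evaluation: winning coefficients
        with the median score taken over the original (un-augmented)
        normalized training cohort."""
        Xn = self.normalizer.transform(train_table)
        model = SignatureModel(
            self.best.signature,
            np.asarray(self.best.coefficients),
            training_median_score=0.0,
            endpoint=endpoint,
        )
        median = float(np.median(radiomics_score(Xn, model)))
        return SignatureModel(
            self.best.signature, np.asarray(self.best.coefficients), median, endpoint
        )


def _split_half(
    n: int, events: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random half/half split stratified by event status."""
    idx_a, idx_b = [], []
    for cls in (0, 1):
        members = np.flatnonzero(events == cls)
        rng.shuffle(members)
        half = len(members) // 2
        idx_a.extend(members[:half].tolist())
        idx_b.extend(members[half:].tolist())
    return np.sort(np.array(idx_a, dtype=int)), np.sort(np.array(idx_b, dtype=int))


def optimize_signature(
    tables: Mapping[tuple, pd.DataFrame],
    times: np.ndarray,
    events: np.ndarray,
    *,
    alphas: Sequence[float] = (0.5,),
    factor: int = 4,
    k_neighbors: int = 5,
    max_significant: int = 7,
    ri_strategy: str = "harmonic",
    seed: int = 0,
) -> OptimizationResult:
    """Grid search over feature tables x alphas maximizing the RI.

    ``tables`` maps a hyperparameter grid point (e.g. (R, K, S)) to the
    training-cohort feature table computed under those parameters; all
    tables must share the patient index.  Returns the winning record, the
    full ledger and the winning grid point's fitted normalizer.
    """
    if not tables:
        raise ValueError("empty hyperparameter grid")
    if not alphas:
        raise ValueError("empty alpha grid")
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    records: list[OptimizationRecord] = []
    skips: list[dict] = []
    normalizers: dict[tuple, ZScoreNormalizer] = {}

    for gp_i, (gp, table) in enumerate(sorted(tables.items(), key=lambda kv: repr(kv[0]))):
        norm = ZScoreNormalizer().fit(table)
        normalizers[gp] = norm
        Xn = norm.transform(table)
        # derive a sub-seed per grid point so augmentation/split are
        # reproducible yet independent across grid points
        sub_seed = (seed * 1000003 + gp_i) % (2**31 - 1)
        Xa, ta, ea = SurvivalSMOTE(factor, k_neighbors, sub_seed).fit_resample(
            Xn, times, events
        )
        rng = np.random.default_rng(sub_seed + 1)
        idx_tr, idx_val = _split_half(len(Xa), ea, rng)
        X_tr, X_val = Xa.iloc[idx_tr], Xa.iloc[idx_val]
        t_tr, t_val = ta[idx_tr], ta[idx_val]
        e_tr, e_val = ea[idx_tr], ea[idx_val]
        for alpha in alphas:
            cfg = CoxnetConfig(alpha=alpha, max_significant=max_significant)
            try:
                sig_feats = coxnet_significant_features(X_tr, t_tr, e_tr, cfg)
            except NoFeaturesSelectedError as exc:
                skips.append({"grid_point": gp, "alpha": alpha, "reason": str(exc)})
                continue
            for subset in enumerate_signatures(sig_feats):
                try:
                    beta = fit_cphm(X_tr[list(subset)], t_tr, e_tr)
                except SignatureSkipped as exc:
                    skips.append(
                        {"grid_point": gp, "alpha": alpha, "signature": subset, "reason": str(exc)}
                    )
                    continue
                model = SignatureModel(subset, beta, 0.0)
                s_tr = radiomics_score(X_tr, model)
                median = float(np.median(s_tr))
                rep_tr = evaluate_stratification(s_tr, t_tr, e_tr, median, dataset="train")
                s_val = radiomics_score(X_val, model)
                rep_val = evaluate_stratification(s_val, t_val, e_val, median, dataset="val")
                ri = robustness_index(rep_tr.nlpc, rep_val.nlpc, ri_strategy)
                records.append(
                    OptimizationRecord(
                        grid_point=gp,
                        alpha=alpha,
                        signature=subset,
                        nlpc_train=rep_tr.nlpc,
                        nlpc_val=rep_val.nlpc,
                        ri=ri,
                        coefficients=tuple(beta.tolist()),
                        median_score=median,
                    )
                )
    if not records:
        raise RuntimeError(f"all grid points failed; skips: {skips}")
    best = max(records, key=lambda r: r.ri)  # max is stable: first argmax wins
    ledger = pd.DataFrame(
        {
            "grid_point": [repr(r.grid_point) for r in records],
            "alpha": [r.alpha for r in records],
            "signature": ["|".join(r.signature) for r in records],
            "nlpc_train": [r.nlpc_train for r in records],
            "nlpc_val": [r.nlpc_val for r in records],
            "ri": [r.ri for r in records],
        }
    )
    # significant features of the winning grid point/alpha are recoverable
    # from the ledger; store the winner's set for convenience
    win_feats = tuple(
        dict.fromkeys(f for r in records if r.grid_point == best.grid_point and r.alpha == best.alpha for f in r.signature)
    )
    return OptimizationResult(
        best=best,
        ledger=ledger,
        skips=skips,
        normalizer=normalizers[best.grid_point],
        significant_features=win_feats,
    )


class SignatureOptimizer(BaseEstimator):
    """Estimator wrapper around :func:`optimize_signature`.

    ``fit(tables, times, events)`` stores the winning record as
    ``best_record_``, the ledger as ``ledger_`` and, after calling
    ``build_model``, exposes a ready :class:`SignatureModel`.
    """

    def __init__(
        self,
        alphas: Sequence[float] = (0.5,),
        factor: int = 4,
        k_neighbors: int = 5,
        max_significant: int = 7,
        ri_strategy: str = "harmonic",
        random_state: int = 0,
    ):
        self.alphas = alphas
        self.factor = factor
        self.k_neighbors = k_neighbors
        self.max_significant = max_significant
        self.ri_strategy = ri_strategy
        self.random_state = random_state

    def fit(self, tables: Mapping[tuple, pd.DataFrame], times, events):
        result = optimize_signature(
            tables,
            times,
            events,
            alphas=self.alphas,
            factor=self.factor,
            k_neighbors=self.k_neighbors,
            max_significant=self.max_significant,
            ri_strategy=self.ri_strategy,
            seed=self.random_state,
        )
        self.result_ = result
        self.best_record_ = result.best
        self.ledger_ = result.ledger
        self.normalizer_ = result.normalizer
        return self

    def build_model(self, train_table: pd.DataFrame, endpoint: str = "") -> SignatureModel:
        return self.result_.build_model(train_table, endpoint)
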