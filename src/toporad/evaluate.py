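"""Kaplan-Meier risk-group evaluation: log-rank p, Harrell's c-index and
the composite index nLPC = (-log10 p) x c.

Patients are stratified into high- and low-risk groups by a reference
median radiomics score (always the training median — the test set never
uses its own).  The c-index is computed from the response score defined as
minus the radiomics score, so c = 1 means higher radiomics scores always
pair with shorter survival.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index

__all__ = [
    "EvaluationReport",
    "stratify_by_median",
    "km_estimate",
    "logrank_test",
    "harrell_c",
    "nlpc",
    "evaluate_stratification",
]


@dataclass(frozen=True)
class EvaluationReport:
    """p, c-index and nLPC for one endpoint on one dataset."""

    endpoint: str
    dataset: str
    p_logrank: float
    c_index: float
    nlpc: float
    n_high: int
    n_low: int
    median_used: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def stratify_by_median(scores: np.ndarray, median_ref: float) -> np.ndarray:
    """Boolean high-risk flags: score > reference median -> high risk.

    Scores equal to the median go to the low-risk group.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(median_ref):
        raise ValueError("median_ref must be finite")
    return scores > median_ref


def km_estimate(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate; returns (event_times, S(t)) steps."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> float:
    """Two-sided two-group log-rank p-value (chi-square, 1 df)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() == 0 and eb.sum() == 0:
        warnings.warn("no events in either group; log-rank p defined as 1")
        return 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.p_value)


def harrell_c(scores: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Harrell's concordance of the response score (-radiomics score) with
    survival time; ties in the response receive half credit."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if scores.size < 2:
        raise ValueError("need at least two patients")
    if events.sum() == 0:
        raise ValueError("no permissible pairs: no events observed")
    return float(concordance_index(times, -scores, events))


def nlpc(p: float, c: float) -> float:
    """The composite evaluation index (-log10 p) x c."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if not 0 <= c <= 1:
        raise ValueError("c must lie in [0, 1]")
    return float(-np.log10(p) * c)


def evaluate_stratification(
    scores: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    median_ref: float,
    *,
    endpoint: str = "",
    dataset: str = "",
) -> EvaluationReport:
    """Full evaluation of one score vector against one endpoint."""
    high = stratify_by_median(scores, median_ref)
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if high.all() or (~high).all():
        # degenerate stratification: groups do not partition -> p = 1
        warnings.warn("median stratification produced a single group; p set to 1")
        p = 1.0
    else:
        p = logrank_test(times[high], events[high], times[~high], events[~high])
    c = harrell_c(scores, times, events)
    return EvaluationReport(
        endpoint=endpoint,
        dataset=dataset,
        p_logrank=p,
        c_index=c,
        nlpc=nlpc(p, c),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        median_used=float(median_ref),
    )
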