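"""Screening-performance measures computed from screening traces.

All measures consume a :class:`~screensim.al_engine.ScreeningTrace` (the
complete prioritized order of the non-prior pool with true labels):

* recall curve -- cumulative relevant count per screening position;
* WSS@r (work saved over sampling) -- the fraction of the pool that need
  not be screened to reach recall ``r``, minus the ``1 - r`` allowance,
  in percent: ``100 * ((N - n*) / N - (1 - r))`` where ``n*`` is the
  first position at which ``ceil(r * R)`` relevant records are found;
* RRF@p (relevant records found) -- percent of relevant records found
  after screening a ``ceil(p * N)``-record prefix;
* TD / ATD (time to discovery) -- the fraction of the pool screened
  before a given relevant record is found, averaged over records and
  runs; high TD flags hard-to-find records and candidate noisy labels.

Prior records are excluded from every numerator and denominator: they are
never part of the trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .al_engine import ScreeningTrace
from .exceptions import ConfigurationError


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation cut-offs: recall level for WSS, prefix fraction for RRF."""

    recall_level: float = 0.95
    screen_fraction: float = 0.10

    def __post_init__(self):
        if not 0 < self.recall_level <= 1:
            raise ConfigurationError("recall_level must be in (0, 1]")
        if not 0 < self.screen_fraction <= 1:
            raise ConfigurationError("screen_fraction must be in (0, 1]")


def recall_curve(trace: ScreeningTrace) -> np.ndarray:
    """Cumulative relevant count: s[k-1] = relevant among first k screened."""
    return np.cumsum(trace.labels_in_order)


def wss(trace: ScreeningTrace, config: MetricConfig = MetricConfig()) -> float:
    """Work saved over sampling at ``config.recall_level``, in percent.

    With ``m = ceil(r * R)`` and ``n*`` the smallest prefix containing
    ``m`` relevant records, returns ``100 * ((N - n*) / N - (1 - r))``.
    Best case (all relevant first) gives ``100 * (r - m / N)``; worst case
    ``-100 * (1 - r)``.
    """
    r = config.recall_level
    n_pool, r_pool = trace.n_pool, trace.r_pool
    if r_pool < 1:
        raise ConfigurationError("wss needs at least one relevant pool record")
    m = math.ceil(r * r_pool)
    curve = recall_curve(trace)
    n_star = int(np.searchsorted(curve, m)) + 1  # positions are 1-based
    return 100.0 * ((n_pool - n_star) / n_pool - (1.0 - r))


def rrf(trace: ScreeningTrace, config: MetricConfig = MetricConfig()) -> float:
    """Percent of relevant records found in the first ceil(p*N) screened."""
    n_pool, r_pool = trace.n_pool, trace.r_pool
    if r_pool < 1:
        raise ConfigurationError("rrf needs at least one relevant pool record")
    k = math.ceil(config.screen_fraction * n_pool)
    curve = recall_curve(trace)
    return 100.0 * float(curve[k - 1]) / r_pool


def time_to_discovery(trace: ScreeningTrace) -> dict[str, float]:
    """TD per relevant pool record: screening position / pool size.

    Prior relevant records are not in the trace, hence not in the map.
    """
    n_pool = trace.n_pool
    return {
        rid: (k + 1) / n_pool
        for k, (rid, label) in enumerate(zip(trace.ordered_ids, trace.labels_in_order))
        if label == 1
    }


def atd(traces: list[ScreeningTrace]) -> tuple[float, float]:
    """Average time to discovery pooled over records and runs.

    Returns ``(fraction, abstracts)``: the mean TD as a fraction of the
    pool, and the same quantity expressed as a mean abstract count
    (fraction times the mean pool size across runs).
    """
    if not traces:
        raise ConfigurationError("atd needs at least one trace")
    tds: list[float] = []
    for trace in traces:
        tds.extend(time_to_discovery(trace).values())
    if not tds:
        raise ConfigurationError("no relevant records in any trace")
    fraction = float(np.mean(tds))
    mean_n = float(np.mean([t.n_pool for t in traces]))
    return fraction, fraction * mean_n


def hard_to_find(traces: list[ScreeningTrace], top_k: int) -> list[tuple[str, float]]:
    """Rank records by mean TD across runs, hardest (latest found) first.

    Ties break by record_id.  ``top_k`` larger than the number of ranked
    records returns the full ranking.  High mean TD flags hard-to-find
    records whose labels are worth re-examining.
    """
    if top_k <= 0:
        raise ConfigurationError("top_k must be positive")
    if not traces:
        raise ConfigurationError("hard_to_find needs at least one trace")
    pooled: dict[str, list[float]] = {}
    for trace in traces:
        for rid, td in time_to_discovery(trace).items():
            pooled.setdefault(rid, []).append(td)
    ranking = sorted(
        ((rid, float(np.mean(v))) for rid, v in pooled.items()),
        key=lambda item: (-item[1], item[0]),
    )
    return ranking[:top_k]


def summarize_runs(
    traces: list[ScreeningTrace], config: MetricConfig = MetricConfig()
) -> dict:
    """Per-run WSS/RRF then mean and sample SD over runs, plus pooled ATD.

    The mean-then-SD-over-runs aggregation matches how multi-run
    simulation results are conventionally tabulated; SD is NaN for a
    single run.
    """
    wss_runs = [wss(t, config) for t in traces]
    rrf_runs = [rrf(t, config) for t in traces]
    atd_fraction, atd_abstracts = atd(traces)

    def _sd(values):
        return float(np.std(values, ddof=1)) if len(values) > 1 else math.nan

    return {
        "n_runs": len(traces),
        "wss": {"mean": float(np.mean(wss_runs)), "sd": _sd(wss_runs), "per_run": wss_runs},
        "rrf": {"mean": float(np.mean(rrf_runs)), "sd": _sd(rrf_runs), "per_run": rrf_runs},
        "atd": {"fraction": atd_fraction, "abstracts": atd_abstracts},
    }


def mean_recall_curve(traces: list[ScreeningTrace]) -> np.ndarray:
    """Mean cumulative-relevant curve over runs (pools of equal size)."""
    sizes = {t.n_pool for t in traces}
    if len(sizes) != 1:
        raise ConfigurationError("mean_recall_curve needs equal-size pools")
    return np.mean([recall_curve(t) for t in traces], axis=0)
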