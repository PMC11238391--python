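"""Orchestration of multi-dataset, multi-stage screening experiments.

A "study" runs the active-learning simulation against each of the three
adjudication stages of a corpus -- (1) the clinicians' title-abstract
selection, (2) the research methodologist's re-evaluation, (3) the final
full-text inclusions -- aggregates per-run metrics into per-stage
summaries, tabulates summaries across datasets with an unweighted Totals
row, and measures how label noise degrades screening performance on
synthetic corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import al_engine, metrics
from .corpus_io import Corpus
from .exceptions import InfeasibleSimulationError, StudyError, ValidationError
from .synthetic import GeneratorConfig, generate_corpus

#: Stage roles in adjudication order, mapped to canonical label columns.
STAGE_COLUMNS = {
    "clinician": "label_clinician",
    "methodologist": "label_methodologist",
    "fulltext": "label_fulltext",
}


@dataclass
class StageSummary:
    """Per-stage aggregate over runs; the per-dataset table row analogue.

    ``status`` is ``"infeasible"`` (numeric fields NaN) when the stage
    has fewer than two relevant records or too few irrelevant ones --
    such stages are reported as NA, not failed.
    """

    stage: str
    n_selected: int
    status: str = "ok"
    n_runs: int = 0
    wss95_mean: float = math.nan
    wss95_sd: float = math.nan
    rrf10_mean: float = math.nan
    rrf10_sd: float = math.nan
    atd_fraction: float = math.nan
    atd_abstracts: float = math.nan


def resolve_stage_column(corpus: Corpus, stage: str) -> str:
    """Map a stage role to a label column of ``corpus``.

    The clinician stage uses the consolidated clinician column when
    present; otherwise the union (logical OR) of the two rater columns is
    materialized, reflecting union-style triage in which a record flagged
    by either rater moves forward.
    """
    if stage not in STAGE_COLUMNS:
        raise ValidationError(f"unknown stage {stage!r}; choose from {list(STAGE_COLUMNS)}")
    column = STAGE_COLUMNS[stage]
    if column in corpus.stage_columns:
        return column
    if stage == "clinician" and {
        "label_clinician1",
        "label_clinician2",
    } <= set(corpus.stage_columns):
        return "label_clinician:or"
    raise ValidationError(f"corpus has no column for stage {stage!r}")


def _with_stage(corpus: Corpus, stage: str) -> tuple[Corpus, str]:
    column = resolve_stage_column(corpus, stage)
    if column == "label_clinician:or":
        r1 = corpus.labels("label_clinician1")
        r2 = corpus.labels("label_clinician2")
        union = [
            None if (a is None and b is None) else int(bool(a) or bool(b))
            for a, b in zip(r1, r2)
        ]
        return corpus.with_column("label_clinician", union), "label_clinician"
    return corpus, column


def run_stage(
    corpus: Corpus,
    stage: str,
    config: al_engine.SimulationConfig,
    n_runs: int | str = "all",
    metric_config: metrics.MetricConfig = metrics.MetricConfig(),
) -> StageSummary:
    """Simulate one stage and aggregate its runs into a StageSummary."""
    corpus, column = _with_stage(corpus, stage)
    labels = corpus.labels(column)
    n_selected = sum(1 for v in labels if v == 1)
    sim_config = replace(config, stage=column)
    try:
        traces = al_engine.run_batch(corpus, column, sim_config, n_runs=n_runs)
    except InfeasibleSimulationError:
        return StageSummary(stage=stage, n_selected=n_selected, status="infeasible")
    summary = metrics.summarize_runs(traces, metric_config)
    return StageSummary(
        stage=stage,
        n_selected=n_selected,
        status="ok",
        n_runs=summary["n_runs"],
        wss95_mean=summary["wss"]["mean"],
        wss95_sd=summary["wss"]["sd"],
        rrf10_mean=summary["rrf"]["mean"],
        rrf10_sd=summary["rrf"]["sd"],
        atd_fraction=summary["atd"]["fraction"],
        atd_abstracts=summary["atd"]["abstracts"],
    )


def run_three_stage_study(
    corpus: Corpus,
    config: al_engine.SimulationConfig,
    n_runs: int | str = "all",
    metric_config: metrics.MetricConfig = metrics.MetricConfig(),
) -> dict[str, StageSummary]:
    """Run the simulation against all three adjudication stages.

    Stages with fewer than two relevant records come back with status
    ``"infeasible"``; if no stage is feasible a :class:`StudyError` is
    raised.
    """
    summaries = {
        stage: run_stage(corpus, stage, config, n_runs, metric_config)
        for stage in STAGE_COLUMNS
    }
    if all(s.status == "infeasible" for s in summaries.values()):
        raise StudyError("no feasible stage in corpus")
    return summaries


def aggregate_datasets(
    rows: dict[str, dict[str, StageSummary]],
) -> pd.DataFrame:
    """Tabulate per-dataset stage summaries with an unweighted Totals row.

    ``rows`` maps dataset name -> stage -> StageSummary.  The Totals row
    holds, per stage, the unweighted mean and sample SD of the
    per-dataset mean metrics, computed only over datasets whose stage was
    feasible; infeasible cells stay NaN and their exclusion count is
    recorded in the ``n_excluded_*`` columns of the Totals row.
    """
    if not rows:
        raise ValidationError("aggregate_datasets needs at least one dataset")
    stages = list(STAGE_COLUMNS)
    table_rows = []
    for dataset, summaries in rows.items():
        row: dict[str, object] = {"dataset": dataset}
        for stage in stages:
            s = summaries[stage]
            row[f"select_{stage}"] = s.n_selected
            row[f"wss95_{stage}"] = s.wss95_mean
            row[f"wss95_sd_{stage}"] = s.wss95_sd
            row[f"rrf10_{stage}"] = s.rrf10_mean
            row[f"rrf10_sd_{stage}"] = s.rrf10_sd
            row[f"status_{stage}"] = s.status
        table_rows.append(row)
    frame = pd.DataFrame(table_rows)

    totals: dict[str, object] = {"dataset": "Total"}
    for stage in stages:
        ok = frame[frame[f"status_{stage}"] == "ok"]
        totals[f"select_{stage}"] = frame[f"select_{stage}"].sum()
        for metric in ("wss95", "rrf10"):
            values = ok[f"{metric}_{stage}"]
            totals[f"{metric}_{stage}"] = values.mean() if len(values) else math.nan
            totals[f"{metric}_sd_{stage}"] = (
                values.std(ddof=1) if len(values) > 1 else math.nan
            )
        totals[f"status_{stage}"] = "ok"
        totals[f"n_excluded_{stage}"] = int((frame[f"status_{stage}"] != "ok").sum())
    return pd.concat([frame, pd.DataFrame([totals])], ignore_index=True)


def noise_degradation_experiment(
    noise_grid,
    generator_config: GeneratorConfig,
    n_replicates: int = 20,
    seed: int = 0,
    sim_config: al_engine.SimulationConfig | None = None,
    n_runs: int | str = 1,
    max_retries: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Mean clinician-stage WSS@95 as a function of rater false-inclusion rate.

    For each noise rate in the ascending ``noise_grid``, ``n_replicates``
    corpora are generated with ``rater_fp`` set to the rate, the
    clinician stage is simulated, and the mean WSS@95 recorded.  The
    returned trend statistic is the Spearman rank correlation between the
    noise rate and the replicate-level WSS values (negative when noisier
    labels degrade screening performance); NaN when the grid has a single
    point.
    """
    noise_grid = list(noise_grid)
    if noise_grid != sorted(noise_grid):
        raise ValidationError("noise_grid must be sorted ascending")
    if sim_config is None:
        sim_config = al_engine.SimulationConfig(seed=seed)

    records = []
    pairs: list[tuple[float, float]] = []
    for rate_index, rate in enumerate(noise_grid):
        rep_values = []
        for rep in range(n_replicates):
            summary = None
            for attempt in range(max_retries):
                corpus_seed = int(
                    np.random.SeedSequence(
                        [seed, rate_index, rep, attempt]
                    ).generate_state(1)[0] % (2**31)
                )
                gen = replace(
                    generator_config, rater_fp=float(rate), seed=corpus_seed
                )
                corpus = generate_corpus(gen)
                candidate = run_stage(
                    corpus,
                    "clinician",
                    replace(sim_config, seed=corpus_seed),
                    n_runs=n_runs,
                )
                if candidate.status == "ok":
                    summary = candidate
                    break
            if summary is None:
                raise StudyError(
                    f"no feasible clinician stage after {max_retries} retries "
                    f"at noise rate {rate}"
                )
            rep_values.append(summary.wss95_mean)
            pairs.append((rate, summary.wss95_mean))
        records.append(
            {
                "noise_rate": rate,
                "wss95_mean": float(np.mean(rep_values)),
                "wss95_sd": float(np.std(rep_values, ddof=1))
                if len(rep_values) > 1
                else math.nan,
                "n_replicates": len(rep_values),
            }
        )

    table = pd.DataFrame(records)
    if len(noise_grid) < 2:
        return table, math.nan
    rates, values = zip(*pairs)
    rho = float(spearmanr(rates, values).statistic)
    return table, rho
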