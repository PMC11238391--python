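"""Pool-based active-learning simulation of prioritized screening.

The simulated workflow mirrors how screening-prioritization tools are
used in practice: the reviewer supplies a small set of prior knowledge
(one known-relevant and ten known-irrelevant records), a classifier is
trained on everything labeled so far, the unscreened pool is ranked by
predicted relevance, the top-ranked record is "screened" (its true label
at the chosen adjudication stage is revealed), and the model is
retrained.  The loop runs until the pool is exhausted, producing a
:class:`ScreeningTrace` -- the complete screening order with true labels
-- from which all performance metrics are computed.

Features are TF-IDF weighted unigrams fit once on the whole corpus
(the pool's text is visible to a screener from the start); the classifier
is a multinomial naive Bayes with additive smoothing.  Because relevance
prevalence is typically 1-25%, relevant training records are up-weighted
so the labeled-class imbalance does not collapse the posterior.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.naive_bayes import MultinomialNB

from .corpus_io import Corpus
from .exceptions import (
    ConfigurationError,
    FeaturizationError,
    InfeasibleSimulationError,
)

DEFAULT_SMOOTHING = 3.822  # additive-smoothing default of the reference tooling


@dataclass(frozen=True)
class PriorSet:
    """Seeded prior knowledge: one relevant + ten irrelevant record ids."""

    relevant_id: str
    irrelevant_ids: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if self.relevant_id in self.irrelevant_ids:
            raise ConfigurationError("relevant prior overlaps irrelevant priors")
        if len(set(self.irrelevant_ids)) != len(self.irrelevant_ids):
            raise ConfigurationError("duplicate irrelevant prior ids")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return (self.relevant_id, *self.irrelevant_ids)


@dataclass
class SimulationConfig:
    """Knobs of one simulation.

    stage
        Label column used as ground truth for the run.
    smoothing
        Additive (Lidstone) smoothing constant of the naive Bayes
        classifier; must be positive.
    balance_ratio
        Multiplier on the dynamic up-weighting of relevant training
        records.  1.0 weights the relevant class up to parity with the
        irrelevant class.
    retrain_every
        Number of labels revealed between retrainings (1 = retrain after
        every screened record).
    seed
        Master RNG seed: drives prior selection and tie-breaking.
    n_prior_irrelevant
        Size of the shared irrelevant prior set (default ten).
    """

    stage: str = "label_fulltext"
    smoothing: float = DEFAULT_SMOOTHING
    balance_ratio: float = 1.0
    retrain_every: int = 1
    seed: int = 0
    n_prior_irrelevant: int = 10

    def __post_init__(self):
        if self.smoothing <= 0:
            raise ConfigurationError("smoothing must be > 0")
        if self.balance_ratio <= 0:
            raise ConfigurationError("balance_ratio must be > 0")
        if self.retrain_every < 1:
            raise ConfigurationError("retrain_every must be >= 1")
        if self.n_prior_irrelevant < 1:
            raise ConfigurationError("n_prior_irrelevant must be >= 1")


@dataclass
class ScreeningTrace:
    """The screening order of the non-prior pool with true labels.

    ``ordered_ids`` is a complete permutation of the pool (priors
    excluded); ``labels_in_order`` the corresponding true binary labels.
    """

    ordered_ids: list[str]
    labels_in_order: np.ndarray
    prior: PriorSet | None = None
    run_index: int = 0

    def __post_init__(self):
        self.labels_in_order = np.asarray(self.labels_in_order, dtype=int)
        if len(self.ordered_ids) != self.labels_in_order.size:
            raise ConfigurationError("trace ids and labels differ in length")

    @property
    def n_pool(self) -> int:
        return len(self.ordered_ids)

    @property
    def r_pool(self) -> int:
        return int(self.labels_in_order.sum())


def fit_features(texts: list[str]):
    """TF-IDF featurization: fit once over the whole corpus.

    Lowercased unigram tokens of at least two word characters; smoothed
    idf ``ln((1+D)/(1+df)) + 1``; rows L2-normalized.

    Returns
    -------
    (matrix, vocabulary)
        Sparse document-term weight matrix and the fitted vocabulary
        (term -> column index).
    """
    if not texts or all(not t.strip() for t in texts):
        raise FeaturizationError("no nonempty texts to featurize")
    vectorizer = TfidfVectorizer(lowercase=True, token_pattern=r"(?u)\b\w\w+\b")
    try:
        matrix = vectorizer.fit_transform(texts)
    except ValueError as exc:  # sklearn raises on empty vocabulary
        raise FeaturizationError(str(exc)) from exc
    return matrix, vectorizer.vocabulary_


def train_and_score(
    features,
    training_idx,
    training_labels,
    config: SimulationConfig,
    candidate_idx,
) -> np.ndarray:
    """Fit naive Bayes on the labeled rows; score candidate rows.

    Relevant training rows receive sample weight
    ``balance_ratio * n_irrelevant / n_relevant`` so the effective class
    shares stay balanced as the labeled set grows.  Returns the posterior
    probability of relevance per candidate; deterministic given inputs.
    """
    training_idx = np.asarray(training_idx, dtype=int)
    training_labels = np.asarray(training_labels, dtype=int)
    candidate_idx = np.asarray(candidate_idx, dtype=int)
    if candidate_idx.size == 0:
        return np.empty(0)

    n_rel = int(training_labels.sum())
    n_irr = training_labels.size - n_rel
    if n_rel == 0 or n_irr == 0:
        raise InfeasibleSimulationError(
            "training set must contain both classes"
        )
    weights = np.ones(training_labels.size)
    weights[training_labels == 1] = config.balance_ratio * n_irr / n_rel

    model = MultinomialNB(alpha=config.smoothing)
    model.fit(features[training_idx], training_labels, sample_weight=weights)
    scores = model.predict_proba(features[candidate_idx])
    return scores[:, list(model.classes_).index(1)]


def _stage_arrays(corpus: Corpus, stage: str):
    labels = corpus.labels(stage)
    ids = corpus.ids()
    labeled_idx = np.array([i for i, v in enumerate(labels) if v is not None], dtype=int)
    values = np.array([labels[i] for i in labeled_idx], dtype=int)
    return ids, labeled_idx, values


def check_feasible(corpus: Corpus, stage: str, n_irrelevant: int = 10) -> None:
    """Raise InfeasibleSimulationError unless the stage supports a run."""
    _, labeled_idx, values = _stage_arrays(corpus, stage)
    n_rel = int(values.sum())
    n_irr = values.size - n_rel
    if n_rel < 2:
        raise InfeasibleSimulationError(
            f"stage {stage!r} has {n_rel} relevant record(s); a simulation "
            "needs at least one relevant record as training data and one "
            "relevant record as a target to detect"
        )
    if n_irr < n_irrelevant:
        raise InfeasibleSimulationError(
            f"stage {stage!r} has {n_irr} irrelevant records; "
            f"{n_irrelevant} are needed as prior knowledge"
        )


def select_priors(
    corpus: Corpus, stage: str, seed: int, n_irrelevant: int = 10
) -> PriorSet:
    """Draw the prior knowledge: 1 relevant + ``n_irrelevant`` irrelevant.

    The irrelevant priors are drawn once per dataset from ``seed`` and are
    meant to be shared across runs; the relevant prior is varied per run
    by :func:`run_batch`.
    """
    check_feasible(corpus, stage, n_irrelevant)
    ids, labeled_idx, values = _stage_arrays(corpus, stage)
    rel_ids = [ids[i] for i, v in zip(labeled_idx, values) if v == 1]
    irr_ids = [ids[i] for i, v in zip(labeled_idx, values) if v == 0]
    rng = np.random.default_rng(seed)
    irrelevant = tuple(rng.choice(irr_ids, size=n_irrelevant, replace=False))
    relevant = str(rng.choice(rel_ids))
    return PriorSet(relevant, irrelevant, seed)


def _trace_rng(prior: PriorSet, config: SimulationConfig) -> np.random.Generator:
    # reproducible from (prior, config) alone; the relevant id enters via crc32
    return np.random.default_rng(
        [config.seed, prior.seed, zlib.crc32(prior.relevant_id.encode())]
    )


def simulate_screening(
    corpus: Corpus,
    stage: str,
    prior: PriorSet,
    config: SimulationConfig,
    features=None,
    run_index: int = 0,
    score_fn=None,
) -> ScreeningTrace:
    """Run one full prioritized-screening simulation.

    Loop: train on everything labeled so far (priors + screened), score
    the unscreened pool, reveal the true stage label of the top-scoring
    record (ties broken by an initial seeded shuffle), retrain every
    ``config.retrain_every`` labels, until the pool is exhausted.  The
    returned trace excludes the priors and is fully reproducible from
    ``(corpus, prior, config)``.

    ``score_fn(features, train_idx, train_labels, config, candidate_idx)``
    may replace the trained scorer (e.g. a random scorer for baseline
    checks).
    """
    ids, labeled_idx, values = _stage_arrays(corpus, stage)
    id_to_pos = {ids[i]: i for i in labeled_idx}
    stage_label = {ids[i]: int(v) for i, v in zip(labeled_idx, values)}

    for rid in prior.all_ids:
        if rid not in id_to_pos:
            raise ConfigurationError(f"prior id {rid!r} missing stage label {stage!r}")
    if stage_label[prior.relevant_id] != 1:
        raise ConfigurationError("relevant prior is not labeled relevant at stage")
    for rid in prior.irrelevant_ids:
        if stage_label[rid] != 0:
            raise ConfigurationError(f"irrelevant prior {rid!r} not labeled irrelevant")

    if features is None:
        features, _ = fit_features(corpus.texts())
    if score_fn is None:
        score_fn = train_and_score

    prior_pos = [id_to_pos[r] for r in prior.all_ids]
    pool_pos = np.array([i for i in labeled_idx if ids[i] not in set(prior.all_ids)], dtype=int)

    rng = _trace_rng(prior, config)
    tiebreak = np.empty(len(corpus), dtype=int)
    tiebreak[pool_pos] = rng.permutation(pool_pos.size)

    train_idx = list(prior_pos)
    train_labels = [1] + [0] * len(prior.irrelevant_ids)
    unscreened = list(pool_pos)
    ordered_ids: list[str] = []
    labels_in_order: list[int] = []

    while unscreened:
        cand = np.array(unscreened, dtype=int)
        scores = score_fn(features, train_idx, train_labels, config, cand)
        # highest score first; ties -> lowest post-shuffle index
        order = np.lexsort((tiebreak[cand], -np.asarray(scores)))
        for j in order[: config.retrain_every]:
            pos = int(cand[j])
            rid = ids[pos]
            label = stage_label[rid]
            ordered_ids.append(rid)
            labels_in_order.append(label)
            train_idx.append(pos)
            train_labels.append(label)
        taken = {int(cand[j]) for j in order[: config.retrain_every]}
        unscreened = [p for p in unscreened if p not in taken]

    return ScreeningTrace(ordered_ids, np.array(labels_in_order), prior, run_index)


def run_batch(
    corpus: Corpus,
    stage: str,
    config: SimulationConfig,
    n_runs: int | str = "all",
) -> list[ScreeningTrace]:
    """Multiple runs varying the relevant prior, sharing irrelevant priors.

    ``n_runs="all"`` runs once per relevant record.  The run order of
    relevant priors is a seeded permutation; an ``n_runs`` exceeding the
    number of relevant records is clamped with a warning.
    """
    check_feasible(corpus, stage, config.n_prior_irrelevant)
    ids, labeled_idx, values = _stage_arrays(corpus, stage)
    rel_ids = [ids[i] for i, v in zip(labeled_idx, values) if v == 1]
    irr_ids = [ids[i] for i, v in zip(labeled_idx, values) if v == 0]

    rng = np.random.default_rng(config.seed)
    shared_irrelevant = tuple(
        rng.choice(irr_ids, size=config.n_prior_irrelevant, replace=False)
    )
    rel_order = [str(r) for r in rng.permutation(rel_ids)]

    if n_runs == "all":
        chosen = rel_order
    else:
        n_runs = int(n_runs)
        if n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1 or 'all'")
        if n_runs > len(rel_order):
            warnings.warn(
                f"n_runs={n_runs} exceeds the {len(rel_order)} relevant "
                "records; clamping",
                stacklevel=2,
            )
            n_runs = len(rel_order)
        chosen = rel_order[:n_runs]

    features, _ = fit_features(corpus.texts())
    traces = []
    for run_index, rel_id in enumerate(chosen):
        prior = PriorSet(rel_id, shared_irrelevant, config.seed)
        traces.append(
            simulate_screening(
                corpus, stage, prior, config, features=features, run_index=run_index
            )
        )
    return traces


def write_trace(trace: ScreeningTrace, path) -> None:
    """Write a trace as CSV (position, record_id, label)."""
    import pandas as pd

    pd.DataFrame(
        {
            "position": np.arange(1, trace.n_pool + 1),
            "record_id": trace.ordered_ids,
            "label": trace.labels_in_order,
        }
    ).to_csv(path, index=False)


def read_trace(path) -> ScreeningTrace:
    """Read a trace CSV written by :func:`write_trace` (prior not restored)."""
    import pandas as pd

    frame = pd.read_csv(path, dtype={"record_id": str})
    return ScreeningTrace(
        list(frame["record_id"]), frame["label"].to_numpy(dtype=int)
    )
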