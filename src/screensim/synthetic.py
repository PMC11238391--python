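"""Synthetic labeled title-abstract corpora with controllable label noise.

The generator emulates the statistical structure of real screening
datasets used in guideline development: a few hundred records, low
relevance prevalence (1-25%), topic-separable text, two imperfect
title-abstract raters whose errors may be correlated, and nested
three-stage adjudication in which a methodologist re-evaluates the
raters' inclusions (historically dropping about half of them) and a
final full-text pass excludes a further fraction.

Text is a two-class unigram multinomial mixture over pseudo-words: the
relevant and irrelevant classes draw tokens from distributions whose
divergence is controlled by ``signal_strength`` (0 = indistinguishable,
``inf`` = disjoint vocabularies).  This is sufficient structure for a
bag-of-words screening model; no grammar is simulated.

Stage columns are nested by construction:
``label_fulltext <= label_methodologist <= label_clinician`` (as sets of
inclusions), with ``label_clinician`` the union (logical OR) of the two
rater columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .corpus_io import Corpus, Record
from .exceptions import CalibrationError, ConfigurationError, ValidationError


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic corpus.

    n_records
        Corpus size N (>= 20); real screening corpora run a few hundred.
    prevalence
        True-relevance probability per record, in (0, 0.5).
    vocab_size
        Number of distinct pseudo-word types.
    signal_strength
        Divergence between the relevant and irrelevant token
        distributions; 0 makes the classes indistinguishable, ``inf``
        gives disjoint vocabularies (perfectly separable).
    doc_length
        Mean abstract length in tokens (Poisson).
    rater_fp
        Per-rater probability of including an irrelevant record
        (false inclusion / over-inclusion).
    rater_fn
        Per-rater probability of excluding a relevant record.
    rater_correlation
        Probability that the two raters share one error draw on a record
        (shared-latent coupling); 0 models independently screening
        raters (the default; with the default error rates the implied
        inter-rater kappa is about 0.5), 1 makes the raters identical.
    methodologist_exclusion
        Fraction of clinician inclusions the methodologist relabels
        irrelevant; default 0.49, the over-inclusion rate observed when
        methodologists re-evaluate clinician title-abstract selections.
    fulltext_exclusion
        Further fraction of methodologist inclusions dropped at full
        text; default 0.133.
    seed
        Master seed; corpora are bitwise reproducible from the config.
    """

    n_records: int = 400
    prevalence: float = 0.05
    vocab_size: int = 150
    signal_strength: float = 3.0
    doc_length: float = 60.0
    rater_fp: float = 0.03
    rater_fn: float = 0.10
    rater_correlation: float = 0.0
    methodologist_exclusion: float = 0.49
    fulltext_exclusion: float = 0.133
    seed: int = 0
    max_retries: int = 10

    def __post_init__(self):
        if self.n_records < 20:
            raise ConfigurationError("n_records must be >= 20")
        if not 0 < self.prevalence < 0.5:
            raise ConfigurationError("prevalence must be in (0, 0.5)")
        if self.vocab_size < 6:
            raise ConfigurationError("vocab_size must be >= 6")
        if self.signal_strength < 0:
            raise ConfigurationError("signal_strength must be >= 0")
        if self.doc_length <= 0:
            raise ConfigurationError("doc_length must be > 0")
        for name in ("rater_fp", "rater_fn"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if not 0 <= self.rater_correlation <= 1:
            raise ConfigurationError("rater_correlation must be in [0, 1]")
        for name in ("methodologist_exclusion", "fulltext_exclusion"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be in [0, 1)")


def _class_distributions(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Token distributions for the relevant and irrelevant classes.

    The vocabulary splits into a relevant-signal third, an
    irrelevant-signal third and a shared remainder.  Each class mixes a
    uniform distribution over its signal block (weight s/(1+s)) with a
    uniform distribution over the whole vocabulary.
    """
    v = config.vocab_size
    third = v // 3
    s = config.signal_strength
    m = 1.0 if math.isinf(s) else s / (1.0 + s)

    base = np.full(v, 1.0 / v)
    rel = (1 - m) * base
    irr = (1 - m) * base
    rel[:third] += m / third
    irr[third : 2 * third] += m / third
    return rel / rel.sum(), irr / irr.sum()


def _render_doc(rng, dist, n_tokens: int) -> str:
    counts = rng.multinomial(n_tokens, dist)
    words = []
    for token_index in np.nonzero(counts)[0]:
        words.extend([f"w{token_index:04d}"] * counts[token_index])
    rng.shuffle(words)
    return " ".join(words)


def apply_rater_noise(
    truth: np.ndarray, config: GeneratorConfig, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Two noisy rater label vectors from the true labels.

    Each rater flips relevant -> irrelevant with probability
    ``rater_fn`` and irrelevant -> relevant with ``rater_fp``.  With
    probability ``rater_correlation`` a record's two flip decisions share
    one latent uniform draw (identical flips); otherwise they are
    independent.  Deterministic under the supplied RNG/seed.
    """
    truth = np.asarray(truth, dtype=int)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = truth.size
    p_flip = np.where(truth == 1, config.rater_fn, config.rater_fp)

    shared = rng.random(n) < config.rater_correlation
    u0 = rng.random(n)
    u1 = rng.random(n)
    u2 = rng.random(n)
    flip1 = np.where(shared, u0, u1) < p_flip
    flip2 = np.where(shared, u0, u2) < p_flip
    return (truth ^ flip1).astype(int), (truth ^ flip2).astype(int)


def _staged_exclusion(
    inclusions: np.ndarray, truth: np.ndarray, fraction: float, rng
) -> np.ndarray:
    """Drop ``fraction`` of current inclusions, false positives first.

    Removal targets are chosen uniformly among the stage's false
    positives; only when those are exhausted does the exclusion hit true
    positives (modeling adjudicator error on an over-inclusive input).
    """
    out = inclusions.copy()
    included = np.flatnonzero(inclusions == 1)
    n_remove = int(round(fraction * included.size))
    if n_remove == 0:
        return out
    false_pos = included[truth[included] == 0]
    true_pos = included[truth[included] == 1]
    order = np.concatenate([rng.permutation(false_pos), rng.permutation(true_pos)])
    out[order[:n_remove].astype(int)] = 0
    return out


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate one synthetic labeled corpus.

    Returns a :class:`~screensim.corpus_io.Corpus` with columns
    ``truth``, ``label_clinician1``, ``label_clinician2``,
    ``label_clinician`` (OR of the raters), ``label_methodologist`` and
    ``label_fulltext``, nested by construction.  Configurations whose
    truth draw yields fewer than two relevant records are redrawn from a
    child seed, up to ``max_retries`` times.
    """
    rel_dist, irr_dist = _class_distributions(config)
    seed_seq = np.random.SeedSequence(config.seed)

    for attempt, child in enumerate(seed_seq.spawn(config.max_retries)):
        rng = np.random.default_rng(child)
        truth = (rng.random(config.n_records) < config.prevalence).astype(int)
        if truth.sum() >= 2:
            break
    else:
        raise ValidationError(
            f"could not draw >= 2 relevant records in {config.max_retries} "
            f"attempts (N={config.n_records}, prevalence={config.prevalence})"
        )

    rater1, rater2 = apply_rater_noise(truth, config, rng)
    clinician = (rater1 | rater2).astype(int)
    methodologist = _staged_exclusion(
        clinician, truth, config.methodologist_exclusion, rng
    )
    fulltext = _staged_exclusion(methodologist, truth, config.fulltext_exclusion, rng)

    records = []
    for i in range(config.n_records):
        dist = rel_dist if truth[i] else irr_dist
        title = _render_doc(rng, dist, 6)
        n_tokens = max(3, int(rng.poisson(config.doc_length)))
        abstract = _render_doc(rng, dist, n_tokens)
        records.append(
            Record(
                record_id=f"r{i:04d}",
                title=title,
                abstract=abstract,
                labels={
                    "truth": int(truth[i]),
                    "label_clinician1": int(rater1[i]),
                    "label_clinician2": int(rater2[i]),
                    "label_clinician": int(clinician[i]),
                    "label_methodologist": int(methodologist[i]),
                    "label_fulltext": int(fulltext[i]),
                },
            )
        )
    columns = [
        "truth",
        "label_clinician1",
        "label_clinician2",
        "label_clinician",
        "label_methodologist",
        "label_fulltext",
    ]
    return Corpus(records, columns, source=f"synthetic(seed={config.seed})")


def expected_kappa(
    pi: float, fp: float, fn: float, rho: float = 0.0
) -> float:
    """Closed-form Cohen's kappa of two coupled noisy raters.

    Under the shared-latent coupling of :func:`apply_rater_noise`, the
    probability that both raters flip a record of flip-probability ``p``
    is ``rho*p + (1-rho)*p**2``; discordance has probability
    ``2*(1-rho)*p*(1-p)``.  Mixing over the two truth classes gives the
    population 2x2 table, from which kappa follows.
    """

    def cells(p):
        both = rho * p + (1 - rho) * p * p
        neither = rho * (1 - p) + (1 - rho) * (1 - p) ** 2
        one = (1 - rho) * p * (1 - p)
        return both, neither, one

    both_fn, neither_fn, one_fn = cells(fn)
    both_fp, neither_fp, one_fp = cells(fp)
    # a = both say relevant, d = both say irrelevant, b/c = discordant
    a = pi * neither_fn + (1 - pi) * both_fp
    d = pi * both_fn + (1 - pi) * neither_fp
    b = pi * one_fn + (1 - pi) * one_fp
    c = b
    p_o = a + d
    pa1 = a + b
    pb1 = a + c
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0:
        return math.nan
    return (p_o - p_e) / (1 - p_e)


def _bisect(func, lo: float, hi: float, tol: float = 1e-10) -> float:
    f_lo = func(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = func(mid)
        if abs(f_mid) < tol:
            return mid
        if (f_lo < 0) == (f_mid < 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def calibrate_to_kappa(
    target_kappa: float, pi: float, fp: float
) -> dict[str, float]:
    """Find (rater_correlation, rater_fn) achieving a target kappa.

    Searches the analytic kappa expression: kappa rises monotonically
    with the rater coupling ``rho`` (reaching 1 as the raters become
    identical) and falls as ``rater_fn`` grows.  If the target lies below
    the independent-rater kappa at the default ``fn = fp``, the miss rate
    is raised instead; targets below the attainable floor raise
    :class:`CalibrationError` carrying the attainable range.
    """
    if not -1 < target_kappa < 1:
        raise CalibrationError(
            f"target kappa {target_kappa} outside the open interval (-1, 1); "
            "kappa = 1 requires error-free identical raters",
            attainable_range=(-1.0, 1.0),
        )
    if not 0 < pi < 1:
        raise ConfigurationError("pi must be in (0, 1)")
    if not 0 <= fp < 1:
        raise ConfigurationError("fp must be in [0, 1)")

    fn_grid = np.linspace(max(fp, 1e-6), 0.999, 400)
    kappa0 = np.array([expected_kappa(pi, fp, f, 0.0) for f in fn_grid])
    floor = float(np.nanmin(kappa0))
    if target_kappa < floor:
        raise CalibrationError(
            f"target kappa {target_kappa} unattainable with pi={pi}, fp={fp}",
            attainable_range=(floor, 1.0),
        )

    fn_default = max(fp, 1e-6)
    k_independent = expected_kappa(pi, fp, fn_default, 0.0)
    if target_kappa >= k_independent:
        fn = fn_default
        rho = _bisect(lambda r: expected_kappa(pi, fp, fn, r) - target_kappa, 0.0, 1.0)
    else:
        rho = 0.0
        # kappa0 decreases in fn until raters saturate; bisect on the
        # first bracketing segment of the grid
        idx = int(np.argmax(kappa0 <= target_kappa))
        lo = fn_grid[max(idx - 1, 0)]
        hi = fn_grid[idx]
        fn = _bisect(lambda f: expected_kappa(pi, fp, f, 0.0) - target_kappa, lo, hi)
    return {"rater_correlation": float(rho), "rater_fn": float(fn)}


def separable_config(**overrides) -> GeneratorConfig:
    """Convenience: a noise-free, perfectly separable corpus config."""
    base = GeneratorConfig(
        signal_strength=math.inf,
        rater_fp=0.0,
        rater_fn=0.0,
        methodologist_exclusion=0.0,
        fulltext_exclusion=0.0,
    )
    return replace(base, **overrides)
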