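"""Inter-rater reliability of manual screening: Cohen's kappa.

Two raters independently label each record relevant/irrelevant; kappa is
the chance-corrected agreement computed from the 2x2 contingency table.
Pairs in which either label is missing are dropped listwise before the
table is built, and the number of dropped pairs is reported.  When both
raters are constant (chance agreement equals 1) kappa is undefined and an
explicit error is raised rather than reporting a fabricated value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .corpus_io import Corpus
from .exceptions import ConfigurationError, UndefinedKappaError


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its observed/chance agreement and contingency.

    ``contingency`` is (a, b, c, d): both-relevant, A-only, B-only,
    both-irrelevant counts over the jointly labeled pairs.
    """

    kappa: float
    p_o: float
    p_e: float
    contingency: tuple[int, int, int, int]
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return sum(self.contingency)


def _to_float(labels) -> np.ndarray:
    return np.array(
        [np.nan if v is None else float(v) for v in labels], dtype=float
    )


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Cohen's kappa between two binary label vectors.

    Pairs with a missing label on either side are dropped listwise.
    Raises :class:`UndefinedKappaError` when both raters are constant
    (p_e = 1) and :class:`ConfigurationError` when no jointly labeled
    pair remains.
    """
    a = _to_float(labels_a)
    b = _to_float(labels_b)
    if a.shape != b.shape:
        raise ConfigurationError(
            f"label vectors differ in length: {a.size} vs {b.size}"
        )
    keep = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int((~keep).sum())
    a, b = a[keep].astype(int), b[keep].astype(int)
    if a.size == 0:
        raise ConfigurationError("no jointly labeled pairs")

    cell_a = int(np.sum((a == 1) & (b == 1)))
    cell_b = int(np.sum((a == 1) & (b == 0)))
    cell_c = int(np.sum((a == 0) & (b == 1)))
    cell_d = int(np.sum((a == 0) & (b == 0)))
    contingency = (cell_a, cell_b, cell_c, cell_d)
    n = a.size

    p_o = (cell_a + cell_d) / n
    pa1 = (cell_a + cell_b) / n
    pb1 = (cell_a + cell_c) / n
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0:
        raise UndefinedKappaError(
            "kappa undefined: both raters constant (chance agreement = 1)",
            contingency=contingency,
        )
    kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(kappa, p_o, p_e, contingency, n_dropped)


def kappa_table(
    corpora: list[Corpus], rater_columns: tuple[str, str]
) -> tuple[list[float | None], float]:
    """Per-corpus kappa plus the unweighted mean over defined values.

    Corpora where kappa is undefined contribute ``None`` and are excluded
    from the mean, mirroring how degenerate datasets are reported as NA
    rather than folded in as zero agreement.
    """
    col_a, col_b = rater_columns
    values: list[float | None] = []
    for corpus in corpora:
        for col in (col_a, col_b):
            if all(v is None for v in corpus.labels(col)):
                raise ConfigurationError(
                    f"corpus {corpus.source!r} has no labels in column {col!r}"
                )
        try:
            values.append(cohens_kappa(corpus.labels(col_a), corpus.labels(col_b)).kappa)
        except UndefinedKappaError:
            values.append(None)
    defined = [v for v in values if v is not None]
    mean = float(np.mean(defined)) if defined else math.nan
    return values, mean
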