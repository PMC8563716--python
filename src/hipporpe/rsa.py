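"""Representational similarity analysis of the hidden subfield layers.

A layer's representation of the task is summarized by the 10x10 matrix of
Pearson correlations between the settled activation patterns the ten
stimuli evoke in it.  Derived quantities:

* early-minus-delayed *difference matrices* expose where the two training
  schedules sculpt representations differently;
* the mean *intercategory similarity* (the 25 cells pairing a category-A
  with a category-B stimulus) measures blurring of the category boundary;
* the *category representational difference* (CRD) of an exception is the
  normalized contrast between its mean within-category and
  between-category correlation,

      CRD = ((1 + rho_intra) - (1 + rho_inter))
            / ((1 + rho_intra) + (1 + rho_inter)),

  positive when the exception sits representationally with its own
  category;
* per-batch CRD and intercategory-similarity samples from the two
  conditions are compared with a two-sided Wilcoxon rank-sum test
  (statistic reported on the Mann-Whitney U convention of the first
  sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .stimuli import CANONICAL_ORDER

__all__ = [
    "SimilarityMatrix",
    "CRDRecord",
    "RankSumResult",
    "rsa_matrix",
    "condition_difference",
    "intercategory_similarity",
    "intracategory_similarity",
    "crd",
    "ranksum_compare",
]

_CATEGORY = np.array([0] * 5 + [1] * 5)  # canonical order: A block then B block


@dataclass(frozen=True)
class SimilarityMatrix:
    """10x10 Pearson correlation matrix for one subfield/condition/time.

    Stimulus order is the canonical one (category A then B, each
    P, P, R, R, E).  Cells whose correlation is undefined (a constant
    activation vector) are NaN and excluded from downstream means.
    """

    values: np.ndarray
    subfield: str = ""
    condition: str = ""
    checkpoint: int | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (10, 10):
            raise ValueError("similarity matrix must be 10x10")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite.T], atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1.0 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=CANONICAL_ORDER, columns=CANONICAL_ORDER).to_csv(path)


@dataclass(frozen=True)
class CRDRecord:
    exception_id: str
    rho_intra: float
    rho_inter: float
    crd: float
    subfield: str = ""
    condition: str = ""
    batch: int | None = None


@dataclass(frozen=True)
class RankSumResult:
    statistic_W: float
    p_value: float
    n_early: int
    n_delayed: int
    medians: tuple[float, float]


def rsa_matrix(activations: np.ndarray, subfield: str = "", condition: str = "",
               checkpoint: int | None = None) -> SimilarityMatrix:
    """Pearson correlation matrix of ten stimulus activation patterns.

    ``activations`` has shape (10, n_units), rows in canonical order.
    Constant rows make a correlation undefined; those cells are set to
    NaN with a warning rather than silently zeroed.
    """
    acts = np.asarray(activations, dtype=float)
    if acts.ndim != 2 or acts.shape[0] != 10 or acts.shape[1] < 2:
        raise ValueError("need a (10, n_units>=2) activation array")
    sd = acts.std(axis=1)
    # tolerance: a nominally constant vector has sd at rounding level
    constant = sd <= 1e-12 * np.maximum(1.0, np.abs(acts).max(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(acts)
    np.fill_diagonal(corr, 1.0)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant activation vector(s); "
            "their correlations are undefined and flagged as NaN",
            RuntimeWarning,
        )
        corr[constant, :] = np.nan
        corr[:, constant] = np.nan
        np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return SimilarityMatrix(values=corr, subfield=subfield, condition=condition,
                            checkpoint=checkpoint)


def condition_difference(early: SimilarityMatrix, delayed: SimilarityMatrix) -> np.ndarray:
    """Elementwise early-minus-delayed similarity difference."""
    if early.subfield != delayed.subfield:
        raise ValueError("difference requires matching subfields")
    return early.values - delayed.values


def _cross_mask() -> np.ndarray:
    return _CATEGORY[:, None] != _CATEGORY[None, :]


def intercategory_similarity(matrix: SimilarityMatrix) -> float:
    """Mean of the 25 cells pairing a category-A with a category-B
    stimulus (NaN cells excluded)."""
    cells = matrix.values[np.triu(_cross_mask())]
    return float(np.nanmean(cells))


def intracategory_similarity(matrix: SimilarityMatrix) -> float:
    """Mean within-category off-diagonal similarity (NaN cells excluded)."""
    same = ~_cross_mask()
    np.fill_diagonal(same, False)
    return float(np.nanmean(matrix.values[np.triu(same)]))


def crd(matrix: SimilarityMatrix, exception_id: str, batch: int | None = None) -> CRDRecord:
    """Category representational difference of one exception.

    ``rho_intra`` averages the exception's correlation with the four
    other members of its category (self excluded); ``rho_inter`` with the
    five opposite-category stimuli.
    """
    if exception_id not in ("EA", "EB"):
        raise ValueError("exception_id must be 'EA' or 'EB'")
    i = CANONICAL_ORDER.index(exception_id)
    own = _CATEGORY == _CATEGORY[i]
    own[i] = False
    rho_intra = float(np.nanmean(matrix.values[i, own]))
    rho_inter = float(np.nanmean(matrix.values[i, ~own & (np.arange(10) != i)]))
    denom = (1 + rho_intra) + (1 + rho_inter)
    if denom <= 0:
        raise ZeroDivisionError("degenerate CRD: both mean correlations are -1")
    value = ((1 + rho_intra) - (1 + rho_inter)) / denom
    return CRDRecord(exception_id=exception_id, rho_intra=rho_intra, rho_inter=rho_inter,
                     crd=value, subfield=matrix.subfield, condition=matrix.condition,
                     batch=batch)


def ranksum_compare(values_early: Sequence[float], values_delayed: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum comparison of per-batch scalars.

    The statistic is the Mann-Whitney U of the early sample (the
    convention under which two n=500 samples range over 0..250,000).
    All-tied samples yield p = 1 with a warning.
    """
    x = np.asarray(values_early, dtype=float)
    y = np.asarray(values_delayed, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        warnings.warn("all observations tied; rank-sum test is uninformative", RuntimeWarning)
        return RankSumResult(statistic_W=x.size * y.size / 2.0, p_value=1.0,
                             n_early=x.size, n_delayed=y.size,
                             medians=(float(np.median(x)), float(np.median(y))))
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return RankSumResult(statistic_W=float(res.statistic), p_value=float(res.pvalue),
                         n_early=x.size, n_delayed=y.size,
                         medians=(float(np.median(x)), float(np.median(y))))
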