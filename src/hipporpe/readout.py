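"""Luce-choice accuracy from the EC_out category units.

The network's categorization response on a test trial is read from the
two EC_out units coding the category dimension.  Accuracy is the Luce
choice ratio of cosine similarities between that 2-vector and the target
versus nontarget one-hot codes:

    accuracy(x) = cos(x, target) / (cos(x, target) + cos(x, nontarget))

Because the target and nontarget are complementary one-hots and the
readout is nonnegative, this reduces to x_target / (x_target +
x_nontarget); both forms are computed and the reduction is exercised as a
test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stimuli import StimulusSet

__all__ = [
    "CategoryReadout",
    "ZeroReadoutError",
    "luce_accuracy",
    "snapshot_accuracy",
    "aggregate_accuracy",
]


class ZeroReadoutError(ValueError):
    """Raised when both category units are exactly zero, leaving the
    choice undefined.  Callers may opt into mapping this to 0.5 via
    ``luce_accuracy(..., zero_readout='half')`` — the default refuses, so
    an untrained-network pathology cannot masquerade as chance
    performance."""


@dataclass(frozen=True)
class CategoryReadout:
    """EC_out activation on the category unit pair plus its target code."""

    x_d5: tuple[float, float]
    target_d5: tuple[int, int]

    def __post_init__(self) -> None:
        if sorted(self.target_d5) != [0, 1]:
            raise ValueError("target must be a one-hot pair")
        if not all(0.0 <= v <= 1.0 for v in self.x_d5):
            raise ValueError("readout values must lie in [0, 1]")

    @property
    def nontarget_d5(self) -> tuple[int, int]:
        return (self.target_d5[1], self.target_d5[0])


def luce_accuracy(readout: CategoryReadout, zero_readout: str = "error") -> float:
    """Luce-choice accuracy of one category readout.

    Computed from the explicit cosine ratio.  A zero readout vector
    raises :class:`ZeroReadoutError` unless ``zero_readout='half'``.
    """
    x = np.asarray(readout.x_d5, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0.0:
        if zero_readout == "half":
            return 0.5
        raise ZeroReadoutError("both category units are zero; accuracy undefined")
    t = np.asarray(readout.target_d5, dtype=float)
    nt = np.asarray(readout.nontarget_d5, dtype=float)
    cos_t = float(x @ t) / norm
    cos_nt = float(x @ nt) / norm
    return cos_t / (cos_t + cos_nt)


def snapshot_accuracy(snapshot, stimulus_set: StimulusSet,
                      zero_readout: str = "error") -> dict[str, float]:
    """Per-stimulus Luce accuracy from one test snapshot's EC_out rows."""
    from .stimuli import CANONICAL_ORDER

    out = snapshot.activations["EC_out"]
    acc = {}
    for i, sid in enumerate(CANONICAL_ORDER):
        s = stimulus_set[sid]
        target = (1, 0) if s.features.d5 == 0 else (0, 1)
        x = np.clip(out[i, 8:10], 0.0, 1.0)
        acc[sid] = luce_accuracy(CategoryReadout((float(x[0]), float(x[1])), target),
                                 zero_readout=zero_readout)
    return acc


def aggregate_accuracy(records: pd.DataFrame, by: Sequence[str] = ("condition", "role"),
                       n_boot: int = 10_000, seed: int = 0,
                       ci: float = 0.95) -> pd.DataFrame:
    """Bootstrap summary of accuracy records.

    Within each group, batch means are computed first; the summary is the
    median of bootstrapped means across batches with a percentile
    confidence interval.  Groups with no rows are omitted.

    Returns a frame with the grouping columns plus ``n_batches``,
    ``median_boot_mean``, ``ci_low``, ``ci_high``.
    """
    if records.empty:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for keys, group in records.groupby(list(by), sort=True, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        batch_means = group.groupby("batch", observed=True)["accuracy"].mean().to_numpy()
        n = batch_means.size
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = batch_means[idx].mean(axis=1)
        rows.append(
            (*keys, n, float(np.median(boot_means)),
             float(np.quantile(boot_means, alpha)), float(np.quantile(boot_means, 1 - alpha)))
        )
    return pd.DataFrame(rows, columns=[*by, "n_batches", "median_boot_mean", "ci_low", "ci_high"])
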