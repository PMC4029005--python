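"""Amplicon (16S tag) profile computations.

Relative abundance per sample, cumulative dominance of a named taxon set,
and richness normalized by random subsampling to a common depth
(rarefaction without replacement).  The exact expectation of subsampled
richness under the hypergeometric model,

    E[S] = sum_t (1 - C(N - n_t, d) / C(N, d)),

is provided alongside the Monte-Carlo estimator.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ParameterError, UndefinedValueError

__all__ = [
    "relative_abundance",
    "cumulative_share",
    "CumulativeShare",
    "subsampled_richness",
    "RichnessResult",
    "expected_richness",
]


def relative_abundance(counts):
    """Per-sample fractions: count / sample total.

    Accepts a Series (one sample, taxa index) or a DataFrame
    (samples x taxa); any sample with a zero total is an error.
    """
    if isinstance(counts, Mapping):
        counts = pd.Series(counts, dtype=float)
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise UndefinedValueError("sample has zero total count")
        if (counts < 0).any():
            raise ParameterError("counts must be nonnegative")
        return counts / total
    frame = pd.DataFrame(counts).astype(float)
    if (frame < 0).to_numpy().any():
        raise ParameterError("counts must be nonnegative")
    totals = frame.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise UndefinedValueError(f"samples with zero total count: {bad}")
    return frame.div(totals, axis=0)


class CumulativeShare(NamedTuple):
    percent: int
    exact: float


def cumulative_share(fractions, taxa: Iterable[str]) -> CumulativeShare:
    """Summed share of the named taxa, as a rounded integer percent (the
    conventional reporting style) plus the unrounded value.

    ``fractions`` maps taxa to relative abundances in [0, 1].
    """
    if isinstance(fractions, Mapping):
        fractions = pd.Series(fractions, dtype=float)
    taxa = list(taxa)
    missing = [t for t in taxa if t not in fractions.index]
    if missing:
        raise KeyError(f"unknown taxa: {missing}")
    exact = float(fractions.loc[taxa].sum() * 100.0)
    return CumulativeShare(percent=int(round(exact)), exact=exact)


class RichnessResult(NamedTuple):
    mean: float
    sd: float
    values: np.ndarray


def subsampled_richness(
    counts, depth: int, seed: int = 0, reps: int = 100
) -> RichnessResult:
    """Observed richness after drawing ``depth`` reads without replacement.

    Richness is the number of taxa with at least one drawn read; repeated
    ``reps`` times, with the mean and standard deviation reported.
    """
    if isinstance(counts, Mapping):
        counts = pd.Series(counts)
    arr = np.asarray(counts, dtype=np.int64)
    if (arr < 0).any():
        raise ParameterError("counts must be nonnegative")
    total = int(arr.sum())
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    if depth > total:
        raise ParameterError(f"depth {depth} exceeds sample total {total}")
    if reps < 1:
        raise ParameterError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty(reps, dtype=np.int64)
    for r in range(reps):
        draw = rng.multivariate_hypergeometric(arr, depth)
        values[r] = int((draw > 0).sum())
    return RichnessResult(
        mean=float(values.mean()), sd=float(values.std(ddof=1)) if reps > 1 else 0.0,
        values=values,
    )


def expected_richness(counts, depth: int) -> float:
    """Exact expectation of subsampled richness under sampling without
    replacement (hypergeometric inclusion probabilities)."""
    if isinstance(counts, Mapping):
        counts = pd.Series(counts)
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    if depth < 1 or depth > total:
        raise ParameterError("depth must lie in 1..sample total")
    arr = arr[arr > 0]
    # P(taxon t unseen) = C(N - n_t, d) / C(N, d) = Hypergeom pmf at 0
    p_unseen = hypergeom.pmf(0, total, arr, depth)
    return float(np.sum(1.0 - p_unseen))
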