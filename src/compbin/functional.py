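"""Functional-category (COG/KEGG-style) profile comparisons.

Per-sample category hit counts are normalized by the sample's total hits;
profiles across metagenomes are compared by PCA (covariance on the
proportions, no further standardization by default), nearest-neighbor
grouping in proportion space, and two-profile comparison tables with a
Spearman rank-concordance statistic.

Published tables often print only rounded percent columns plus the hit
counts of one profile.  ``implied_total`` inverts a single (hits, percent)
anchor; ``consistent_total`` recovers the interval of totals consistent
with the rounding of a whole printed column and returns its midpoint,
which is the right tool when the anchor alone is too coarse.
"""

from __future__ import annotations

import decimal
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .binning import Embedding, pca_embed
from .errors import ParameterError, UndefinedValueError

__all__ = [
    "normalize_categories",
    "percent_view",
    "round_half_up",
    "profile_pca",
    "nearest_profile",
    "NearestProfile",
    "compare_category_tables",
    "implied_total",
    "consistent_total",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with halves away from zero, as printed tables use.

    Values are first quantized at 1e-9 so that float representation dust
    (e.g. 5.949999...9993 for 5.95) does not flip the rounding.
    """
    q = decimal.Decimal(repr(round(float(x), 9)))
    exp = decimal.Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=decimal.ROUND_HALF_UP))


def normalize_categories(counts):
    """Per-sample proportions: hits in a category / total hits.

    Accepts a Series (one sample) or DataFrame (samples x categories).
    """
    if isinstance(counts, Mapping):
        counts = pd.Series(counts, dtype=float)
    if isinstance(counts, pd.Series):
        total = counts.sum()
        if total <= 0:
            raise UndefinedValueError("sample has zero total hits")
        if (counts < 0).any():
            raise ParameterError("hit counts must be nonnegative")
        return counts / total
    frame = pd.DataFrame(counts).astype(float)
    if (frame < 0).to_numpy().any():
        raise ParameterError("hit counts must be nonnegative")
    totals = frame.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise UndefinedValueError(f"samples with zero total hits: {bad}")
    return frame.div(totals, axis=0)


def percent_view(proportions, decimals: int = 1):
    """Proportions as percent, rounded half-up at ``decimals`` places."""
    if isinstance(proportions, Mapping):
        proportions = pd.Series(proportions, dtype=float)
    if isinstance(proportions, pd.Series):
        return proportions.map(lambda v: round_half_up(100.0 * v, decimals))
    return pd.DataFrame(proportions).apply(
        lambda col: col.map(lambda v: round_half_up(100.0 * v, decimals))
    )


def profile_pca(proportions, n_components: int | None = None,
                standardize: bool = False) -> Embedding:
    """PCA of samples over their category proportions.

    Covariance PCA on the proportions by default; ``standardize`` switches
    to per-category z-scoring first (correlation-style PCA).
    """
    frame = pd.DataFrame(proportions).astype(float)
    if frame.shape[0] < 3:
        raise ParameterError("profile PCA requires at least 3 samples")
    values = frame.to_numpy()
    if standardize:
        sd = values.std(axis=0)
        sd[sd <= 1e-12] = 1.0
        values = (values - values.mean(axis=0)) / sd
    emb = pca_embed(values, n_components=n_components)
    emb.contig_ids = [str(s) for s in frame.index]
    return emb


class NearestProfile(NamedTuple):
    nearest: str
    distance: float
    ranking: pd.DataFrame


def nearest_profile(data, query: str) -> NearestProfile:
    """Nearest other sample to ``query`` by Euclidean distance, with the
    full ranked distance table; ties break lexicographically."""
    if isinstance(data, Embedding):
        frame = pd.DataFrame(data.coordinates, index=data.contig_ids)
    else:
        frame = pd.DataFrame(data).astype(float)
    if frame.shape[0] < 2:
        raise ParameterError("need at least 2 samples")
    if query not in frame.index:
        raise KeyError(f"unknown sample {query!r}")
    others = frame.drop(index=query)
    dists = cdist(
        frame.loc[[query]].to_numpy(), others.to_numpy(), metric="euclidean"
    )[0]
    ranking = pd.DataFrame({"sample": others.index, "distance": dists})
    ranking = ranking.sort_values(
        ["distance", "sample"], kind="stable"
    ).reset_index(drop=True)
    return NearestProfile(
        nearest=str(ranking.iloc[0]["sample"]),
        distance=float(ranking.iloc[0]["distance"]),
        ranking=ranking,
    )


def compare_category_tables(counts_a, percent_b) -> tuple[pd.DataFrame, float]:
    """Two-profile comparison table in the style of published COG tables.

    ``counts_a`` are one profile's raw hit counts; ``percent_b`` the other
    profile's printed percent column.  Rows are the shared categories with
    A's hits, A's percent (normalized, 1 dp) and B's percent; the second
    return value is the Spearman rank correlation between the two percent
    columns.
    """
    counts_a = pd.Series(counts_a, dtype=float)
    percent_b = pd.Series(percent_b, dtype=float)
    shared = [c for c in counts_a.index if c in percent_b.index]
    if not shared:
        raise KeyError("no shared categories between the two profiles")
    props = normalize_categories(counts_a.loc[shared])
    table = pd.DataFrame(
        {
            "hits_a": counts_a.loc[shared].astype(int),
            "percent_a": percent_view(props),
            "percent_a_exact": 100.0 * props,
            "percent_b": percent_b.loc[shared],
        }
    )
    rho = float(spearmanr(table["percent_a"], table["percent_b"]).statistic)
    return table, rho


def implied_total(hits: float, percent: float) -> float:
    """Total hit count implied by a single (hits, printed percent) anchor."""
    if percent <= 0 or hits <= 0:
        raise ParameterError("hits and percent must be positive")
    return 100.0 * hits / percent


def consistent_total(
    hits: Sequence[float], percents: Sequence[float], decimals: int = 1
) -> float:
    """Total hit count consistent with a whole printed percent column.

    Each printed percent p_i constrains the true total T to the interval
    where 100*h_i/T rounds to p_i at ``decimals`` places; the midpoint of
    the intersection of all row intervals is returned.  Raises
    ParameterError if the printed column is internally inconsistent.
    """
    hits = np.asarray(hits, dtype=float)
    percents = np.asarray(percents, dtype=float)
    if hits.shape != percents.shape or hits.size == 0:
        raise ParameterError("hits and percents must be equal-length, non-empty")
    if (hits <= 0).any() or (percents <= 0).any():
        raise ParameterError("hits and percents must be positive")
    half = 0.5 * 10.0**-decimals
    lo = float(np.max(100.0 * hits / (percents + half)))
    hi = float(np.min(100.0 * hits / (percents - half)))
    if lo > hi:
        raise ParameterError("printed percent column is internally inconsistent")
    return 0.5 * (lo + hi)
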