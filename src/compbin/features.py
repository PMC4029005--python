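"""Nucleotide-composition features for contig binning.

Composition-based binning rests on the observation that each genome carries
a characteristic oligonucleotide usage signature: GC content plus the
frequencies of short k-mers (here k = 2..5) are similar across fragments of
one genome and differ between genomes.  This module computes those features
per contig and assembles them into a contigs x features matrix, optionally
z-scored per column so that GC (a percentage-scale quantity) and k-mer
frequencies (each <= 1) contribute comparably to Euclidean distances.

Windows containing any non-ACGT base are skipped rather than the whole
contig being rejected, so sequences with ambiguity codes remain usable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, ParameterError, UndefinedValueError

__all__ = [
    "Contig",
    "FeatureMatrix",
    "gc_fraction",
    "kmer_names",
    "kmer_frequencies",
    "composition_matrix",
    "normalize_features",
    "reverse_complement",
]

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# byte -> base code lookup; -1 marks anything outside A/C/G/T (either case)
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass
class Contig:
    """An assembled sequence with optional truth label and coverage."""

    id: str
    seq: str
    source: str | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ParameterError("contig id must be non-empty")
        if not self.seq:
            raise ParameterError(f"contig {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to base codes 0..3; non-ACGT positions become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); ambiguous bases are excluded entirely.

    Raises :class:`UndefinedValueError` if the sequence contains no
    unambiguous base.
    """
    if not seq:
        raise UndefinedValueError("empty sequence has no GC fraction")
    codes = _encode(seq)
    valid = codes >= 0
    denom = int(valid.sum())
    if denom == 0:
        raise UndefinedValueError("sequence contains no A/C/G/T bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / denom


def _canonical_index(k: int) -> tuple[list[str], np.ndarray]:
    """Canonical k-mer names and a map from k-mer code to canonical column.

    The canonical representative of a k-mer is the lexicographic minimum of
    the k-mer and its reverse complement.
    """
    names: list[str] = []
    col_of: dict[str, int] = {}
    mapping = np.empty(4**k, dtype=np.int64)
    for code, kmer in enumerate(_all_kmers(k)):
        canon = min(kmer, reverse_complement(kmer))
        if canon not in col_of:
            col_of[canon] = len(names)
            names.append(canon)
        mapping[code] = col_of[canon]
    return names, mapping


def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


def kmer_names(k: int, strand_mode: str = "single") -> list[str]:
    """Feature names for k-mers in fixed lexicographic order.

    ``single`` lists all 4**k k-mers; ``combined`` lists the canonical
    (reverse-complement-collapsed) set.
    """
    _check_strand_mode(strand_mode)
    if strand_mode == "single":
        return _all_kmers(k)
    return _canonical_index(k)[0]


def _check_strand_mode(strand_mode: str) -> None:
    if strand_mode not in ("single", "combined"):
        raise ParameterError(
            f"strand_mode must be 'single' or 'combined', got {strand_mode!r}"
        )


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Counts over the 4**k k-mer codes from sliding windows; windows with
    any non-ACGT base are skipped."""
    codes = _encode(seq)
    n = codes.size
    if n < k:
        raise UndefinedValueError(f"sequence shorter than k={k}")
    valid = codes >= 0
    nwin = n - k + 1
    window_code = np.zeros(nwin, dtype=np.int64)
    window_ok = np.ones(nwin, dtype=bool)
    safe = np.where(valid, codes, 0)
    for j in range(k):
        window_code = window_code * 4 + safe[j : j + nwin]
        window_ok &= valid[j : j + nwin]
    return np.bincount(window_code[window_ok], minlength=4**k)


def kmer_frequencies(seq: str, k: int, strand_mode: str = "single") -> dict[str, float]:
    """Sliding-window k-mer frequencies, summing to 1 over valid windows.

    ``combined`` adds the counts of each k-mer's reverse complement before
    normalizing, collapsing the table to the canonical k-mer set.
    """
    if not 2 <= k <= 5:
        raise ParameterError(f"k must be in 2..5, got {k}")
    _check_strand_mode(strand_mode)
    counts = _kmer_counts(seq, k)
    total = counts.sum()
    if total == 0:
        raise UndefinedValueError("no window free of ambiguous bases")
    if strand_mode == "single":
        freqs = counts / total
        return dict(zip(_all_kmers(k), freqs))
    names, mapping = _canonical_index(k)
    canon = np.zeros(len(names))
    # forward counts plus reverse-complement counts, folded onto canonical set
    rc_perm = _rc_permutation(k)
    folded = counts + counts[rc_perm]
    np.add.at(canon, mapping, folded)
    canon = canon / canon.sum()
    return dict(zip(names, canon))


def _rc_permutation(k: int) -> np.ndarray:
    kmers = _all_kmers(k)
    index = {kmer: i for i, kmer in enumerate(kmers)}
    return np.array([index[reverse_complement(km)] for km in kmers], dtype=np.int64)


@dataclass
class FeatureMatrix:
    """Contigs x composition-features matrix.

    ``feature_names`` starts with ``gc`` (when included) followed by k-mer
    names for each k in ascending order.  ``normalized`` marks a per-column
    z-scored view; ``constant_columns`` lists columns that had zero variance
    at normalization time (their z-scores are set to 0).
    """

    contig_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    normalized: bool = False
    constant_columns: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.contig_ids), len(self.feature_names)):
            raise ParameterError(
                "feature matrix shape does not match ids x feature names"
            )

    @property
    def n_contigs(self) -> int:
        return len(self.contig_ids)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.contig_ids, columns=self.feature_names
        )


def composition_matrix(
    contigs: Iterable[Contig],
    ks: Sequence[int] = (2, 3, 4, 5),
    min_len: int = 1000,
    strand_mode: str = "single",
    include_gc: bool = True,
) -> FeatureMatrix:
    """Raw composition matrix: GC plus k-mer frequency blocks per contig.

    Contigs shorter than ``min_len`` are excluded and reported in
    ``excluded``.  Within each k block the row sums to 1.
    """
    ks = sorted(ks)
    if not ks or not all(2 <= k <= 5 for k in ks):
        raise ParameterError(f"ks must be a non-empty subset of 2..5, got {ks}")
    if min_len < max(ks):
        raise ParameterError("min_len must be at least the largest k")
    _check_strand_mode(strand_mode)

    names: list[str] = (["gc"] if include_gc else [])
    for k in ks:
        names.extend(kmer_names(k, strand_mode))

    kept: list[Contig] = []
    excluded: list[str] = []
    for contig in contigs:
        if contig.length >= min_len:
            kept.append(contig)
        else:
            excluded.append(contig.id)
    if not kept:
        raise EmptyInputError(f"no contig of length >= {min_len}")

    rows = np.empty((len(kept), len(names)))
    for i, contig in enumerate(kept):
        parts: list[np.ndarray] = []
        if include_gc:
            parts.append(np.array([gc_fraction(contig.seq)]))
        for k in ks:
            freqs = kmer_frequencies(contig.seq, k, strand_mode)
            parts.append(np.fromiter(freqs.values(), dtype=float))
        rows[i] = np.concatenate(parts)

    return FeatureMatrix(
        contig_ids=[c.id for c in kept],
        feature_names=names,
        values=rows,
        normalized=False,
        excluded=excluded,
    )


def normalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-column z-score: (x - mean) / sd.  Constant columns become 0 and
    are flagged.  Idempotent up to floating-point noise."""
    if fm.n_contigs < 2:
        raise ParameterError("normalization requires at least 2 contigs")
    values = fm.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    constant = sd <= 1e-12
    sd_safe = np.where(constant, 1.0, sd)
    z = (values - mean) / sd_safe
    z[:, constant] = 0.0
    return replace(
        fm,
        values=z,
        normalized=True,
        constant_columns=[n for n, c in zip(fm.feature_names, constant) if c],
    )
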