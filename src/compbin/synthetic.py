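"""Synthetic bacterial communities for exercising the binning pipeline.

The simulator produces what a shotgun-metagenome assembly of a simple gut
community would hand to the binning stage: a set of contigs drawn from
several genomes whose nucleotide composition differs (distinct GC content
and higher-order k-mer biases), with abundance-weighted sampling, a minimum
contig length, optional shared ~1 kb repeat elements, and a partial table
of taxon annotations standing in for homology-based labels.  It also draws
multinomial amplicon (taxon-count) and functional-category count tables.

Each genome is an order-k Markov chain over {A,C,G,T}.  The transition
matrix is built from the target base composition, multiplicatively
perturbed by a genome-specific random pattern (the "skew"), and then
iteratively rescaled so that the stationary base distribution matches the
requested GC.  This is the simplest generative model that yields the
distinct tetranucleotide signatures composition binning relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numba import njit

from .errors import ParameterError
from .features import Contig

__all__ = [
    "RepeatElement",
    "GenomeSpec",
    "LognormalLengths",
    "CommunitySpec",
    "CommunityDataset",
    "generate_genome",
    "simulate_community",
    "simulate_amplicon_counts",
    "simulate_category_counts",
    "default_community_spec",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatElement:
    """A repeated insertion element shared across one genome."""

    length: int = 1000
    copies: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ParameterError("repeat element length must be >= 1")
        if self.copies < 0:
            raise ParameterError("repeat copy count must be >= 0")


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of one synthetic genome.

    ``gc`` is the target stationary GC fraction; ``order`` the Markov order
    (0..3); ``skew`` the strength of the genome-specific multiplicative
    perturbation of transition probabilities (0 = i.i.d. bases at the GC
    target); ``signature`` seeds the perturbation pattern so two genomes
    with equal GC can still differ in k-mer usage.
    """

    name: str
    length: int
    gc: float = 0.5
    order: int = 2
    skew: float = 0.3
    signature: int = 0
    repeat_element: RepeatElement | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ParameterError("genome name must be non-empty")
        if self.length <= 0:
            raise ParameterError("genome length must be positive")
        if not 0.0 < self.gc < 1.0:
            raise ParameterError("target GC must lie strictly in (0, 1)")
        if not 0 <= self.order <= 3:
            raise ParameterError("Markov order must be in 0..3")
        if self.skew < 0:
            raise ParameterError("skew must be nonnegative")


@dataclass(frozen=True)
class LognormalLengths:
    """Truncated log-normal contig length model (heavy-tailed, like
    assembly output); ``median`` is the untruncated median in bases."""

    median: float = 2000.0
    sigma: float = 0.7

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ParameterError("length model parameters must be positive")


@dataclass(frozen=True)
class CommunitySpec:
    genomes: tuple[GenomeSpec, ...]
    abundances: tuple[float, ...]
    n_contigs: int = 2000
    contig_length_model: LognormalLengths = field(default_factory=LognormalLengths)
    min_contig_len: int = 500
    label_fraction: float = 0.2
    label_error: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genomes", tuple(self.genomes))
        object.__setattr__(self, "abundances", tuple(float(a) for a in self.abundances))
        if not self.genomes:
            raise ParameterError("community needs at least one genome")
        if len(self.abundances) != len(self.genomes):
            raise ParameterError("one abundance per genome required")
        if any(a < 0 for a in self.abundances):
            raise ParameterError("abundances must be nonnegative")
        if abs(sum(self.abundances) - 1.0) > 1e-6:
            raise ParameterError("abundances must sum to 1")
        if self.min_contig_len < 1:
            raise ParameterError("min_contig_len must be >= 1")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ParameterError("label_fraction must lie in [0, 1]")
        if not 0.0 <= self.label_error <= 1.0:
            raise ParameterError("label_error must lie in [0, 1]")
        if self.n_contigs < 1:
            raise ParameterError("n_contigs must be >= 1")
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            raise ParameterError("genome names must be unique")


@dataclass
class CommunityDataset:
    """Simulated contigs with complete truth labels, a partial observed
    label table, and a manifest echoing the spec and seed."""

    contigs: list[Contig]
    labels: dict[str, str]
    genomes: dict[str, str]
    manifest: dict

    @property
    def truth(self) -> dict[str, str]:
        return {c.id: c.source for c in self.contigs}


# ---------------------------------------------------------------------------
# genome generation


@njit(cache=True)
def _markov_emit(cum: np.ndarray, order: int, length: int, state: int, u: np.ndarray):
    """Emit ``length`` base codes from an order-``order`` chain given
    per-state cumulative transition probabilities and uniform draws."""
    out = np.empty(length, dtype=np.uint8)
    mask = 1
    for _ in range(order):
        mask *= 4
    for i in range(length):
        row = cum[state]
        x = u[i]
        b = 0
        while b < 3 and row[b] < x:
            b += 1
        out[i] = b
        state = (state * 4 + b) % mask
    return out


def _transition_matrix(spec: GenomeSpec) -> np.ndarray:
    """Per-context transition probabilities with stationary GC matched to
    the target by iterative column rescaling."""
    n_states = 4**spec.order
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    rng = np.random.default_rng(np.uint32(spec.signature))
    pattern = rng.uniform(-1.0, 1.0, size=(n_states, 4))
    T = p[None, :] * np.exp(spec.skew * pattern)
    T /= T.sum(axis=1, keepdims=True)

    # rescale toward the target base marginal; the stationary distribution
    # of the context chain is found by power iteration
    for _ in range(60):
        pi = np.full(n_states, 1.0 / n_states)
        step = _context_step(T, spec.order)
        for _ in range(200):
            nxt = step(pi)
            if np.abs(nxt - pi).max() < 1e-12:
                pi = nxt
                break
            pi = nxt
        marginal = (pi[:, None] * T).sum(axis=0)
        if np.abs(marginal - p).max() < 1e-9:
            break
        T = T * (p / marginal)[None, :]
        T /= T.sum(axis=1, keepdims=True)
    return T


def _context_step(T: np.ndarray, order: int):
    """One step of the context-chain distribution: context (b1..bk) emits b
    and moves to (b2..bk b)."""
    n_states = T.shape[0]
    if order == 0:
        return lambda pi: pi
    next_state = np.empty((n_states, 4), dtype=np.int64)
    for s in range(n_states):
        for b in range(4):
            next_state[s, b] = (s * 4 + b) % n_states
    flat_to = next_state.ravel()

    def step(pi: np.ndarray) -> np.ndarray:
        flow = (pi[:, None] * T).ravel()
        out = np.zeros(n_states)
        np.add.at(out, flat_to, flow)
        return out

    return step


def _emit_sequence(spec: GenomeSpec, length: int, rng: np.random.Generator) -> np.ndarray:
    T = _transition_matrix(spec)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    if spec.order == 0:
        state = 0
    else:
        p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
        warm = rng.choice(4, size=spec.order, p=p)
        state = 0
        for b in warm:
            state = state * 4 + int(b)
    u = rng.random(length)
    return _markov_emit(cum, spec.order, length, state, u)


def generate_genome(spec: GenomeSpec, seed: int) -> str:
    """Generate one genome sequence of exactly ``spec.length`` bases.

    If the spec carries a repeat element, an identical element sequence is
    pasted (overwriting) at ``copies`` non-overlapping random positions, so
    the total length is preserved.
    """
    rng = np.random.default_rng(seed)
    codes = _emit_sequence(spec, spec.length, rng)
    rep = spec.repeat_element
    if rep is not None and rep.copies > 0:
        if rep.length > spec.length:
            raise ParameterError("repeat element longer than the genome")
        element = _emit_sequence(spec, rep.length, rng)
        positions = _nonoverlapping_positions(
            rng, spec.length, rep.length, rep.copies
        )
        for pos in positions:
            codes[pos : pos + rep.length] = element
    return _BASES[codes].tobytes().decode("ascii")


def _nonoverlapping_positions(
    rng: np.random.Generator, genome_len: int, rep_len: int, copies: int
) -> list[int]:
    if copies * rep_len > genome_len:
        raise ParameterError("repeat copies do not fit in the genome")
    chosen: list[int] = []
    for _ in range(10000):
        pos = int(rng.integers(0, genome_len - rep_len + 1))
        if all(abs(pos - q) >= rep_len for q in chosen):
            chosen.append(pos)
            if len(chosen) == copies:
                return chosen
    raise ParameterError("could not place non-overlapping repeat copies")


# ---------------------------------------------------------------------------
# community simulation


def simulate_community(cspec: CommunitySpec, seed: int) -> CommunityDataset:
    """Draw an abundance-weighted contig set from the community's genomes.

    The number of contigs per genome is multinomial with weights
    abundance x genome length; contig lengths follow the truncated
    log-normal model; every contig records its true source genome and a
    ``label_fraction`` subset receives an observed taxon label.
    """
    rng = np.random.default_rng(seed)
    genome_seeds = rng.integers(0, 2**31 - 1, size=len(cspec.genomes))
    sequences = {
        g.name: generate_genome(g, int(s))
        for g, s in zip(cspec.genomes, genome_seeds)
    }

    weights = np.array(
        [a * g.length for a, g in zip(cspec.abundances, cspec.genomes)], dtype=float
    )
    if weights.sum() <= 0:
        raise ParameterError("abundance-weighted genome lengths sum to zero")
    weights = weights / weights.sum()
    counts = rng.multinomial(cspec.n_contigs, weights)

    model = cspec.contig_length_model
    mu = np.log(model.median)
    contigs: list[Contig] = []
    idx = 0
    for g, n_g in zip(cspec.genomes, counts):
        seq = sequences[g.name]
        for _ in range(int(n_g)):
            length = 0
            while length < cspec.min_contig_len:
                length = int(np.round(rng.lognormal(mu, model.sigma)))
                length = min(length, g.length)
                if g.length < cspec.min_contig_len:
                    raise ParameterError(
                        f"genome {g.name!r} shorter than min_contig_len"
                    )
            start = int(rng.integers(0, g.length - length + 1))
            contigs.append(
                Contig(
                    id=f"ctg{idx:05d}",
                    seq=seq[start : start + length],
                    source=g.name,
                )
            )
            idx += 1

    # fold coverage implied by the sampled bases relative to genome size
    sampled = {g.name: 0 for g in cspec.genomes}
    for c in contigs:
        sampled[c.source] += c.length
    for c in contigs:
        glen = next(g.length for g in cspec.genomes if g.name == c.source)
        c.coverage = sampled[c.source] / glen

    labels: dict[str, str] = {}
    taxa = [g.name for g in cspec.genomes]
    for c in contigs:
        if rng.random() < cspec.label_fraction:
            taxon = c.source
            if cspec.label_error > 0 and rng.random() < cspec.label_error:
                others = [t for t in taxa if t != taxon]
                if others:
                    taxon = others[int(rng.integers(0, len(others)))]
            labels[c.id] = taxon

    manifest = {
        "seed": int(seed),
        "n_contigs": cspec.n_contigs,
        "min_contig_len": cspec.min_contig_len,
        "label_fraction": cspec.label_fraction,
        "genomes": {
            g.name: {"length": g.length, "gc": g.gc, "order": g.order, "skew": g.skew}
            for g in cspec.genomes
        },
        "abundances": dict(zip(taxa, cspec.abundances)),
    }
    return CommunityDataset(
        contigs=contigs, labels=labels, genomes=sequences, manifest=manifest
    )


# ---------------------------------------------------------------------------
# count-table simulators


def _check_profile(profile: Mapping[str, float]) -> None:
    vals = np.array(list(profile.values()), dtype=float)
    if (vals < 0).any():
        raise ParameterError("proportions must be nonnegative")
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ParameterError("proportions must sum to 1")


def simulate_amplicon_counts(
    profiles: Mapping[str, Mapping[str, float]],
    depths: Mapping[str, int],
    seed: int,
) -> pd.DataFrame:
    """Multinomial per-sample taxon counts (samples x taxa).

    ``profiles`` maps sample -> taxon -> proportion (each summing to 1);
    ``depths`` maps sample -> read total.  Row sums equal depths exactly.
    """
    if set(profiles) != set(depths):
        raise ParameterError("profiles and depths must cover the same samples")
    rng = np.random.default_rng(seed)
    taxa = sorted({t for p in profiles.values() for t in p})
    rows = {}
    for sample in sorted(profiles):
        _check_profile(profiles[sample])
        depth = int(depths[sample])
        if depth < 1:
            raise ParameterError("read depth must be >= 1")
        p = np.array([profiles[sample].get(t, 0.0) for t in taxa], dtype=float)
        p = p / p.sum()
        rows[sample] = rng.multinomial(depth, p)
    return pd.DataFrame.from_dict(rows, orient="index", columns=taxa)


def simulate_category_counts(
    base: Mapping[str, float], total_hits: int, seed: int
) -> pd.Series:
    """One sample's multinomial functional-category hit counts."""
    _check_profile(base)
    if total_hits < 1:
        raise ParameterError("total_hits must be >= 1")
    rng = np.random.default_rng(seed)
    cats = sorted(base)
    p = np.array([base[c] for c in cats], dtype=float)
    p = p / p.sum()
    return pd.Series(rng.multinomial(int(total_hits), p), index=cats)


# ---------------------------------------------------------------------------
# default study-like community

#: taxa of a simple blood-feeding-invertebrate gut community, with GC
#: targets spaced 0.05 apart and distinct transition-skew signatures
_DEFAULT_PANEL = [
    ("Fusobacterium", 0.30, 0.05),
    ("Clostridium", 0.35, 0.10),
    ("Bacteroides", 0.40, 0.08),
    ("Rikenella", 0.45, 0.30),
    ("Erysipelothrix", 0.50, 0.07),
    ("Proteus", 0.55, 0.12),
    ("Aeromonas", 0.60, 0.25),
    ("Desulfovibrio", 0.65, 0.03),
]


def default_community_spec(
    genome_length: int = 300_000,
    n_contigs: int = 2000,
    min_contig_len: int = 1000,
    label_fraction: float = 0.2,
    skew: float = 0.35,
) -> CommunitySpec:
    """An eight-genome community with pairwise GC gaps of 0.05, distinct
    dinucleotide skews, and uneven abundances, mirroring a moderately
    complex gut microbiome."""
    genomes = tuple(
        GenomeSpec(
            name=name,
            length=genome_length,
            gc=gc,
            order=2,
            skew=skew,
            signature=17 + 101 * i,
        )
        for i, (name, gc, _a) in enumerate(_DEFAULT_PANEL)
    )
    abundances = np.array([a for _n, _gc, a in _DEFAULT_PANEL], dtype=float)
    abundances = abundances / abundances.sum()
    return CommunitySpec(
        genomes=genomes,
        abundances=tuple(abundances),
        n_contigs=n_contigs,
        min_contig_len=min_contig_len,
        label_fraction=label_fraction,
    )
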