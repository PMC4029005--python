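"""FASTA/TSV input-output, assembly statistics, run configuration, logging.

All tabular outputs are written deterministically (rows sorted by contig or
sample id) and every CLI run leaves a manifest sufficient to reproduce its
outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import EmptyInputError, FastaParseError, ParameterError
from .features import Contig

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_counts",
    "write_counts",
    "assembly_stats",
    "RunConfig",
    "write_manifest",
    "logger",
]

logger = logging.getLogger("compbin")


def read_fasta(path) -> list[Contig]:
    """Read contigs from FASTA; ids are header tokens up to the first
    whitespace, sequences are uppercased.  Duplicate ids and sequence data
    before the first header are errors (with line numbers)."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {current_id!r} has no sequence", line_no)
        contigs.append(Contig(id=current_id, seq=seq))

    line_no = 0
    with open(path) as handle:
        for line_no, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                current_id = line[1:].split()[0] if len(line) > 1 else ""
                if not current_id:
                    raise FastaParseError("empty FASTA header", line_no)
                if current_id in seen:
                    raise FastaParseError(
                        f"duplicate contig id {current_id!r}", line_no
                    )
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError("sequence data before first header", line_no)
                chunks.append(line.upper())
        flush(line_no)
    logger.info("read %d contigs from %s", len(contigs), path)
    return contigs


def write_fasta(contigs: Iterable[Contig], path, width: int = 80) -> None:
    """Write contigs as FASTA wrapped at ``width`` columns."""
    if width < 1:
        raise ParameterError("line width must be >= 1")
    with open(path, "w") as handle:
        for contig in contigs:
            handle.write(f">{contig.id}\n")
            seq = contig.seq
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def read_labels(path) -> dict[str, str]:
    """Two-column TSV (contig_id, taxon) -> dict."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["contig_id", "taxon"],
                        dtype=str, comment="#")
    return dict(zip(frame["contig_id"], frame["taxon"]))


def write_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as handle:
        for contig_id in sorted(labels):
            handle.write(f"{contig_id}\t{labels[contig_id]}\n")


def read_counts(path) -> pd.DataFrame:
    """Count table TSV with rows = taxa/categories, columns = samples;
    returned transposed to the in-memory samples x features orientation."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.T


def write_counts(table: pd.DataFrame, path) -> None:
    """Write a samples x features table as TSV with rows = features."""
    table.T.sort_index().to_csv(path, sep="\t")


def assembly_stats(contigs: Sequence[Contig], min_len: int = 500) -> dict:
    """Contig count, total bases, mean length, N50 and maximum length over
    contigs of length >= ``min_len``.

    N50 is the length L such that contigs of length >= L, taken in
    descending order, first reach half the filtered total.
    """
    lengths = sorted((c.length for c in contigs if c.length >= min_len), reverse=True)
    if not lengths:
        raise EmptyInputError(f"no contig of length >= {min_len}")
    total = sum(lengths)
    half = total / 2
    running = 0
    n50 = lengths[-1]
    for length in lengths:
        running += length
        if running >= half:
            n50 = length
            break
    return {
        "count": len(lengths),
        "total_bases": total,
        "mean_length": total / len(lengths),
        "n50": n50,
        "max_length": lengths[0],
    }


@dataclass
class RunConfig:
    """Stage parameters for the pipeline, echoed into every output dir."""

    seed: int = 0
    # feature stage
    min_len: int = 1000
    ks: tuple[int, ...] = (2, 3, 4, 5)
    strand_mode: str = "single"
    # K-means route
    k: int = 10
    runs: int = 100
    pca_variance: float = 0.9
    # ESOM route
    grid_rows: int = 50
    grid_cols: int = 82
    epochs: int = 20
    ridge_quantile: float = 0.6
    # labeling / consensus
    min_frac: float = 0.5
    # amplicon stage
    depth: int | None = None
    reps: int = 100

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ParameterError("seed must be nonnegative")
        if not self.ks or not all(2 <= k <= 5 for k in self.ks):
            raise ParameterError("ks must be a subset of 2..5")
        if self.min_len < max(self.ks):
            raise ParameterError("min_len must cover the largest k")
        if self.k < 1 or self.runs < 1 or self.epochs < 1 or self.reps < 1:
            raise ParameterError("k, runs, epochs and reps must be >= 1")
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ParameterError("SOM grid must be at least 2x2")
        if not 0.0 < self.ridge_quantile <= 1.0:
            raise ParameterError("ridge_quantile must lie in (0, 1]")
        if not 0.0 < self.pca_variance <= 1.0:
            raise ParameterError("pca_variance must lie in (0, 1]")
        if not 0.0 <= self.min_frac < 1.0:
            raise ParameterError("min_frac must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "ks" in data:
            data["ks"] = tuple(data["ks"])
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["ks"] = list(self.ks)
        return data


def write_manifest(outdir, config: RunConfig, extra: dict | None = None) -> Path:
    """Write a YAML manifest (config + versions) into ``outdir``."""
    import numpy
    import scipy
    import sklearn

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "versions": {
            "compbin": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.yaml"
    with open(path, "w") as handle:
        yaml.safe_dump(manifest, handle, sort_keys=True)
    return path
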