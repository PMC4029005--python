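"""End-to-end binning pipeline: features -> two routes -> consensus.

This is the composition the CLI ``bin`` command and the recovery
experiments run: compute the full composition matrix and the
tetranucleotide matrix, cluster by PCA + K-means and by ESOM, label both
clusterings from the partial annotation table, and reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import binning, features
from .features import Contig
from .io import RunConfig

__all__ = ["BinningResult", "bin_contigs", "recovery_experiment"]


@dataclass
class BinningResult:
    embedding: binning.Embedding
    kmeans: binning.ClusterAssignment
    som: binning.EsomMap
    esom: binning.ClusterAssignment
    bins: binning.BinAssignment
    agreement: float

    @property
    def esom_cluster_count(self) -> int:
        return self.esom.n_clusters


def bin_contigs(
    contigs: Sequence[Contig],
    labels: Mapping[str, str],
    config: RunConfig | None = None,
) -> BinningResult:
    """Run the full two-route consensus binning on a contig set."""
    cfg = config or RunConfig()

    fm = features.normalize_features(
        features.composition_matrix(
            contigs, ks=cfg.ks, min_len=cfg.min_len, strand_mode=cfg.strand_mode
        )
    )
    embedding = binning.pca_embed(fm)
    km = binning.kmeans_best_of(
        embedding.retained(cfg.pca_variance), k=cfg.k, runs=cfg.runs, seed=cfg.seed
    )

    tetra = features.normalize_features(
        features.composition_matrix(
            contigs,
            ks=(4,),
            min_len=cfg.min_len,
            strand_mode=cfg.strand_mode,
            include_gc=False,
        )
    )
    som = binning.esom_train(
        tetra,
        rows=cfg.grid_rows,
        cols=cfg.grid_cols,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    esom_ca = binning.esom_clusters(som, ridge_quantile=cfg.ridge_quantile)

    km_labeled = binning.label_clusters(km, labels, min_frac=cfg.min_frac)
    esom_labeled = binning.label_clusters(esom_ca, labels, min_frac=cfg.min_frac)
    bins = binning.consensus_bins(km_labeled, esom_labeled)
    agreement = binning.agreement_fraction(km_labeled, esom_labeled)
    return BinningResult(
        embedding=embedding,
        kmeans=km_labeled,
        som=som,
        esom=esom_labeled,
        bins=bins,
        agreement=agreement,
    )


def recovery_experiment(seeds: Sequence[int], config: RunConfig | None = None):
    """Bin a fresh default synthetic community per seed; returns one record
    per seed with the route agreement, ESOM cluster count, consensus bins
    and the simulation truth (for parameter-recovery scoring)."""
    from .synthetic import default_community_spec, simulate_community

    base = (config or RunConfig()).to_dict()
    records = []
    for seed in seeds:
        base["ks"] = tuple(base["ks"])
        cfg = RunConfig(**{**base, "seed": int(seed)})
        dataset = simulate_community(
            default_community_spec(min_contig_len=cfg.min_len), int(seed)
        )
        result = bin_contigs(dataset.contigs, dataset.labels, cfg)
        records.append(
            {
                "seed": int(seed),
                "agreement": result.agreement,
                "esom_clusters": result.esom_cluster_count,
                "result": result,
                "dataset": dataset,
            }
        )
    return records
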