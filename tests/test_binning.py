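"""Binning route correctness: PCA embedding, best-of-runs K-means, ESOM
training and valley extraction, cluster labeling, consensus and summary."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from compbin import (
    DISCARDED,
    UNLABELED,
    ClusterAssignment,
    CommunitySpec,
    EmptyInputError,
    GenomeSpec,
    ParameterError,
    RepeatElement,
    RunConfig,
    UndefinedValueError,
    agreement_fraction,
    bin_contigs,
    bin_summary,
    consensus_bins,
    esom_clusters,
    esom_train,
    kmeans_best_of,
    label_clusters,
    pca_embed,
    simulate_community,
)
from compbin.features import Contig


# ---------------------------------------------------------------------------
# PCA


def test_pca_identical_rows_give_identical_coordinates():
    data = np.tile([1.0, 2.0, 3.0], (2, 1))
    emb = pca_embed(data)
    np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1])
    assert emb.eigenvalues[0] == pytest.approx(0.0, abs=1e-12)


def test_pca_collinear_points_put_all_variance_on_pc1():
    t = np.linspace(0, 1, 30)
    direction = np.array([1.0, -2.0, 0.5, 3.0, 1.0])
    data = np.outer(t, direction)
    emb = pca_embed(data)
    assert emb.explained_variance_ratio[0] == pytest.approx(1.0)
    assert np.all(emb.eigenvalues[1:] < 1e-12)


def test_pca_full_rank_reconstruction_and_orthonormality():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(50, 20))
    emb = pca_embed(data)
    recon = emb.coordinates @ emb.component_loadings + emb.mean
    np.testing.assert_allclose(recon, data, atol=1e-8)
    gram = emb.component_loadings @ emb.component_loadings.T
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-6)
    assert np.all(np.diff(emb.eigenvalues) <= 1e-12)


def test_pca_single_row_rejected():
    with pytest.raises(ParameterError):
        pca_embed(np.ones((1, 5)))


# ---------------------------------------------------------------------------
# K-means


def _sse(points, labels):
    sse = 0.0
    for lab in np.unique(labels):
        cluster = points[labels == lab]
        sse += ((cluster - cluster.mean(axis=0)) ** 2).sum()
    return sse


def test_kmeans_separated_blobs_recovered_exactly():
    rng = np.random.default_rng(1)
    blob1 = rng.normal([0, 0], 0.1, size=(25, 2))
    blob2 = rng.normal([10, 10], 0.1, size=(25, 2))
    data = np.vstack([blob1, blob2])
    ca = kmeans_best_of(data, k=2, runs=10, seed=0)
    truth = np.array([0] * 25 + [1] * 25)
    assert adjusted_rand_score(truth, ca.cluster) == 1.0


def test_kmeans_matches_brute_force_optimum_on_six_points():
    """Best-of-runs SSE equals the minimum over all 2-partitions."""
    rng = np.random.default_rng(3)
    points = rng.normal(size=(6, 2))
    best = np.inf
    for assignment in itertools.product([0, 1], repeat=6):
        labels = np.array(assignment)
        if len(np.unique(labels)) < 2:
            continue
        best = min(best, _sse(points, labels))
    ca = kmeans_best_of(points, k=2, runs=100, seed=0)
    assert ca.score == pytest.approx(best, rel=1e-9)


def test_kmeans_parameter_checks():
    data = np.zeros((5, 2))
    with pytest.raises(ParameterError):
        kmeans_best_of(data, k=0)
    with pytest.raises(ParameterError):
        kmeans_best_of(data, k=6)
    with pytest.raises(ParameterError):
        kmeans_best_of(data, k=2, runs=0)


def test_kmeans_sse_non_increasing_in_runs():
    rng = np.random.default_rng(4)
    data = rng.normal(size=(60, 4))
    sse = [kmeans_best_of(data, k=5, runs=r, seed=9).score for r in (1, 5, 25)]
    assert sse[1] <= sse[0] + 1e-9
    assert sse[2] <= sse[1] + 1e-9


# ---------------------------------------------------------------------------
# ESOM


def test_esom_identical_inputs_collapse_to_one_unit():
    data = np.tile([0.3, -1.2, 0.7], (40, 1))
    som = esom_train(data, rows=5, cols=6, epochs=5, seed=0)
    assert len(set(som.bmu.tolist())) == 1
    assert som.quantization_error == pytest.approx(0.0, abs=1e-6)


def _two_cloud_som(seed=0):
    rng = np.random.default_rng(seed)
    cloud1 = rng.normal(0.0, 0.3, size=(100, 8))
    cloud2 = rng.normal(4.0, 0.3, size=(100, 8))
    data = np.vstack([cloud1, cloud2])
    som = esom_train(data, rows=20, cols=30, epochs=10, seed=seed)
    return som, np.array([0] * 100 + [1] * 100)


def test_esom_two_clouds_separated_by_umatrix_ridge():
    som, truth = _two_cloud_som()
    bmu_cells = np.unravel_index(som.bmu, (som.rows, som.cols))
    within = som.umatrix[bmu_cells].mean()
    assert som.umatrix.max() > 2 * within
    # and BMUs fall in two distinct regions matching the cloud split
    ca = esom_clusters(som, ridge_quantile=0.6)
    assert ca.n_clusters == 2
    assert adjusted_rand_score(truth, ca.cluster) == 1.0


def test_esom_quantization_error_decreases_over_epochs():
    som, _ = _two_cloud_som(seed=5)
    qe = som.epoch_errors
    assert np.all(np.diff(qe) <= 0.01 * qe[:-1])


def test_esom_everything_a_valley_is_one_cluster():
    som, _ = _two_cloud_som(seed=2)
    ca = esom_clusters(som, ridge_quantile=1.0)
    assert ca.n_clusters == 1


def test_esom_parameter_checks():
    data = np.zeros((10, 3))
    with pytest.raises(ParameterError):
        esom_train(data, rows=1, cols=5)
    with pytest.raises(ParameterError):
        esom_train(data, rows=5, cols=5, epochs=0)
    som, _ = _two_cloud_som(seed=3)
    with pytest.raises(ParameterError):
        esom_clusters(som, ridge_quantile=0.0)


# ---------------------------------------------------------------------------
# labeling and consensus


def _assignment(ids, clusters, taxa=None):
    ca = ClusterAssignment(
        contig_ids=list(ids), cluster=np.array(clusters), method="kmeans_pca"
    )
    if taxa:
        ca.cluster_taxa = taxa
    return ca


def test_label_clusters_majority_and_tie():
    ca = _assignment(["a", "b", "c", "d", "e"], [0, 0, 0, 1, 1])
    labeled = label_clusters(ca, {"a": "X", "b": "X", "c": "X", "d": "X", "e": "Y"})
    assert labeled.cluster_taxa[0] == "X"
    assert labeled.label_support[0] == 1.0
    assert labeled.cluster_taxa[1] == UNLABELED  # 50/50 tie stays unlabeled


def test_label_clusters_empty_table_warns_all_unlabeled(caplog):
    ca = _assignment(["a", "b"], [0, 1])
    with caplog.at_level("WARNING", logger="compbin"):
        labeled = label_clusters(ca, {})
    assert set(labeled.cluster_taxa.values()) == {UNLABELED}
    assert any("empty label table" in m for m in caplog.messages)


def test_consensus_rules():
    a = _assignment(["c1", "c2", "c3", "c4"], [0, 1, 2, 3],
                    {0: "X", 1: "X", 2: "X", 3: UNLABELED})
    b = _assignment(["c1", "c2", "c3", "c4"], [0, 1, 2, 3],
                    {0: "X", 1: "Y", 2: UNLABELED, 3: UNLABELED})
    bins = consensus_bins(a, b)
    assert bins.assignments["c1"] == "X"
    assert bins.assignments["c2"] == DISCARDED
    assert bins.assignments["c3"] == "X"
    assert "c3" in bins.single_route
    assert bins.assignments["c4"] == UNLABELED
    # DISCARDED count equals the disagreement count
    assert len(bins.discarded) == 1
    # no taxon appears that neither input carried
    taxa = set(bins.binned().values())
    assert taxa <= (set(a.cluster_taxa.values()) | set(b.cluster_taxa.values()))


def test_consensus_requires_shared_contigs():
    a = _assignment(["c1"], [0], {0: "X"})
    b = _assignment(["c2"], [0], {0: "X"})
    with pytest.raises(EmptyInputError):
        consensus_bins(a, b)


def test_agreement_fraction_hand_counts():
    ids = ["c1", "c2", "c3", "c4"]
    a = _assignment(ids, [0, 0, 1, 1], {0: "X", 1: "Y"})
    b = _assignment(ids, [0, 0, 1, 2], {0: "X", 1: "Y", 2: "Z"})
    assert agreement_fraction(a, a) == 1.0
    assert agreement_fraction(a, b) == 0.75
    c = _assignment(ids, [0, 0, 0, 0], {0: UNLABELED})
    with pytest.raises(UndefinedValueError):
        agreement_fraction(a, c)


def test_bin_summary_bases_and_discarded_row():
    from compbin.binning import BinAssignment

    contigs = [Contig("c1", "A" * 1000), Contig("c2", "C" * 2000)]
    bins = BinAssignment(
        assignments={"c1": "X", "c2": "X"}, single_route=set(), dropped=[]
    )
    summary = bin_summary(bins, contigs)
    assert summary.loc["X", "total_bases"] == 3000
    assert summary.loc["X", "total_mb"] == 0.0
    assert summary.loc["X", "contig_count"] == 2

    all_discarded = BinAssignment(
        assignments={"c1": DISCARDED, "c2": DISCARDED},
        single_route=set(),
        dropped=[],
    )
    summary = bin_summary(all_discarded, contigs)
    assert list(summary.index) == [DISCARDED]
    assert summary.loc[DISCARDED, "contig_count"] == 2


# ---------------------------------------------------------------------------
# pipeline-level properties (cheap four-genome community)


def test_small_pipeline_recovers_bins(small_dataset, small_config):
    result = bin_contigs(small_dataset.contigs, small_dataset.labels, small_config)
    truth = small_dataset.truth
    binned = result.bins.binned()
    assert len(binned) > 0.8 * len(small_dataset.contigs)
    ari = adjusted_rand_score(
        [truth[c] for c in binned], list(binned.values())
    )
    assert ari > 0.9
    assert result.agreement > 0.8


def test_repeat_elements_do_not_move_nonrepeat_contigs():
    """Pasting a shared 1 kb repeat into two genomes only affects the bins
    of contigs that contain repeat sequence."""

    def build(with_repeats: bool):
        rep = RepeatElement(length=1000, copies=8) if with_repeats else None
        genomes = (
            GenomeSpec(name="a", length=120_000, gc=0.35, signature=1,
                       repeat_element=rep),
            GenomeSpec(name="b", length=120_000, gc=0.55, signature=2,
                       repeat_element=rep),
        )
        spec = CommunitySpec(
            genomes=genomes, abundances=(0.5, 0.5), n_contigs=200,
            min_contig_len=1000, label_fraction=0.3,
        )
        return simulate_community(spec, 11)

    plain = build(False)
    with_rep = build(True)
    cfg = RunConfig(seed=11, k=4, runs=20, grid_rows=12, grid_cols=20, epochs=8)
    bins_plain = bin_contigs(plain.contigs, plain.labels, cfg).bins
    bins_rep = bin_contigs(with_rep.contigs, with_rep.labels, cfg).bins

    seq_plain = {c.id: c.seq for c in plain.contigs}
    seq_rep = {c.id: c.seq for c in with_rep.contigs}
    untouched = [cid for cid in seq_plain if seq_plain[cid] == seq_rep[cid]]
    assert len(untouched) > 100  # most contigs carry no repeat sequence
    moved = [
        cid
        for cid in untouched
        if bins_plain.assignments[cid] != bins_rep.assignments[cid]
    ]
    assert moved == []


def test_cluster_labeling_recovers_true_taxa(recovery_records):
    """With 20% annotation labels, at least 7 of the 8 planted taxa end up
    correctly named on each route's clusters (median over 10 seeds)."""
    per_seed = []
    for rec in recovery_records:
        truth = rec["dataset"].truth
        correct_taxa = set()
        for route in (rec["result"].kmeans, rec["result"].esom):
            taxa = route.taxa()
            for cluster in range(route.n_clusters):
                members = [
                    cid
                    for cid, c in zip(route.contig_ids, route.cluster)
                    if c == cluster
                ]
                sources = [truth[m] for m in members]
                majority = max(set(sources), key=sources.count)
                if route.cluster_taxa.get(cluster) == majority:
                    correct_taxa.add(majority)
        per_seed.append(len(correct_taxa))
    assert float(np.median(per_seed)) >= 7


def test_bin_totals_track_truth_totals(recovery_records):
    """Per-bin base totals stay within 10% of the truth totals computed
    over the same (non-discarded) contigs."""
    rec = recovery_records[0]
    contigs = {c.id: c for c in rec["dataset"].contigs}
    truth = rec["dataset"].truth
    summary = bin_summary(rec["result"].bins, list(contigs.values()))
    binned = rec["result"].bins.binned()
    for taxon in {t for t in binned.values()}:
        truth_bases = sum(
            contigs[cid].length
            for cid in binned
            if truth[cid] == taxon
        )
        assert summary.loc[taxon, "total_bases"] == pytest.approx(
            truth_bases, rel=0.10
        )


def test_kmeans_on_synthetic_community(small_dataset, small_config):
    """k clusters requested with fewer taxa: at most k non-empty clusters
    and the best-of-many SSE never above a single run's."""
    from compbin import composition_matrix, normalize_features, pca_embed

    fm = normalize_features(
        composition_matrix(small_dataset.contigs, min_len=1000)
    )
    emb = pca_embed(fm).retained(0.9)
    many = kmeans_best_of(emb, k=10, runs=30, seed=1)
    single = kmeans_best_of(emb, k=10, runs=1, seed=1)
    assert many.n_clusters <= 10
    assert many.score <= single.score + 1e-9
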