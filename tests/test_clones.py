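"""Clone pipeline: QC, normalization, clustering, CNV, votes, DE."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from clonerx import clones as cl
from clonerx.errors import (
    AllCellsRemovedError,
    GroupTooSmallError,
    NoMarkersFoundError,
    NoReferenceError,
    TooFewMalignantCellsError,
    ZeroCellError,
)
from clonerx.sim import SimConfig, simulate_patient


def _adata(counts, genes=None, barcodes=None, var_extra=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    var = pd.DataFrame(index=pd.Index(genes or [f"G{i}" for i in range(g)], name="symbol"))
    if var_extra:
        for k, v in var_extra.items():
            var[k] = v
    return ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=barcodes or [f"c{i}" for i in range(n)]),
        var=var,
    )


class TestQC:
    def test_mito_bound_exclusive_above(self):
        counts = np.array([[88, 12], [95, 5]])  # mito fractions 0.12, 0.05
        adata = _adata(counts, genes=["G1", "MT-X"])
        kept = cl.qc_filter(adata, min_genes=0, max_genes=10, max_mito_frac=0.10)
        assert list(kept.obs_names) == ["c1"]

    def test_organoid_mode_keeps_higher_mito(self):
        counts = np.array([[85, 15], [95, 5]])  # fractions 0.15, 0.05
        adata = _adata(counts, genes=["G1", "MT-X"])
        kept = cl.qc_filter(adata, min_genes=0, max_genes=10, max_mito_frac=0.20)
        assert len(kept) == 2

    def test_permissive_bounds_are_identity(self):
        counts = np.array([[1, 0, 3], [4, 5, 6]])
        adata = _adata(counts)
        kept = cl.qc_filter(adata, min_genes=0, max_genes=10**9, max_mito_frac=1.0)
        assert list(kept.obs_names) == list(adata.obs_names)

    def test_all_removed_raises(self):
        adata = _adata(np.array([[1, 1], [2, 2]]))
        with pytest.raises(AllCellsRemovedError):
            cl.qc_filter(adata, min_genes=100, max_genes=200, max_mito_frac=1.0)


class TestLogNormalize:
    def test_hand_computed_toy_cell(self):
        counts = np.array([[100, 300, 600]])  # total 1000, scale 1e4
        norm = cl.lognormalize(_adata(counts), scale=1e4)
        want = np.log1p(1e4 * np.array([100, 300, 600]) / 1000)
        np.testing.assert_allclose(norm.X.toarray()[0], want, rtol=1e-6)

    def test_depth_invariance(self):
        counts = np.array([[10, 30, 60], [20, 60, 120]])  # same composition
        norm = cl.lognormalize(_adata(counts))
        np.testing.assert_allclose(norm.X.toarray()[0], norm.X.toarray()[1], rtol=1e-6)

    def test_zero_cell_raises(self):
        with pytest.raises(ZeroCellError):
            cl.lognormalize(_adata(np.array([[0, 0], [1, 2]])))


class TestClustering:
    def _blobs(self, rng, n=120, sep=8.0):
        a = rng.poisson(2.0, size=(n // 2, 60))
        b = rng.poisson(2.0, size=(n // 2, 60))
        b[:, :20] += rng.poisson(sep, size=(n // 2, 20))
        return _adata(np.vstack([a, b]) + 1)

    def test_two_blobs_fully_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        adata = cl.lognormalize(self._blobs(rng))
        labels = cl.cluster_cells(adata, resolution=0.5, seed=0)
        truth = np.repeat([0, 1], len(adata) // 2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_cells_one_cluster(self):
        counts = np.tile(np.arange(1, 41), (60, 1))
        adata = cl.lognormalize(_adata(counts))
        labels = cl.cluster_cells(adata, resolution=0.5, seed=0)
        assert len(np.unique(labels)) == 1

    def test_seed_determinism(self, rng):
        adata = cl.lognormalize(self._blobs(rng))
        l1 = cl.cluster_cells(adata, seed=7)
        l2 = cl.cluster_cells(adata, seed=7)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            cl.cluster_cells(_adata(np.ones((10, 5))))


class TestMarkerScore:
    def _marker_adata(self, rng, n=90):
        # marker genes on top of a 40-gene background so marker spikes do not
        # dominate library size
        genes = ["CD3D", "CD3E", "CD34", "KIT", "HK1", "HK2"] + [
            f"BG{i}" for i in range(40)
        ]
        counts = rng.poisson(3.0, size=(n, len(genes)))
        counts[: n // 3, 0:2] += 20  # cluster 0: T markers
        counts[n // 3: 2 * n // 3, 2:4] += 20  # cluster 1: blast markers
        adata = cl.lognormalize(_adata(counts + 1, genes=genes))
        clusters = np.repeat([0, 1, 2], n // 3)
        return adata, clusters

    def test_overexpressed_markers_label_cluster(self, rng):
        adata, clusters = self._marker_adata(rng)
        ann = cl.marker_score(adata, clusters)
        assert ann.loc[0, "label"] == "T cell" and not ann.loc[0, "malignant"]
        assert ann.loc[1, "label"] == "Leukemic blast" and ann.loc[1, "malignant"]

    def test_low_signal_cluster_unknown(self, rng):
        adata, clusters = self._marker_adata(rng)
        ann = cl.marker_score(adata, clusters)
        assert ann.loc[2, "label"] == "Unknown"

    def test_shared_marker_has_zero_weight(self, rng):
        adata, clusters = self._marker_adata(rng)
        db = {
            "T cell": {"positive": ["CD3D", "CD3E", "HK1"], "malignant": False},
            "Leukemic blast": {"positive": ["CD34", "KIT", "HK1"], "malignant": True},
        }
        ann_shared = cl.marker_score(adata, clusters, db)
        db_nohk = {
            "T cell": {"positive": ["CD3D", "CD3E"], "malignant": False},
            "Leukemic blast": {"positive": ["CD34", "KIT"], "malignant": True},
        }
        ann_without = cl.marker_score(adata, clusters, db_nohk)
        # HK1 is listed by every type -> weight 0 -> scores scale only by the
        # 1/sqrt(n_markers) normalization, rankings identical
        assert (ann_shared["label"] == ann_without["label"]).all()

    def test_no_markers_raises(self, rng):
        adata, clusters = self._marker_adata(rng)
        with pytest.raises(NoMarkersFoundError):
            cl.marker_score(adata, clusters, {"X": {"positive": ["NOPE"], "malignant": False}})


def _cnv_patient(seed=21, **kw):
    cfg = SimConfig(n_cells=600, n_genes=800, seed=seed, **kw)
    adata, truth = simulate_patient(cfg)
    norm = cl.lognormalize(cl.qc_filter(adata, 0, 10**9, 1.0))
    labels = adata.obs.loc[norm.obs_names, "true_label"].to_numpy()
    return norm, labels


class TestCNV:
    def test_reference_cells_centred_near_zero(self):
        norm, labels = _cnv_patient()
        ref = labels == "normal"
        cnv = cl.infer_cnv_profiles(norm, ref, window=21)
        ref_profiles = cnv.profiles.loc[norm.obs_names[ref]]
        assert abs(float(ref_profiles.to_numpy().mean())) < 0.01
        arm_abs = cnv.arm_means.loc[norm.obs_names[ref]].mean(axis=0).abs()
        assert (arm_abs < 3 * cnv.ref_sd).all()

    def test_planted_gain_shifts_arm_in_most_cells(self):
        norm, labels = _cnv_patient()
        cnv = cl.infer_cnv_profiles(norm, labels == "normal", window=21)
        clone_a = cnv.arm_means.loc[norm.obs_names[labels == "A"]]
        assert (clone_a["1p"] > 0).mean() >= 0.9  # planted 1.5x gain
        assert (clone_a["7q"] < 0).mean() >= 0.9  # planted 0.5x loss

    def test_window_one_equals_centred_expression(self):
        norm, labels = _cnv_patient()
        ref = labels == "normal"
        cnv = cl.infer_cnv_profiles(norm, ref, window=1, winsor_sd=np.inf)
        genes = cnv.profiles.columns
        X = norm[:, genes].X.toarray()
        centred = X - X[ref].mean(axis=0)
        np.testing.assert_allclose(cnv.profiles.to_numpy(), centred, atol=1e-5)

    def test_missing_reference_raises(self):
        norm, labels = _cnv_patient()
        with pytest.raises(NoReferenceError):
            cl.infer_cnv_profiles(norm, np.zeros(len(norm), dtype=bool))


class TestEnsembleVote:
    @pytest.mark.parametrize(
        "votes,want",
        [((True, True, False), True), ((False, False, True), False),
         ((True, True, True), True), ((False, False, False), False)],
    )
    def test_majority(self, votes, want):
        out = cl.call_malignant_ensemble(*[np.array([v]) for v in votes])
        assert out[0] == want

    def test_permutation_symmetry(self, rng):
        v = [rng.random(50) > 0.5 for _ in range(3)]
        base = cl.call_malignant_ensemble(*v)
        np.testing.assert_array_equal(base, cl.call_malignant_ensemble(v[2], v[0], v[1]))


class TestSubclones:
    def _arm_means(self, rng, n_a=120, n_b=80, shift=1.0):
        arms = [f"{c}{a}" for c in range(1, 11) for a in "pq"]
        X = rng.normal(0, 0.5, size=(n_a + n_b, len(arms)))
        X[:n_a, 0] += shift
        X[n_a:, 5] -= shift
        return pd.DataFrame(X, columns=arms, index=[f"c{i}" for i in range(n_a + n_b)])

    def test_planted_clones_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        am = self._arm_means(rng, shift=2.0)
        res = cl.detect_subclones(am)
        truth = np.repeat([0, 1], [120, 80])
        assert not res.degenerate
        assert adjusted_rand_score(truth, res.labels) >= 0.9
        assert res.labels.value_counts()["A"] >= res.labels.value_counts()["B"]

    def test_homogeneous_population_degenerate(self, rng):
        am = self._arm_means(rng, shift=0.0)
        res = cl.detect_subclones(am)
        assert res.degenerate
        assert (res.labels == "A").all()

    def test_fractions_sum_to_one_and_in_tree(self, rng):
        am = self._arm_means(rng, shift=1.5)
        res = cl.detect_subclones(am)
        assert sum(res.fractions.values()) == pytest.approx(1.0)
        assert res.newick.startswith("(") and res.newick.endswith(");")

    def test_too_few_cells_raises(self, rng):
        with pytest.raises(TooFewMalignantCellsError):
            cl.detect_subclones(self._arm_means(rng).head(20))


class TestSignature:
    def _groups(self, rng, n=200, genes=60, fold_idx=None, fold=2.0):
        base = rng.poisson(3.0, size=(2 * n, genes)) + 1
        if fold_idx is not None:
            base[:n, fold_idx] = rng.poisson(3.0 * fold, size=n) + 1
        adata = cl.lognormalize(_adata(base))
        g = np.zeros(2 * n, dtype=bool); g[:n] = True
        return adata, g, ~g

    def test_identical_groups_empty_after_filters(self, rng):
        adata, g, r = self._groups(rng)
        sig = cl.compute_signature(adata, g, r)
        assert (sig["log2fc"].abs() < 1).all()  # no planted effect survives
        assert len(sig) < 5  # filters remove essentially everything

    def test_swapping_groups_negates_log2fc(self, rng):
        adata, g, r = self._groups(rng, fold_idx=0)
        s1 = cl.compute_signature(adata, g, r, min_abs_log2fc=0.0, min_pct=0.0)
        s2 = cl.compute_signature(adata, r, g, min_abs_log2fc=0.0, min_pct=0.0)
        joined = s1.join(s2, lsuffix="_a", rsuffix="_b")
        np.testing.assert_allclose(joined["log2fc_a"], -joined["log2fc_b"], atol=1e-6)

    def test_planted_twofold_gene_detected(self, rng):
        adata, g, r = self._groups(rng, fold_idx=3, fold=2.0)
        sig = cl.compute_signature(adata, g, r)
        assert "G3" in sig.index
        assert sig.loc["G3", "qvalue"] < 0.05
        assert sig.loc["G3", "log2fc"] == pytest.approx(1.0, abs=0.35)

    def test_small_group_raises(self, rng):
        adata, g, r = self._groups(rng)
        tiny = np.zeros_like(g); tiny[:2] = True
        with pytest.raises(GroupTooSmallError):
            cl.compute_signature(adata, tiny, r & ~tiny)

    def test_signature_vector_maps_landmarks(self):
        sig = pd.DataFrame({"log2fc": [1.5, -2.0]}, index=["L1", "X9"])
        vec = cl.signature_vector(sig, ["L1", "L2", "L3"])
        assert list(vec) == [1.5, 0.0, 0.0]


class TestEndToEndPipeline:
    def test_combination_mode_with_planted_clones(self, tiny_patient):
        from sklearn.metrics import balanced_accuracy_score

        adata, truth = tiny_patient
        res = cl.analyze_patient(adata, cl.PipelineConfig(window=21))
        tab = res.cell_table
        true = adata.obs.loc[tab.index, "true_label"]
        ba = balanced_accuracy_score(true != "normal", tab["consensus"] == "malignant")
        assert ba >= 0.9
        assert set(res.signatures) >= {"all_malignant"}
        # subclone labels exist only for consensus-malignant cells
        assert (tab.loc[tab["consensus"] == "normal", "subclone"] == "none").all()

    def test_low_malignant_fraction_triggers_monotherapy(self):
        cfg = SimConfig(
            n_cells=700, n_genes=500, seed=33,
            clone_fractions={"normal": 0.94, "A": 0.03, "B": 0.03},
        )
        adata, _ = simulate_patient(cfg)
        res = cl.analyze_patient(adata, cl.PipelineConfig(window=21))
        assert res.mode == "monotherapy"
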