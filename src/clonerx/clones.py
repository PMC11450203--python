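"""From a raw count matrix to clone labels and per-clone expression signatures.

The pipeline mirrors standard single-cell tumor analysis practice:

1. QC filtering on detected genes and mitochondrial fraction.
2. Library-size normalization (counts per ``scale`` total, log1p).
3. Graph-based clustering in PCA space (Leiden community detection).
4. Marker-based cell-type annotation with specificity-weighted scores.
5. Expression-derived CNV profiles: genes ordered along the genome,
   centred on a normal reference, smoothed with a moving average within
   each chromosome arm, summarized as per-arm segment means.  This is a
   deliberately simplified analogue of HMM-based CNV callers: it delivers
   the same contract (per-cell CNV profiles and clades) without modelling
   discrete copy states.
6. A three-classifier majority vote for malignant vs normal: marker vote,
   aneuploidy-score vote against the normal-reference null, and a two-way
   clustering of CNV profiles with the near-diploid cluster called normal.
7. Hierarchical (Ward) clustering of malignant arm-level profiles into
   broad subclones; the two largest clades become subclones A and B.
8. Per-clone differential expression against patient-matched normal cells
   (Wilcoxon rank-sum, Benjamini-Hochberg FDR), yielding the log2
   fold-change signature handed to the response model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from scipy import sparse, stats
from scipy.cluster import hierarchy
from scipy.ndimage import uniform_filter1d
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

from .errors import (
    AllCellsRemovedError,
    GroupTooSmallError,
    NoMarkersFoundError,
    NoReferenceError,
    TooFewMalignantCellsError,
    ZeroCellError,
)
from .sim import AML_MARKER_DB

__all__ = [
    "qc_filter",
    "lognormalize",
    "cluster_cells",
    "marker_score",
    "infer_cnv_profiles",
    "aneuploidy_vote",
    "cnv_cluster_vote",
    "call_malignant_ensemble",
    "detect_subclones",
    "compute_signature",
    "signature_vector",
    "analyze_patient",
    "CNVProfileSet",
    "SubcloneResult",
    "CloneResult",
    "PipelineConfig",
]

log = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito_frac: float = 0.10,
) -> ad.AnnData:
    """Remove cells with too few/many detected genes or high mitochondrial load.

    Mitochondrial genes are identified by the ``MT-`` symbol prefix
    (case-insensitive).  Bounds are inclusive: a cell is kept iff
    ``min_genes <= n_genes <= max_genes`` and ``mito_frac <= max_mito_frac``.
    """
    X = adata.X
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = adata.var_names.str.upper().str.startswith(MITO_PREFIX)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    keep = (n_genes >= min_genes) & (n_genes <= max_genes) & (mito_frac <= max_mito_frac)
    log.info(
        "QC: kept %d / %d cells (min_genes=%s, max_genes=%s, max_mito=%.2f)",
        int(keep.sum()), adata.n_obs, min_genes, max_genes, max_mito_frac,
    )
    if not keep.any():
        raise AllCellsRemovedError("QC filtering removed every cell")
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = n_genes[keep]
    out.obs["mito_frac"] = mito_frac[keep]
    return out


def lognormalize(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``scale`` total counts, then log(1 + x).

    Raw counts are preserved in ``layers['counts']``.
    """
    total = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(total == 0):
        raise ZeroCellError(f"{int((total == 0).sum())} cell(s) have zero total counts")
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    return out


# ---------------------------------------------------------------------------
# clustering and annotation
# ---------------------------------------------------------------------------


def cluster_cells(
    adata: ad.AnnData,
    resolution: float = 1.0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a kNN graph in PCA space.

    Returns an integer cluster label per cell; deterministic under a fixed
    seed.  Requires >= 50 cells.
    """
    if adata.n_obs < 50:
        raise ValueError(f"clustering needs >= 50 cells, got {adata.n_obs}")
    X = _dense(adata.X)
    if np.allclose(X, X[0]):  # identical cells: PCA is degenerate, one community
        return np.zeros(adata.n_obs, dtype=int)
    work = adata.copy()
    n_comps = int(min(n_pcs, work.n_obs - 1, work.n_vars - 1))
    sc.pp.pca(work, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(
        work, n_neighbors=min(n_neighbors, work.n_obs - 1), random_state=seed
    )
    sc.tl.leiden(
        work,
        resolution=resolution,
        random_state=seed,
        flavor="igraph",
        n_iterations=2,
        directed=False,
    )
    return work.obs["leiden"].astype(int).to_numpy()


def marker_score(
    adata: ad.AnnData,
    clusters: np.ndarray,
    marker_db: dict | None = None,
) -> pd.DataFrame:
    """Specificity-weighted marker scoring of clusters, one label per cluster.

    For each cell type, positive (minus negative) marker genes contribute
    their per-cell standardized expression, weighted by marker specificity:
    a marker listed by ``k`` of ``K`` cell types gets weight
    ``1 - (k - 1)/(K - 1)`` (a marker shared by all types is ignored).
    Per-cluster type scores are sums over member cells, scaled by
    ``1/sqrt(n_markers)``.  A cluster whose best score falls below
    ``n_cells_in_cluster / 4`` is labeled ``"Unknown"``.

    Returns a frame indexed by cluster id with columns ``label``, ``score``,
    ``malignant`` and one score column per cell type.
    """
    marker_db = AML_MARKER_DB if marker_db is None else marker_db
    clusters = np.asarray(clusters)
    types = list(marker_db)
    genes_used = sorted(
        {g for t in types for g in marker_db[t].get("positive", [])}
        | {g for t in types for g in marker_db[t].get("negative", [])}
    )
    upper = {g.upper(): g for g in adata.var_names}
    present = {g: upper[g.upper()] for g in genes_used if g.upper() in upper}
    if not present:
        raise NoMarkersFoundError("no marker gene found in the expression matrix")

    # specificity weights over *positive* occurrences
    occur = {g: 0 for g in genes_used}
    for t in types:
        for g in marker_db[t].get("positive", []):
            occur[g] += 1
    K = len(types)
    weight = {
        g: 1.0 if K == 1 else 1.0 - (occur[g] - 1) / (K - 1) if occur[g] >= 1 else 1.0
        for g in genes_used
    }

    expr = _dense(adata[:, [present[g] for g in present]].X)
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0)
    z = (expr - mu) / np.where(sd > 0, sd, 1.0)
    zcol = {g: z[:, i] for i, g in enumerate(present)}

    cell_scores = np.zeros((adata.n_obs, K))
    for j, t in enumerate(types):
        pos = [g for g in marker_db[t].get("positive", []) if g in present]
        neg = [g for g in marker_db[t].get("negative", []) if g in present]
        if not pos and not neg:
            continue
        s = np.zeros(adata.n_obs)
        for g in pos:
            s += weight[g] * zcol[g]
        for g in neg:
            s -= weight[g] * zcol[g]
        cell_scores[:, j] = s / np.sqrt(len(pos) + len(neg))

    rows = []
    for cid in np.unique(clusters):
        mask = clusters == cid
        totals = cell_scores[mask].sum(axis=0)
        best = int(np.argmax(totals))
        score = float(totals[best])
        label = types[best] if score >= mask.sum() / 4.0 else "Unknown"
        malignant = bool(marker_db.get(label, {}).get("malignant", False))
        rows.append(
            {"cluster": int(cid), "label": label, "score": score, "malignant": malignant,
             **{f"score_{t}": float(totals[j]) for j, t in enumerate(types)}}
        )
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# CNV inference
# ---------------------------------------------------------------------------


@dataclass
class CNVProfileSet:
    """Windowed, reference-centred relative-expression profiles.

    ``profiles``: cells x retained-genes smoothed values in genome order;
    ``arm_means``: cells x arms segment means; ``ref_sd``: SD of the normal
    reference values (used for winsorization); ``ref_arm_sd``: per-arm SD of
    the reference cells' segment means (the null scale for aneuploidy calls).
    """

    profiles: pd.DataFrame
    arm_means: pd.DataFrame
    gene_arms: pd.Series
    reference_cells: pd.Index
    ref_sd: float
    ref_arm_sd: pd.Series
    window: int

    def arm_z(self) -> pd.DataFrame:
        """Arm-level means scaled by the reference per-arm SD."""
        sd = self.ref_arm_sd.replace(0.0, np.nan)
        return (self.arm_means / sd).fillna(0.0)


def _genome_order(var: pd.DataFrame) -> pd.Index:
    nuclear = var[var["chromosome"].astype(str) != "MT"].copy()

    def _chrom_key(c: str) -> int:
        c = str(c)
        return {"X": 23, "Y": 24}.get(c, int(c) if c.isdigit() else 99)

    nuclear["_ck"] = nuclear["chromosome"].map(_chrom_key)
    nuclear["_ak"] = nuclear["arm"].astype(str).str[-1].map({"p": 0, "q": 1}).fillna(0)
    nuclear = nuclear.sort_values(["_ck", "_ak", "start"], kind="mergesort")
    return nuclear.index


def infer_cnv_profiles(
    adata: ad.AnnData,
    reference_mask: np.ndarray,
    window: int = 101,
    expr_cutoff: float = 0.1,
    winsor_sd: float = 3.0,
    min_reference: int = 20,
) -> CNVProfileSet:
    """Expression-derived CNV profiles, centred on a normal reference.

    Expects log-normalized data.  Genes with mean expression below
    ``expr_cutoff`` are dropped; remaining genes are ordered along the
    genome, centred on the reference-cell gene means, smoothed with a
    moving average of width ``window`` *within each chromosome arm* (the
    window is clamped to the arm length, kept odd), and winsorized at
    +/- ``winsor_sd`` reference SDs.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.sum() < min_reference:
        raise NoReferenceError(
            f"need >= {min_reference} normal reference cells, got {int(reference_mask.sum())}"
        )
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    for col in ("chromosome", "arm", "start"):
        if col not in adata.var.columns:
            raise ValueError(f"gene metadata lacks column {col!r}")

    order = _genome_order(adata.var)
    X = _dense(adata[:, order].X)
    mean_expr = X.mean(axis=0)
    keep = mean_expr >= expr_cutoff
    X = X[:, keep]
    genes = order[keep]
    arms = adata.var.loc[genes, "arm"].astype(str)

    centred = X - X[reference_mask].mean(axis=0)

    smoothed = np.empty_like(centred)
    for arm_name in arms.unique():
        cols = np.flatnonzero((arms == arm_name).to_numpy())
        w = min(window, cols.size)
        if w % 2 == 0:
            w -= 1
        w = max(w, 1)
        smoothed[:, cols] = uniform_filter1d(
            centred[:, cols], size=w, axis=1, mode="nearest"
        )

    ref_sd = float(smoothed[reference_mask].std())
    if ref_sd > 0:
        smoothed = np.clip(smoothed, -winsor_sd * ref_sd, winsor_sd * ref_sd)

    profiles = pd.DataFrame(smoothed, index=adata.obs_names, columns=genes)
    arm_means = profiles.T.groupby(arms.to_numpy(), sort=False).mean().T
    ref_arm_sd = arm_means.loc[adata.obs_names[reference_mask]].std(ddof=1)
    return CNVProfileSet(
        profiles=profiles,
        arm_means=arm_means,
        gene_arms=arms,
        reference_cells=adata.obs_names[reference_mask],
        ref_sd=ref_sd,
        ref_arm_sd=ref_arm_sd,
        window=window,
    )


def aneuploidy_vote(
    cnv: CNVProfileSet, clusters: np.ndarray, alpha: float = 0.01
) -> pd.Series:
    """Boolean malignant vote: cluster-level aneuploidy against the normal null.

    Single cells carry too little signal for arm-level copy calls, so the
    statistic is computed per expression cluster (as the reference CNV tools
    do) and broadcast to member cells: the cluster's largest standardized arm
    deviation, ``max_a |mean_a| * sqrt(n) / ref_arm_sd_a``, is compared to the
    Gaussian null threshold at family-wise level ``alpha`` over arms.
    """
    clusters = np.asarray(clusters)
    z = cnv.arm_z()
    n_arms = z.shape[1]
    crit = float(stats.norm.ppf(1.0 - alpha / (2.0 * n_arms)))
    vote = pd.Series(False, index=cnv.arm_means.index)
    for cid in np.unique(clusters):
        mask = clusters == cid
        stat = float((z[mask].mean(axis=0).abs() * np.sqrt(mask.sum())).max())
        vote[mask] = stat > crit
    return vote


def cnv_cluster_vote(
    cnv: CNVProfileSet, clusters: np.ndarray, seed: int = 0
) -> pd.Series:
    """Boolean malignant vote: two-way grouping of cluster-level CNV deviation.

    Each expression cluster is summarized by the RMS of its standardized
    arm-level deviations; a 2-means split of these scores separates a
    near-zero (diploid) group from an aneuploid group, and the near-zero
    group is called normal.  With a single expression cluster the vote is
    False everywhere (no evidence of a distinct aneuploid population).
    """
    clusters = np.asarray(clusters)
    z = cnv.arm_z()
    ids = np.unique(clusters)
    if ids.size < 2:
        return pd.Series(False, index=cnv.arm_means.index)
    scores = np.array(
        [
            float(
                np.sqrt(((z[clusters == cid].mean(axis=0)) ** 2).mean())
                * np.sqrt((clusters == cid).sum())
            )
            for cid in ids
        ]
    )
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(scores.reshape(-1, 1))
    malignant_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    cluster_is_mal = {cid: km.labels_[i] == malignant_cluster for i, cid in enumerate(ids)}
    return pd.Series([cluster_is_mal[c] for c in clusters], index=cnv.arm_means.index)


def call_malignant_ensemble(marker_vote, cnv_score_vote, cnv_cluster_vote) -> np.ndarray:
    """Majority vote (>= 2 of 3) over three boolean malignancy classifiers."""
    votes = np.column_stack(
        [np.asarray(v, dtype=bool) for v in (marker_vote, cnv_score_vote, cnv_cluster_vote)]
    )
    return votes.sum(axis=1) >= 2


# ---------------------------------------------------------------------------
# subclones
# ---------------------------------------------------------------------------


@dataclass
class SubcloneResult:
    labels: pd.Series  # cell -> "A" | "B" | "minor"
    fractions: dict
    newick: str
    degenerate: bool


def detect_subclones(
    arm_means: pd.DataFrame,
    k: int = 2,
    min_fraction: float = 0.05,
    min_cells: int = 40,
    min_eig_ratio: float = 2.0,
    seed: int = 0,
) -> SubcloneResult:
    """Split malignant cells into broad CNV subclones by Ward clustering.

    Profiles are centred per cell (removing the global composition/depth
    factor) and projected onto the two leading principal components, where
    clone-difference directions accumulate while per-cell noise stays
    spread out.  The Ward dendrogram (Euclidean distance) is cut into ``k``
    clades and polished by one Gaussian-mixture refinement initialized at
    the clade centroids.  Clades below ``min_fraction`` of malignant cells
    are labeled ``"minor"``; the two largest become subclones A and B (ties
    broken by lower mean intra-clade distance).

    Degeneracy: a clonally homogeneous population has no dominant variance
    direction, so when the top-two eigenvalue ratio of the centred profiles
    falls below ``min_eig_ratio`` (or fewer than two clades pass
    ``min_fraction``) everything is assigned to A with ``degenerate=True``
    and the caller should fall back to monotherapy mode.

    Branch lengths of the emitted Newick tree are clone fractions (the tree
    encodes dominance, not a molecular clock).
    """
    n = len(arm_means)
    if n < min_cells:
        raise TooFewMalignantCellsError(
            f"need >= {min_cells} malignant cells, got {n}"
        )
    X = arm_means.to_numpy()
    X = X - X.mean(axis=1, keepdims=True)
    X = X - X.mean(axis=0)
    _, svals, vt = np.linalg.svd(X, full_matrices=False)
    lam = svals**2
    eig_ratio = float(lam[0] / lam[1]) if lam.size > 1 and lam[1] > 0 else np.inf
    n_comp = int(min(2, X.shape[1], X.shape[0] - 1))
    P = X @ vt[:n_comp].T
    Z = hierarchy.linkage(P, method="ward")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(flat)) == k:
        means = np.vstack([P[flat == c].mean(axis=0) for c in np.unique(flat)])
        gm = GaussianMixture(n_components=k, means_init=means, random_state=seed)
        flat = gm.fit_predict(P) + 1

    sizes = pd.Series(flat).value_counts()
    big = sizes[sizes / n >= min_fraction]
    degenerate = len(big) < 2 or eig_ratio < min_eig_ratio

    labels = pd.Series(index=arm_means.index, dtype=object)
    if degenerate:
        labels[:] = "A"
        fractions = {"A": 1.0}
        newick = "(A:1.0);"
        return SubcloneResult(labels=labels, fractions=fractions, newick=newick,
                              degenerate=True)

    def _intra(cid: int) -> float:
        pts = P[flat == cid]
        return float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).mean())

    ranked = sorted(big.index, key=lambda c: (-sizes[c], _intra(c)))
    name = {ranked[0]: "A", ranked[1]: "B"}
    for cid in sizes.index:
        if cid not in name:
            name[cid] = "minor"
    labels[:] = [name[c] for c in flat]
    fractions = (labels.value_counts() / n).to_dict()
    parts = ",".join(f"{c}:{fractions[c]:.4f}" for c in ("A", "B", "minor") if c in fractions)
    return SubcloneResult(
        labels=labels, fractions=fractions, newick=f"({parts});", degenerate=False
    )


# ---------------------------------------------------------------------------
# differential expression signatures
# ---------------------------------------------------------------------------


def compute_signature(
    adata: ad.AnnData,
    group_mask: np.ndarray,
    ref_mask: np.ndarray,
    min_pct: float = 0.1,
    min_abs_log2fc: float = 0.25,
) -> pd.DataFrame:
    """Clone-vs-normal differential expression on log-normalized data.

    Per gene: log2 fold change of ``(mean(expm1) + 1)`` between group and
    reference, a two-sided Wilcoxon rank-sum p-value, and a Benjamini-
    Hochberg q-value.  Genes expressed in fewer than ``min_pct`` of cells in
    *both* groups, or with |log2FC| below ``min_abs_log2fc``, are excluded
    from testing.  Returns a frame indexed by gene with columns ``log2fc``,
    ``pvalue``, ``qvalue``, ``pct_group``, ``pct_ref``.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if group_mask.sum() < 3 or ref_mask.sum() < 3:
        raise GroupTooSmallError("both groups need >= 3 cells")
    if np.any(group_mask & ref_mask):
        raise ValueError("group and reference masks overlap")

    Xg = _dense(adata[group_mask].X)
    Xr = _dense(adata[ref_mask].X)
    pct_g = (Xg > 0).mean(axis=0)
    pct_r = (Xr > 0).mean(axis=0)
    lfc = np.log2(np.expm1(Xg).mean(axis=0) + 1.0) - np.log2(
        np.expm1(Xr).mean(axis=0) + 1.0
    )
    tested = ((pct_g >= min_pct) | (pct_r >= min_pct)) & (np.abs(lfc) >= min_abs_log2fc)
    genes = adata.var_names[tested]
    if tested.sum() == 0:
        return pd.DataFrame(
            columns=["log2fc", "pvalue", "qvalue", "pct_group", "pct_ref"]
        )
    res = stats.mannwhitneyu(
        Xg[:, tested], Xr[:, tested], alternative="two-sided", axis=0
    )
    pvals = np.asarray(res.pvalue)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "log2fc": lfc[tested],
            "pvalue": pvals,
            "qvalue": qvals,
            "pct_group": pct_g[tested],
            "pct_ref": pct_r[tested],
        },
        index=pd.Index(genes, name="gene"),
    ).sort_values("pvalue", kind="mergesort")


def signature_vector(signature: pd.DataFrame, landmark_genes) -> pd.Series:
    """Map a DE table onto the landmark panel; missing landmarks are 0."""
    return (
        signature["log2fc"].reindex(landmark_genes).fillna(0.0)
        if len(signature)
        else pd.Series(0.0, index=pd.Index(landmark_genes))
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    min_genes: int = 200
    max_genes: int = 6000
    max_mito_frac: float = 0.10
    scale: float = 1e4
    resolution: float = 1.0
    n_pcs: int = 30
    marker_db: dict = field(default_factory=lambda: dict(AML_MARKER_DB))
    normal_anchor_types: tuple = ("T cell", "NK cell", "Stromal cell")
    window: int = 101
    expr_cutoff: float = 0.1
    k_subclones: int = 2
    min_fraction: float = 0.05
    mono_floor: float = 0.10  # malignant fraction below which monotherapy mode fires
    min_pct: float = 0.1
    min_abs_log2fc: float = 0.25
    seed: int = 0


@dataclass
class CloneResult:
    """Per-cell clone map plus the per-clone DE signatures."""

    cell_table: pd.DataFrame  # qc/cluster/type/votes/consensus/subclone per QC cell
    cnv: CNVProfileSet
    subclones: SubcloneResult | None
    signatures: dict  # clone id -> DE DataFrame
    mode: str  # "combination" | "monotherapy"
    clone_fractions: dict
    newick: str | None


def analyze_patient(adata: ad.AnnData, config: PipelineConfig | None = None) -> CloneResult:
    """Run the full clone pipeline on a raw count matrix."""
    cfg = config or PipelineConfig()
    qc = qc_filter(adata, cfg.min_genes, cfg.max_genes, cfg.max_mito_frac)
    norm = lognormalize(qc, cfg.scale)
    clusters = cluster_cells(norm, resolution=cfg.resolution, n_pcs=cfg.n_pcs, seed=cfg.seed)
    ann = marker_score(norm, clusters, cfg.marker_db)

    cell_type = pd.Series(
        [ann.loc[c, "label"] for c in clusters], index=norm.obs_names, name="cell_type"
    )
    marker_malignant = pd.Series(
        [bool(ann.loc[c, "malignant"]) for c in clusters], index=norm.obs_names
    )

    anchor = cell_type.isin(cfg.normal_anchor_types).to_numpy()
    if anchor.sum() < 20:
        raise NoReferenceError(
            "fewer than 20 anchor normal cells "
            f"(types {cfg.normal_anchor_types}) found for CNV reference"
        )
    cnv = infer_cnv_profiles(
        norm, anchor, window=cfg.window, expr_cutoff=cfg.expr_cutoff
    )
    v_score = aneuploidy_vote(cnv, clusters)
    v_clust = cnv_cluster_vote(cnv, clusters, seed=cfg.seed)
    consensus = call_malignant_ensemble(
        marker_malignant.to_numpy(), v_score.to_numpy(), v_clust.to_numpy()
    )

    table = pd.DataFrame(
        {
            "cluster": clusters,
            "cell_type": cell_type.to_numpy(),
            "vote_marker": marker_malignant.to_numpy(),
            "vote_cnv_score": v_score.to_numpy(),
            "vote_cnv_cluster": v_clust.to_numpy(),
            "consensus": np.where(consensus, "malignant", "normal"),
            "subclone": "none",
        },
        index=norm.obs_names,
    )

    malignant_frac = float(consensus.mean())
    normal_mask = ~consensus
    mode = "combination"
    sub: SubcloneResult | None = None
    if malignant_frac < cfg.mono_floor:
        mode = "monotherapy"
    else:
        try:
            sub = detect_subclones(
                cnv.arm_z().loc[table.index[consensus]],
                k=cfg.k_subclones,
                min_fraction=cfg.min_fraction,
                seed=cfg.seed,
            )
        except TooFewMalignantCellsError:
            mode = "monotherapy"
        else:
            if sub.degenerate:
                mode = "monotherapy"
            table.loc[sub.labels.index, "subclone"] = sub.labels

    signatures: dict[str, pd.DataFrame] = {}
    if mode == "combination":
        for clone in ("A", "B"):
            mask = (table["subclone"] == clone).to_numpy()
            signatures[clone] = compute_signature(
                norm, mask, normal_mask, cfg.min_pct, cfg.min_abs_log2fc
            )
    signatures["all_malignant"] = compute_signature(
        norm, consensus, normal_mask, cfg.min_pct, cfg.min_abs_log2fc
    )

    fractions = {
        "malignant": malignant_frac,
        **({} if sub is None else {f"clone_{k}": v for k, v in sub.fractions.items()}),
    }
    return CloneResult(
        cell_table=table,
        cnv=cnv,
        subclones=sub,
        signatures=signatures,
        mode=mode,
        clone_fractions=fractions,
        newick=None if sub is None else sub.newick,
    )
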