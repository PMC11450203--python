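"""Synthetic ground-truth generators for the whole pipeline.

Two generators are provided:

* :func:`simulate_reference` builds a drug-perturbation reference corpus:
  landmark-gene transcriptional signatures, multi-dose Hill-shaped viability
  curves, and binary structure fingerprints, for a panel of drugs measured
  across cell lines.  It emulates, at desk scale, the kind of corpus obtained
  by matching a perturbation-signature resource (LINCS-style) with a
  dose-response viability resource (PharmacoDB-style).

* :func:`simulate_patient` builds a clonally structured single-cell count
  matrix: negative-binomial counts with a normal population and >= 2 malignant
  clones carrying arm-level copy-number dosage effects, clone-specific
  expression modules, cell-type marker genes and a mitochondrial gene block
  so QC is exercisable.

Generative assumptions that matter downstream:

* Drug mechanisms are shared within *module templates*: drugs are grouped
  into structural/mechanistic classes, each class perturbing the same small
  set of landmark genes and sharing a fingerprint scaffold (structurally
  similar compounds hit similar targets -- the premise of fingerprint
  featurization).
* Per (drug, cell line) sensitivity scales the attainable inhibition, and the
  transcriptional signature magnitude tracks the *realized* inhibition, so a
  regressor must combine signature and fingerprint to predict well.
* Malignant clones are assigned the transcriptional program *opposed* by one
  drug class, so signature-reversal ranking has a recoverable ground truth.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "SimConfig",
    "GroundTruth",
    "hill_inhibition",
    "simulate_reference",
    "simulate_patient",
    "AML_MARKER_DB",
    "HGSC_MARKER_DB",
]

# chromosome arms used for gene placement (acrocentric p-arms kept for simplicity)
ARM_NAMES: tuple[str, ...] = tuple(f"{c}{a}" for c in range(1, 23) for a in ("p", "q"))

BLAST_MARKERS = ("CD33", "CD34", "CD38", "PROM1", "ENG", "CD99", "KIT")
TCELL_MARKERS = ("CD3D", "CD3E", "TRAC", "IL7R")
PAX8_MARKERS = ("PAX8", "MUC16", "EPCAM", "WFDC2")

#: built-in marker database for the leukemia-style path; maps cell type to
#: positive marker genes and whether the type is treated as malignant.
AML_MARKER_DB: dict[str, dict] = {
    "Leukemic blast": {"positive": list(BLAST_MARKERS), "negative": [], "malignant": True},
    "T cell": {"positive": list(TCELL_MARKERS), "negative": [], "malignant": False},
}

#: marker database for the ovarian-carcinoma-style path (PAX8+ tumor cells).
HGSC_MARKER_DB: dict[str, dict] = {
    "Epithelial tumor cell": {"positive": list(PAX8_MARKERS), "negative": [], "malignant": True},
    "Stromal cell": {"positive": ["COL1A1", "DCN", "PDGFRB"], "negative": [], "malignant": False},
}


def hill_inhibition(dose_uM, ec50_uM, slope, max_inhibition):
    """Percent inhibition of a log-logistic (Hill) dose-response curve.

    ``I(d) = max_inhibition * d^h / (d^h + EC50^h)``; defined as 0 at d = 0.
    """
    dose = np.asarray(dose_uM, dtype=float)
    with np.errstate(divide="ignore"):
        num = np.power(dose, slope)
        frac = np.where(dose > 0, num / (num + np.power(ec50_uM, slope)), 0.0)
    return max_inhibition * frac


def _child_rng(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream per (seed, purpose)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(tag.encode())])
    )


@dataclass
class SimConfig:
    """Study conditions for both generators.

    Reference-corpus scale mirrors a scaled-down perturbation/viability
    database (drugs x cell lines x doses); patient scale mirrors a single
    10x-style sample with one normal population and two malignant clones
    carrying arm-level copy ratios 1.5x (gain) and 0.5x (loss).
    """

    # ---- reference corpus ----
    n_drugs: int = 50
    n_cell_lines: int = 20
    n_landmark_genes: int = 200
    n_fp_bits: int = 256
    doses_per_drug: int = 8
    dose_min_uM: float = 1e-3
    dose_max_uM: float = 10.0
    hill_ec50_range: tuple[float, float] = (0.01, 10.0)
    hill_slope_range: tuple[float, float] = (0.7, 2.5)
    max_inhibition_range: tuple[float, float] = (60.0, 100.0)
    sensitivity_range: tuple[float, float] = (0.3, 1.0)
    ec50_cell_line_sd: float = 0.15  # SD of per-cell-line log10 EC50 shift
    noise_sd_viability: float = 5.0  # percent viability
    noise_sd_signature: float = 0.1  # log2 fold-change units
    n_module_templates: int = 10
    module_size: int = 10
    module_effect_range: tuple[float, float] = (1.0, 3.0)  # |log2FC| at full inhibition
    fp_flip_rate: float = 0.05  # per-bit flip away from the template scaffold

    # ---- patient sample ----
    n_cells: int = 1000
    n_genes: int = 1500
    clone_fractions: dict = field(
        default_factory=lambda: {"normal": 0.40, "A": 0.35, "B": 0.25}
    )
    cnv_events: dict = field(
        default_factory=lambda: {
            "A": [("1p", 1.5), ("7q", 0.5)],
            "B": [("3q", 1.5), ("10p", 0.5)],
        }
    )
    de_module_scale: float = 1.0  # clone module shift = -scale * drug effect
    marker_fold: float = 8.0
    n_mito_genes: int = 10
    mito_base_frac: float = 0.05
    mito_high_frac: float = 0.15
    frac_cells_high_mito: float = 0.05
    mean_depth: int = 4000
    depth_log_sd: float = 0.25
    nb_dispersion_log_mean: float = np.log(0.3)
    nb_dispersion_log_sd: float = 0.5

    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_drugs": self.n_drugs,
            "n_cell_lines": self.n_cell_lines,
            "n_landmark_genes": self.n_landmark_genes,
            "n_fp_bits": self.n_fp_bits,
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 1 <= self.doses_per_drug <= 35:
            raise ValueError("doses_per_drug must be within [1, 35]")
        total = sum(self.clone_fractions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"clone_fractions must sum to 1, got {total}")
        if any(f < 0 for f in self.clone_fractions.values()):
            raise ValueError("clone_fractions must be nonnegative")
        if self.n_genes < self.n_landmark_genes + self.n_mito_genes + 50:
            raise ValueError("n_genes too small to host landmarks, markers and mito genes")


@dataclass
class GroundTruth:
    """Simulation oracle shared by both generators.

    Reference fields describe per-drug pharmacology and mechanism modules;
    patient fields record true per-cell labels, planted CNV dosage and which
    drug-class template each clone opposes.  Either block may be absent
    depending on which generator produced the object.
    """

    landmark_genes: list | None = None
    drugs: pd.DataFrame | None = None  # index drug_id: ec50_uM, slope, max_inhibition, template_id
    pair_params: pd.DataFrame | None = None  # per (drug_id, cell_line_id): ec50_uM, sensitivity
    modules: dict | None = None  # template_id -> {"genes": [...], "effects": [...]}
    dose_grid_uM: np.ndarray | None = None

    cell_labels: pd.Series | None = None  # barcode -> clone label ("normal", "A", ...)
    clone_templates: dict | None = None  # clone -> opposed template_id
    cnv_map: dict | None = None  # clone -> [(arm, ratio), ...]
    high_mito_barcodes: list | None = None

    def true_inhibition(self, drug_id: str, cell_line_id: str, dose_uM) -> np.ndarray:
        """Noise-free percent inhibition for a (drug, cell line) pair."""
        p = self.pair_params.loc[(drug_id, cell_line_id)]
        d = self.drugs.loc[drug_id]
        return hill_inhibition(
            dose_uM, p["ec50_uM"], d["slope"], d["max_inhibition"] * p["sensitivity"]
        )

    def opposing_drugs(self, clone: str) -> list[str]:
        """Drugs whose mechanism module opposes the planted module of ``clone``."""
        t = self.clone_templates[clone]
        return list(self.drugs.index[self.drugs["template_id"] == t])

    def to_json(self) -> str:
        def _convert(obj):
            if isinstance(obj, pd.DataFrame):
                return obj.reset_index().to_dict(orient="list")
            if isinstance(obj, pd.Series):
                return {"index": list(obj.index), "values": list(obj.values)}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return json.dumps({k: _convert(v) for k, v in asdict(self).items()}, default=str)


# ---------------------------------------------------------------------------
# reference corpus
# ---------------------------------------------------------------------------


def simulate_reference(cfg: SimConfig):
    """Generate a matched perturbation / dose-response / fingerprint corpus.

    Returns
    -------
    perturbations : pd.DataFrame
        One row per (drug, cell line, dose): landmark log2 fold-change vector.
    curves : pd.DataFrame
        One row per (drug, cell line, dose): percent viability.
    fingerprints : pd.DataFrame
        One row per drug: binary bit vector (columns ``bit_0..``).
    truth : GroundTruth
    """
    cfg.validate()
    rng = _child_rng(cfg.seed, "reference")

    landmarks = [f"L{i + 1:04d}" for i in range(cfg.n_landmark_genes)]
    drug_ids = [f"D{i + 1:04d}" for i in range(cfg.n_drugs)]
    cell_ids = [f"C{i + 1:03d}" for i in range(cfg.n_cell_lines)]

    # mechanism templates: gene module + signed effects + fingerprint scaffold
    modules: dict[int, dict] = {}
    scaffolds = np.zeros((cfg.n_module_templates, cfg.n_fp_bits), dtype=np.int8)
    for t in range(cfg.n_module_templates):
        genes = rng.choice(cfg.n_landmark_genes, size=cfg.module_size, replace=False)
        effects = rng.uniform(*cfg.module_effect_range, size=cfg.module_size)
        effects *= rng.choice([-1.0, 1.0], size=cfg.module_size)
        modules[t] = {"genes": [landmarks[g] for g in genes], "effects": effects.tolist()}
        scaffolds[t] = rng.integers(0, 2, size=cfg.n_fp_bits)

    lo, hi = np.log10(cfg.hill_ec50_range[0]), np.log10(cfg.hill_ec50_range[1])
    drugs = pd.DataFrame(
        {
            "ec50_uM": 10.0 ** rng.uniform(lo, hi, size=cfg.n_drugs),
            "slope": rng.uniform(*cfg.hill_slope_range, size=cfg.n_drugs),
            "max_inhibition": rng.uniform(*cfg.max_inhibition_range, size=cfg.n_drugs),
            "template_id": [i % cfg.n_module_templates for i in range(cfg.n_drugs)],
        },
        index=pd.Index(drug_ids, name="drug_id"),
    )

    # fingerprints: template scaffold with per-drug bit flips
    fp = scaffolds[drugs["template_id"].to_numpy()]
    flips = rng.random((cfg.n_drugs, cfg.n_fp_bits)) < cfg.fp_flip_rate
    fp = np.where(flips, 1 - fp, fp).astype(np.int8)
    fingerprints = pd.DataFrame(
        fp, index=pd.Index(drug_ids, name="drug_id"),
        columns=[f"bit_{b}" for b in range(cfg.n_fp_bits)],
    ).reset_index()

    # per (drug, cell line) pharmacology
    n_pairs = cfg.n_drugs * cfg.n_cell_lines
    pair_index = pd.MultiIndex.from_product(
        [drug_ids, cell_ids], names=["drug_id", "cell_line_id"]
    )
    ec50_shift = 10.0 ** rng.normal(0.0, cfg.ec50_cell_line_sd, size=n_pairs)
    pair_params = pd.DataFrame(
        {
            "ec50_uM": np.repeat(drugs["ec50_uM"].to_numpy(), cfg.n_cell_lines) * ec50_shift,
            "sensitivity": rng.uniform(*cfg.sensitivity_range, size=n_pairs),
        },
        index=pair_index,
    )

    dose_grid = np.logspace(
        np.log10(cfg.dose_min_uM), np.log10(cfg.dose_max_uM), cfg.doses_per_drug
    )

    # vectorized inhibition over (pair, dose)
    slope = np.repeat(drugs["slope"].to_numpy(), cfg.n_cell_lines)[:, None]
    max_inh = (
        np.repeat(drugs["max_inhibition"].to_numpy(), cfg.n_cell_lines)
        * pair_params["sensitivity"].to_numpy()
    )[:, None]
    ec50 = pair_params["ec50_uM"].to_numpy()[:, None]
    dnum = np.power(dose_grid[None, :], slope)
    inh = max_inh * dnum / (dnum + np.power(ec50, slope))  # (n_pairs, n_doses)

    meta = pd.DataFrame(
        {
            "drug_id": np.repeat(pair_index.get_level_values(0), cfg.doses_per_drug),
            "cell_line_id": np.repeat(pair_index.get_level_values(1), cfg.doses_per_drug),
            "dose_uM": np.tile(dose_grid, n_pairs),
        }
    )

    viability = 100.0 - inh.ravel()
    if cfg.noise_sd_viability > 0:
        viability = viability + rng.normal(0.0, cfg.noise_sd_viability, size=viability.shape)
    curves = meta.copy()
    curves["viability_pct"] = viability

    # signatures: module genes shift proportionally to realized inhibition
    effect_mat = np.zeros((cfg.n_drugs, cfg.n_landmark_genes))
    gene_pos = {g: i for i, g in enumerate(landmarks)}
    for d, did in enumerate(drug_ids):
        mod = modules[drugs.loc[did, "template_id"]]
        for g, e in zip(mod["genes"], mod["effects"]):
            effect_mat[d, gene_pos[g]] = e
    effect_rows = np.repeat(effect_mat, cfg.n_cell_lines * cfg.doses_per_drug, axis=0)
    sig = effect_rows * (inh.ravel() / 100.0)[:, None]
    if cfg.noise_sd_signature > 0:
        sig = sig + rng.normal(0.0, cfg.noise_sd_signature, size=sig.shape)
    perturbations = pd.concat(
        [meta, pd.DataFrame(sig, columns=landmarks)], axis=1
    )

    truth = GroundTruth(
        landmark_genes=landmarks,
        drugs=drugs,
        pair_params=pair_params,
        modules=modules,
        dose_grid_uM=dose_grid,
    )
    return perturbations, curves, fingerprints, truth


# ---------------------------------------------------------------------------
# patient sample
# ---------------------------------------------------------------------------


def _rank_templates_by_potency(truth: GroundTruth) -> list[int]:
    """Template ids ordered by ascending median EC50 of their member drugs."""
    med = truth.drugs.groupby("template_id")["ec50_uM"].median().sort_values()
    return list(med.index)


def simulate_patient(cfg: SimConfig, reference: GroundTruth | None = None):
    """Generate a clonally structured single-cell count matrix.

    Parameters
    ----------
    cfg
        Study conditions; ``clone_fractions`` must include a ``"normal"``
        component (the downstream pipeline needs a normal reference).
    reference
        Ground truth of a reference corpus.  When given, each malignant clone
        is assigned the expression program opposed by one drug-class template
        (most potent templates first), so signature-reversal ranking has a
        recoverable answer.  Without it, clones differ by CNV dosage only.

    Returns
    -------
    adata : anndata.AnnData
        cells x genes integer counts; ``var`` carries symbol/chromosome/arm/
        start in genome order; ``obs`` carries the true labels.
    truth : GroundTruth
    """
    cfg.validate()
    if "normal" not in cfg.clone_fractions:
        raise ValueError("clone_fractions must include a 'normal' component")
    rng = _child_rng(cfg.seed, "patient")

    landmarks = [f"L{i + 1:04d}" for i in range(cfg.n_landmark_genes)]
    mito = [f"MT-G{i + 1}" for i in range(cfg.n_mito_genes)]
    markers = list(BLAST_MARKERS) + list(TCELL_MARKERS)
    n_filler = cfg.n_genes - len(landmarks) - len(mito) - len(markers)
    filler = [f"F{i + 1:04d}" for i in range(n_filler)]

    nuclear = np.array(landmarks + markers + filler)
    order = rng.permutation(len(nuclear))
    nuclear = nuclear[order]

    # contiguous arm blocks along the shuffled nuclear gene list
    blocks = np.array_split(np.arange(len(nuclear)), len(ARM_NAMES))
    chrom, arm, start = [], [], []
    for arm_name, block in zip(ARM_NAMES, blocks):
        chrom.extend([arm_name[:-1]] * len(block))
        arm.extend([arm_name] * len(block))
        start.extend((100_000 * (np.arange(len(block)) + 1)).tolist())
    var = pd.DataFrame(
        {
            "symbol": list(nuclear) + mito,
            "chromosome": chrom + ["MT"] * len(mito),
            "arm": arm + ["MT"] * len(mito),
            "start": start + (100_000 * (np.arange(len(mito)) + 1)).tolist(),
        }
    ).set_index("symbol")

    symbols = var.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(symbols)}
    is_mito = var["chromosome"].to_numpy() == "MT"

    clones = list(cfg.clone_fractions)
    probs = np.array([cfg.clone_fractions[c] for c in clones])
    labels = rng.choice(clones, size=cfg.n_cells, p=probs)

    # baseline relative expression (nuclear genes)
    base = rng.lognormal(0.0, 1.0, size=cfg.n_genes)
    base[is_mito] = 0.0

    # per-clone multiplicative programs
    malignant = [c for c in clones if c != "normal"]
    clone_templates: dict[str, int] = {}
    mult = {c: np.ones(cfg.n_genes) for c in clones}
    for c in malignant:
        for arm_name, ratio in cfg.cnv_events.get(c, []):
            mult[c][var["arm"].to_numpy() == arm_name] *= ratio
        for g in BLAST_MARKERS:
            mult[c][gene_pos[g]] *= cfg.marker_fold
    for g in TCELL_MARKERS:
        mult["normal"][gene_pos[g]] *= cfg.marker_fold

    if reference is not None:
        ranked = _rank_templates_by_potency(reference)
        for c, t in zip(sorted(malignant), ranked):
            clone_templates[c] = int(t)
            mod = reference.modules[t]
            for g, e in zip(mod["genes"], mod["effects"]):
                # clone shifts opposite to the drug-induced change
                mult[c][gene_pos[g]] *= 2.0 ** (-cfg.de_module_scale * e)

    depth = rng.lognormal(np.log(cfg.mean_depth), cfg.depth_log_sd, size=cfg.n_cells)
    n_high = int(round(cfg.frac_cells_high_mito * cfg.n_cells))
    high_mito = np.zeros(cfg.n_cells, dtype=bool)
    high_mito[rng.choice(cfg.n_cells, size=n_high, replace=False)] = True
    mito_frac = np.where(high_mito, cfg.mito_high_frac, cfg.mito_base_frac)

    dispersion = np.exp(
        rng.normal(cfg.nb_dispersion_log_mean, cfg.nb_dispersion_log_sd, size=cfg.n_genes)
    ).clip(min=0.05)

    counts = np.zeros((cfg.n_cells, cfg.n_genes), dtype=np.int64)
    mito_share = rng.dirichlet(np.full(cfg.n_mito_genes, 5.0))
    for c in clones:
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        rel = base * mult[c]
        rel = rel / rel.sum()
        mean = depth[idx, None] * (1.0 - mito_frac[idx, None]) * rel[None, :]
        mean[:, is_mito] = (depth[idx] * mito_frac[idx])[:, None] * mito_share[None, :]
        lam = rng.gamma(1.0 / dispersion[None, :], dispersion[None, :] * mean)
        counts[idx] = rng.poisson(lam)

    barcodes = [f"CELL{i + 1:05d}" for i in range(cfg.n_cells)]
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame(
            {"true_label": labels, "true_high_mito": high_mito},
            index=pd.Index(barcodes, name="barcode"),
        ),
        var=var.copy(),
    )

    truth = GroundTruth(
        landmark_genes=landmarks,
        drugs=None if reference is None else reference.drugs,
        pair_params=None if reference is None else reference.pair_params,
        modules=None if reference is None else reference.modules,
        dose_grid_uM=None if reference is None else reference.dose_grid_uM,
        cell_labels=pd.Series(labels, index=barcodes, name="true_label"),
        clone_templates=clone_templates or None,
        cnv_map={c: list(cfg.cnv_events.get(c, [])) for c in malignant},
        high_mito_barcodes=[b for b, h in zip(barcodes, high_mito) if h],
    )
    return adata, truth
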