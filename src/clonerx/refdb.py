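"""Training-table assembly: match perturbation signatures to viability curves.

Each perturbation record (drug, cell line, dose, landmark signature) is
paired with the percent inhibition obtained by interpolating that
(drug, cell line) viability curve at the perturbation dose, linearly in
log10-dose space.  Doses outside the measured span are skipped, never
extrapolated.  Drug structure enters as a fixed-length binary fingerprint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyJoinError, OutOfRangeError, ParseError

__all__ = [
    "interpolate_inhibition",
    "build_training_table",
    "fingerprint_from_smiles",
    "TrainingTable",
]

log = logging.getLogger(__name__)

META_COLS = ("drug_id", "cell_line_id", "dose_uM")


@dataclass
class TrainingTable:
    """Feature/target table for the inhibition regressor.

    ``features`` columns are: landmark signature genes (in panel order),
    fingerprint bits ``bit_*``, and ``log10_dose_uM``.  ``target`` is percent
    inhibition in [0, 100].  ``meta`` keeps the originating (drug, cell line,
    dose) triple per row, aligned with ``features``.
    """

    features: pd.DataFrame
    target: pd.Series
    meta: pd.DataFrame
    landmark_genes: list
    n_fp_bits: int

    def __len__(self) -> int:
        return len(self.features)


def interpolate_inhibition(doses_uM, viability_pct, query_dose_uM: float) -> float:
    """Percent inhibition at ``query_dose_uM`` from measured viability points.

    Viability is interpolated linearly in log10-dose between measured knots
    and converted to inhibition as ``100 - viability``, clipped to [0, 100].

    Raises
    ------
    OutOfRangeError
        If the query dose lies outside the measured dose span.
    ValueError
        If fewer than two distinct doses are supplied.
    """
    doses = np.asarray(doses_uM, dtype=float)
    viab = np.asarray(viability_pct, dtype=float)
    if doses.size < 2 or np.unique(doses).size < 2:
        raise ValueError("need >= 2 distinct doses to interpolate")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (uM)")
    order = np.argsort(doses)
    doses, viab = doses[order], viab[order]
    if not (doses[0] <= query_dose_uM <= doses[-1]):
        raise OutOfRangeError(
            f"query dose {query_dose_uM} uM outside measured span "
            f"[{doses[0]}, {doses[-1]}] uM"
        )
    v = float(np.interp(np.log10(query_dose_uM), np.log10(doses), viab))
    return float(np.clip(100.0 - v, 0.0, 100.0))


def build_training_table(
    perturbations: pd.DataFrame,
    curves: pd.DataFrame,
    fingerprints: pd.DataFrame,
    min_doses: int = 2,
) -> TrainingTable:
    """Inner-join perturbations with interpolated inhibition and fingerprints.

    One output row per perturbation record whose (drug, cell line) pair has a
    viability curve with >= ``min_doses`` distinct doses and whose dose falls
    inside the measured span.  Duplicate (drug, cell line, dose) perturbations
    are retained.  Row order is deterministic: sorted by drug, cell line, dose.
    """
    for col in META_COLS:
        for tbl, name in ((perturbations, "perturbations"), (curves, "curves")):
            if col not in tbl.columns:
                raise ValueError(f"{name} table lacks required column {col!r}")
    if "drug_id" not in fingerprints.columns:
        raise ValueError("fingerprints table lacks required column 'drug_id'")

    landmark_genes = [c for c in perturbations.columns if c not in META_COLS]
    bit_cols = [c for c in fingerprints.columns if c != "drug_id"]
    fp_map = fingerprints.set_index("drug_id")[bit_cols]

    curve_groups = {
        key: (grp["dose_uM"].to_numpy(), grp["viability_pct"].to_numpy())
        for key, grp in curves.groupby(["drug_id", "cell_line_id"], sort=False)
    }

    pert = perturbations.sort_values(list(META_COLS), kind="mergesort").reset_index(drop=True)
    keep_idx: list[int] = []
    targets: list[float] = []
    n_no_curve = n_out_of_range = n_no_fp = 0
    for i, (drug, cl, dose) in enumerate(
        zip(pert["drug_id"], pert["cell_line_id"], pert["dose_uM"])
    ):
        if drug not in fp_map.index:
            n_no_fp += 1
            continue
        key = (drug, cl)
        if key not in curve_groups:
            n_no_curve += 1
            continue
        doses, viab = curve_groups[key]
        if np.unique(doses).size < min_doses:
            n_no_curve += 1
            continue
        try:
            inh = interpolate_inhibition(doses, viab, dose)
        except OutOfRangeError:
            n_out_of_range += 1
            continue
        keep_idx.append(i)
        targets.append(inh)

    if n_no_curve or n_out_of_range or n_no_fp:
        log.info(
            "build_training_table skipped rows: %d without curve, %d out of dose "
            "range, %d without fingerprint",
            n_no_curve, n_out_of_range, n_no_fp,
        )
    if not keep_idx:
        raise EmptyJoinError("no perturbation record could be matched to a curve")

    kept = pert.loc[keep_idx].reset_index(drop=True)
    sig = kept[landmark_genes].astype(float)
    fp = fp_map.loc[kept["drug_id"]].reset_index(drop=True).astype(np.int8)
    log_dose = pd.Series(np.log10(kept["dose_uM"].to_numpy()), name="log10_dose_uM")
    features = pd.concat([sig, fp, log_dose], axis=1)
    return TrainingTable(
        features=features,
        target=pd.Series(targets, name="inhibition_pct"),
        meta=kept[list(META_COLS)].copy(),
        landmark_genes=landmark_genes,
        n_fp_bits=len(bit_cols),
    )


def fingerprint_from_smiles(smiles: str, n_bits: int = 1024) -> np.ndarray:
    """Radius-2 circular (Morgan/ECFP4) fingerprint hashed to ``n_bits`` bits.

    Requires RDKit (optional ``chem`` extra).  Raises :class:`ParseError` on
    an unparseable SMILES string.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    return np.array(gen.GetFingerprint(mol), dtype=np.int8)
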