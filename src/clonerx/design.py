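"""Ranked drug-dose predictions per clone and two-drug combination plans.

A clone's cancer-vs-normal differential-expression signature is turned into
a *reversal target* (its negation: the transcriptional change that would move
the clone back toward the normal state).  The pre-trained inhibition model
scores every (drug, dose) pair in the library against that target; predictions
are conformal-filtered and dose-capped, the best surviving dose per drug is
kept, and drugs are ranked by predicted inhibition.  Combination plans pair
the top-ranked drugs of two subclones, excluding same-drug pairs, scored by
the unweighted mean of the two predicted inhibitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyAfterFiltersError, NoValidPairsError
from .model import InhibitionModel, PredictionRecord, apply_dose_cap, conformal_filter, predict_matrix

__all__ = [
    "ClonePredictionSet",
    "CombinationPlan",
    "rank_for_clone",
    "monotherapy_mode",
    "design_combinations",
    "choose_mode",
]

log = logging.getLogger(__name__)


@dataclass
class ClonePredictionSet:
    clone_id: str
    records: list  # PredictionRecord, sorted by predicted inhibition desc
    mode: str  # "combination" | "monotherapy"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clone": self.clone_id,
                "drug_id": [r.drug_id for r in self.records],
                "dose_uM": [r.dose_uM for r in self.records],
                "predicted_inhibition_pct": [
                    r.predicted_inhibition_pct for r in self.records
                ],
                "confidence": [r.confidence for r in self.records],
            }
        )


@dataclass
class CombinationPlan:
    drug_a: str
    dose_a_uM: float
    drug_b: str
    dose_b_uM: float
    score: float  # mean of the two predicted inhibitions
    rank: int
    dose_bracket_a: tuple  # one dilution above and below the predicted dose
    dose_bracket_b: tuple


def _bracket(dose: float, fold: float = 10.0) -> tuple:
    return (dose / fold, dose * fold)


def rank_for_clone(
    model: InhibitionModel,
    signature,
    drug_library: pd.DataFrame,
    dose_grid_uM,
    threshold: float = 0.8,
    cap_uM: float = 1.0,
    clone_id: str = "A",
    mode: str = "combination",
) -> ClonePredictionSet:
    """Rank the drug library for one clone signature.

    ``signature`` is the cancer-vs-normal log2 fold-change vector (array in
    landmark order, or gene -> value mapping); it is negated internally to
    form the reversal target, so high-scoring drugs oppose the malignant
    state.  ``drug_library`` is a fingerprint table (``drug_id`` + bit
    columns).  Per drug, the best surviving dose is retained; ties are broken
    by lower dose, then drug id.

    Raises :class:`EmptyAfterFiltersError` if the signature is empty (no
    differentially expressed genes) or nothing survives the filters.
    """
    sig = (
        pd.Series(signature, dtype=float)
        if isinstance(signature, (dict, pd.Series))
        else pd.Series(np.asarray(signature, dtype=float))
    )
    if len(sig) == 0 or not np.any(sig.to_numpy() != 0.0):
        raise EmptyAfterFiltersError(
            f"clone {clone_id}: empty signature, no prediction possible"
        )

    tidy = predict_matrix(model, -sig if isinstance(signature, (dict, pd.Series)) else -sig.to_numpy(),
                          drug_library, dose_grid_uM)
    tidy = conformal_filter(tidy, threshold)
    tidy = apply_dose_cap(tidy, cap_uM)
    if len(tidy) == 0:
        raise EmptyAfterFiltersError(
            f"clone {clone_id}: no prediction survived confidence >= {threshold} "
            f"and dose <= {cap_uM} uM"
        )

    # best dose per drug: highest prediction, tie -> lower dose
    tidy = tidy.sort_values(
        ["drug_id", "predicted_inhibition_pct", "dose_uM"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    best = tidy.groupby("drug_id", sort=True).head(1)
    best = best.sort_values(
        ["predicted_inhibition_pct", "dose_uM", "drug_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)

    records = [
        PredictionRecord(
            drug_id=str(r.drug_id),
            dose_uM=float(r.dose_uM),
            predicted_inhibition_pct=float(r.predicted_inhibition_pct),
            halfwidth_pct=float(r.halfwidth_pct),
            confidence=float(r.confidence),
        )
        for r in best.itertuples()
    ]
    return ClonePredictionSet(clone_id=clone_id, records=records, mode=mode)


def monotherapy_mode(
    model: InhibitionModel,
    all_malignant_signature,
    drug_library: pd.DataFrame,
    dose_grid_uM,
    threshold: float = 0.8,
    cap_uM: float = 1.0,
    top_k: int = 20,
) -> ClonePredictionSet:
    """Rank drugs against the pooled malignant signature; keep the top-k."""
    ranked = rank_for_clone(
        model,
        all_malignant_signature,
        drug_library,
        dose_grid_uM,
        threshold=threshold,
        cap_uM=cap_uM,
        clone_id="all_malignant",
        mode="monotherapy",
    )
    ranked.records = ranked.records[:top_k]
    return ranked


def choose_mode(malignant_fraction: float, subclones_degenerate: bool, floor: float = 0.10) -> str:
    """Monotherapy when malignant cells are scarce or subclones unresolved."""
    if malignant_fraction < floor or subclones_degenerate:
        return "monotherapy"
    return "combination"


def design_combinations(
    set_a: ClonePredictionSet,
    set_b: ClonePredictionSet,
    k: int = 6,
) -> list[CombinationPlan]:
    """Pair the top-k drugs of two clones into ranked two-drug plans.

    All cross pairs from the two top-k lists are enumerated; pairs sharing a
    drug are excluded (the next-ranked candidates fill in naturally).  Plans
    are ranked by combined score (mean of the two predicted inhibitions),
    ties broken by drug ids.  Each drug carries a dose bracket note: one
    dilution step above and below the predicted dose.
    """
    if not set_a.records or not set_b.records:
        raise NoValidPairsError("both clone prediction sets must be nonempty")
    top_a = set_a.records[:k]
    top_b = set_b.records[:k]
    pairs = []
    for ra in top_a:
        for rb in top_b:
            if ra.drug_id == rb.drug_id:
                continue
            score = 0.5 * (ra.predicted_inhibition_pct + rb.predicted_inhibition_pct)
            pairs.append((score, ra, rb))
    if not pairs:
        raise NoValidPairsError("all candidate pairs share a drug")
    pairs.sort(key=lambda t: (-t[0], t[1].drug_id, t[2].drug_id))
    return [
        CombinationPlan(
            drug_a=ra.drug_id,
            dose_a_uM=ra.dose_uM,
            drug_b=rb.drug_id,
            dose_b_uM=rb.dose_uM,
            score=score,
            rank=i + 1,
            dose_bracket_a=_bracket(ra.dose_uM),
            dose_bracket_b=_bracket(rb.dose_uM),
        )
        for i, (score, ra, rb) in enumerate(pairs)
    ]
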