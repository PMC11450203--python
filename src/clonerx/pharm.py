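"""Validation pharmacometrics: plate normalization, 4PL fitting, ZIP, DSS, ROC.

Percent inhibition is the assay readout: raw viability normalized between a
negative control (DMSO, 0% inhibition) and a total-kill positive control
(benzethonium chloride, 100%).  Dose-response curves are summarized by a
four-parameter log-logistic (4PL) fit; combination matrices by the
zero-interaction-potency (ZIP) delta against the Bliss-independence surface
of the fitted monotherapy margins; single-agent efficacy by the drug
sensitivity score (DSS), a normalized area under the inhibition curve above
an activity threshold.  ROC/AUC with DeLong's paired test compares
classifiers of effective vs ineffective treatments.

The ZIP implementation is the Bliss-referenced delta form (fitted margins,
observed interior cells) rather than the full potency-shift refit of the
original formulation; both are exactly zero on any surface generated under
Bliss independence from its own margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateControlsError,
    FitFailureError,
    InvalidRangeError,
    OneClassOnlyError,
)

__all__ = [
    "percent_inhibition",
    "HillFit",
    "fit_hill",
    "DoseResponseMatrix",
    "zip_score",
    "dss",
    "roc_auc",
    "delong_test",
]

log = logging.getLogger(__name__)


def percent_inhibition(raw, dmso_mean: float, bzcl_mean: float):
    """Normalize a raw viability readout to percent inhibition.

    ``100 * (dmso_mean - raw) / (dmso_mean - bzcl_mean)``.  Values are *not*
    clipped: over-killing beyond the positive control is reported as > 100
    so assay artifacts stay visible.
    """
    if dmso_mean <= bzcl_mean:
        raise DegenerateControlsError(
            f"DMSO control ({dmso_mean}) must exceed BzCl control ({bzcl_mean})"
        )
    raw = np.asarray(raw, dtype=float)
    out = 100.0 * (dmso_mean - raw) / (dmso_mean - bzcl_mean)
    return float(out) if out.ndim == 0 else out


@dataclass
class HillFit:
    """Four-parameter log-logistic fit (percent-inhibition scale).

    ``fallback=True`` marks a failed nonlinear fit replaced by a monotone
    linear interpolant in log10-dose over the observed points.
    """

    ec50_uM: float
    slope: float
    bottom: float
    top: float
    rmse: float
    fallback: bool = False
    knots_dose: np.ndarray | None = None
    knots_inh: np.ndarray | None = None

    def predict(self, dose_uM) -> np.ndarray:
        d = np.asarray(dose_uM, dtype=float)
        if self.fallback:
            order = np.argsort(self.knots_dose)
            kd, ki = self.knots_dose[order], self.knots_inh[order]
            ki = np.maximum.accumulate(ki)  # enforce monotone interpolant
            pos = kd > 0
            out = np.interp(
                np.log10(np.where(d > 0, d, np.min(kd[pos]))),
                np.log10(kd[pos]),
                ki[pos],
            )
            return np.where(d > 0, out, ki[0])
        with np.errstate(divide="ignore"):
            num = np.power(d, self.slope)
            frac = np.where(d > 0, num / (num + self.ec50_uM**self.slope), 0.0)
        return self.bottom + (self.top - self.bottom) * frac


def _fourpl(d, bottom, top, log_ec50, slope):
    with np.errstate(divide="ignore", over="ignore"):
        num = np.power(d, slope)
        frac = np.where(d > 0, num / (num + (10.0**log_ec50) ** slope), 0.0)
    return bottom + (top - bottom) * frac


def fit_hill(doses_uM, inhibitions_pct) -> HillFit:
    """Least-squares 4PL fit in log10-dose with multi-start initials.

    Doses may include 0 (the zero-dose point anchors the bottom asymptote).
    Asymptotes are softly bounded to [-10, 110] percent.  On failure the fit
    falls back to a monotone linear interpolant (flagged, logged).
    """
    d = np.asarray(doses_uM, dtype=float)
    y = np.asarray(inhibitions_pct, dtype=float)
    if d.size < 3:
        raise ValueError(f"need >= 3 dose points, got {d.size}")
    if np.any(d < 0):
        raise ValueError("doses must be nonnegative")
    pos = d[d > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive dose")

    lo, hi = np.log10(pos.min()), np.log10(pos.max())
    bounds = ([-10.0, -10.0, lo - 2.0, 0.05], [110.0, 110.0, hi + 2.0, 10.0])
    b0 = float(np.clip(y[np.argmin(d)], -10, 110))
    t0 = float(np.clip(y[np.argmax(d)], -10, 110))
    if t0 <= b0:
        t0 = b0 + 1.0
    starts = np.linspace(lo, hi, 5)

    best, best_cost = None, np.inf
    for s0 in starts:
        for h0 in (0.5, 1.0, 2.0):
            p0 = np.clip(
                [b0, t0, s0, h0],
                bounds[0], bounds[1],
            )
            try:
                res = optimize.least_squares(
                    lambda p: _fourpl(d, *p) - y, p0, bounds=bounds, method="trf",
                    max_nfev=2000,
                )
            except Exception:  # noqa: BLE001 - optimizer edge cases fall through
                continue
            if res.cost < best_cost:
                best, best_cost = res, res.cost
    if best is None or not np.all(np.isfinite(best.x)):
        log.warning("4PL fit failed; falling back to monotone interpolant")
        return HillFit(
            ec50_uM=np.nan, slope=np.nan, bottom=np.nan, top=np.nan,
            rmse=np.nan, fallback=True, knots_dose=d.copy(), knots_inh=y.copy(),
        )
    bottom, top, log_ec50, slope = best.x
    rmse = float(np.sqrt(np.mean((_fourpl(d, *best.x) - y) ** 2)))
    if abs(top - bottom) < 1e-6:
        slope = 0.0  # flat response: slope is unidentifiable, report 0
    return HillFit(
        ec50_uM=float(10.0**log_ec50), slope=float(slope),
        bottom=float(bottom), top=float(top), rmse=rmse,
    )


# ---------------------------------------------------------------------------
# combination matrices and ZIP
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseMatrix:
    """Percent-inhibition grid with monotherapy margins.

    ``row_doses`` (drug 1) and ``col_doses`` (drug 2) include the zero dose;
    ``grid[i, j]`` is the inhibition at (row_doses[i], col_doses[j]), so
    ``grid[:, 0]`` and ``grid[0, :]`` are the single-agent margins.
    """

    row_doses_uM: np.ndarray
    col_doses_uM: np.ndarray
    grid_pct: np.ndarray

    def __post_init__(self):
        self.row_doses_uM = np.asarray(self.row_doses_uM, dtype=float)
        self.col_doses_uM = np.asarray(self.col_doses_uM, dtype=float)
        self.grid_pct = np.asarray(self.grid_pct, dtype=float)
        if self.grid_pct.shape != (self.row_doses_uM.size, self.col_doses_uM.size):
            raise ValueError("grid dimensions must match the dose lists")
        for doses in (self.row_doses_uM, self.col_doses_uM):
            if np.any(np.diff(doses) <= 0):
                raise ValueError("doses must be strictly increasing")
            if doses[0] != 0:
                raise ValueError("dose lists must start at 0 (monotherapy margin)")

    @classmethod
    def from_csv(cls, path) -> "DoseResponseMatrix":
        """First row / first column are doses; cell [0, 0] is blank."""
        raw = pd.read_csv(path, header=None)
        return cls(
            row_doses_uM=raw.iloc[1:, 0].astype(float).to_numpy(),
            col_doses_uM=raw.iloc[0, 1:].astype(float).to_numpy(),
            grid_pct=raw.iloc[1:, 1:].astype(float).to_numpy(),
        )

    def to_csv(self, path) -> None:
        out = np.full((self.grid_pct.shape[0] + 1, self.grid_pct.shape[1] + 1), np.nan)
        out[0, 1:] = self.col_doses_uM
        out[1:, 0] = self.row_doses_uM
        out[1:, 1:] = self.grid_pct
        pd.DataFrame(out).to_csv(path, header=False, index=False, na_rep="")


def zip_score(matrix: DoseResponseMatrix, region: tuple | None = None) -> float:
    """ZIP synergy delta (percent scale) of a dose-response matrix.

    4PL curves are fitted to each monotherapy margin; the zero-interaction
    expectation at (x1, x2) is the Bliss surface of the fitted fractional
    effects, ``f1 + f2 - f1*f2``.  The score is the mean of (observed -
    expected) over interior cells, optionally restricted to a dose
    ``region = ((row_min, row_max), (col_min, col_max))`` around the
    predicted effective doses, times 100.  Positive values read as synergy
    (> 10 in common practice), values near 0 as additivity.
    """
    fit1 = fit_hill(matrix.row_doses_uM, matrix.grid_pct[:, 0])
    fit2 = fit_hill(matrix.col_doses_uM, matrix.grid_pct[0, :])
    rows = matrix.row_doses_uM[1:]
    cols = matrix.col_doses_uM[1:]
    f1 = np.clip(fit1.predict(rows) / 100.0, 0.0, 1.0)
    f2 = np.clip(fit2.predict(cols) / 100.0, 0.0, 1.0)
    expected = f1[:, None] + f2[None, :] - f1[:, None] * f2[None, :]
    observed = matrix.grid_pct[1:, 1:] / 100.0
    delta = observed - expected
    if region is not None:
        (rlo, rhi), (clo, chi) = region
        rmask = (rows >= rlo) & (rows <= rhi)
        cmask = (cols >= clo) & (cols <= chi)
        if not rmask.any() or not cmask.any():
            raise InvalidRangeError("ZIP region contains no interior doses")
        delta = delta[np.ix_(rmask, cmask)]
    return float(delta.mean() * 100.0)


# ---------------------------------------------------------------------------
# DSS
# ---------------------------------------------------------------------------


def dss(
    fit: HillFit,
    dose_range_uM: tuple,
    activity_threshold: float = 10.0,
    n_grid: int = 1001,
) -> float:
    """Drug sensitivity score: normalized AUC above an activity threshold.

    ``max(0, I(d) - t)`` is integrated over log10-dose across
    ``dose_range_uM`` and normalized by ``(100 - t) * range`` so a curve
    pinned at 100% scores 100 and one never exceeding the threshold scores 0.
    """
    lo, hi = dose_range_uM
    if not (0 < lo < hi):
        raise InvalidRangeError(f"invalid dose range {dose_range_uM}")
    x = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    y = np.maximum(0.0, fit.predict(10.0**x) - activity_threshold)
    area = np.trapezoid(y, x)
    return float(100.0 * area / ((100.0 - activity_threshold) * (x[-1] - x[0])))


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


def _check_labels(labels) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise OneClassOnlyError("need both positive and negative labels")
    return labels


def roc_auc(labels, scores) -> float:
    """AUC by the rank statistic (Mann-Whitney) with tie correction."""
    labels = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _placements(pos: np.ndarray, neg: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
    return v10, v01


def delong_test(labels, scores1, scores2) -> tuple[float, float]:
    """Two-sided DeLong test comparing two paired AUCs.

    Returns ``(z, p)``.  ``z`` is the difference ``AUC1 - AUC2`` divided by
    its DeLong standard error (covariance estimated from placement values).
    Identical score vectors give z = 0, p = 1.
    """
    labels = _check_labels(labels)
    s1, s2 = np.asarray(scores1, dtype=float), np.asarray(scores2, dtype=float)
    if not (labels.size == s1.size == s2.size):
        raise ValueError("labels and both score vectors must be the same length")
    v10 = np.empty((2, int(labels.sum())))
    v01 = np.empty((2, int((~labels).sum())))
    aucs = np.empty(2)
    for i, s in enumerate((s1, s2)):
        v10[i], v01[i] = _placements(s[labels], s[~labels])
        aucs[i] = v10[i].mean()
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    m, n = v10.shape[1], v01.shape[1]
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    diff = aucs[0] - aucs[1]
    if var <= 0:
        return 0.0, 1.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
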