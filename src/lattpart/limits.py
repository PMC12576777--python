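"""The 40%-limit analysis.

Across diverse crystals of flexible molecules the intramolecular penalty
is bounded by roughly 40% of the intermolecular stabilization:
|E_intra-global| ≤ 0.4·|E_inter|.  This module computes the
intra-to-inter ratio r = |E_intra-global / E_inter| and its
adjustment/change decomposition, fits the upper envelope of the
(E_inter, E_intra-global) scatter, evaluates the cumulative distribution
of r, and scores kink-site crystal growth: at a kink (half-crystal)
site a molecule engages a fraction f ≈ 0.5 of its lattice neighbours,
so the net stabilization on incorporation is f·|E_inter| − E_intra-global,
which vanishes at r = f and is still 10% of |E_inter| at r = 0.4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .partition import EnergyPartition

__all__ = ["RatioRecord", "EnvelopeFit", "KinkModel", "LinearFit",
           "ratio", "envelope_fit", "cumulative_fractions",
           "intra_linear_fit", "kink_score", "crystallizability_report",
           "ratio_histogram"]


@dataclass(frozen=True)
class RatioRecord:
    """Dimensionless intra-to-inter ratios of one structure.

    ``r = |E_intra-global / E_inter|`` decomposes additively into the
    adjustment share ``r_adj`` and the change share ``r_chg`` because
    both intramolecular components are non-negative.
    """

    structure_id: str
    dataset: str
    r: float
    r_adj: float
    r_chg: float


@dataclass(frozen=True)
class EnvelopeFit:
    """Upper-envelope slope of E_intra-global vs |E_inter|."""

    estimator: str            # "max-ratio" | "upper-quantile"
    slope: float
    n: int
    level: float | None = None


@dataclass(frozen=True)
class KinkModel:
    """Kink-site incorporation: fraction f of lattice neighbours engaged."""

    f: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.f <= 1.0:
            raise InputError(f"site fraction f = {self.f} outside (0, 1]")

    def score(self, p: EnergyPartition) -> float:
        return kink_score(p, self.f)


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    n: int


def ratio(p: EnergyPartition, dataset: str = "") -> RatioRecord:
    """Intra-to-inter ratio record for one partition ledger."""
    if p.E_inter >= 0:
        raise InputError(
            f"{p.structure_id}: E_inter = {p.E_inter:.3g} >= 0 "
            "(unbound crystal has no meaningful ratio)"
        )
    mag = abs(p.E_inter)
    return RatioRecord(
        structure_id=p.structure_id, dataset=dataset,
        r=abs(p.E_intra_global) / mag,
        r_adj=p.E_adjustment / mag,
        r_chg=p.dE_change_global / mag,
    )


def envelope_fit(records: Sequence[RatioRecord], estimator: str = "max-ratio",
                 level: float = 0.99) -> EnvelopeFit:
    """Upper bound of the ratio cloud.

    ``max-ratio`` takes the largest observed r (the bound through the
    extreme point); ``upper-quantile`` the given quantile of r, which is
    robust to a single outlier.
    """
    if not records:
        raise InputError("no ratio records to fit")
    rs = np.array([rec.r for rec in records])
    if estimator == "max-ratio":
        return EnvelopeFit("max-ratio", float(rs.max()), len(rs))
    if estimator == "upper-quantile":
        if not 0.0 < level < 1.0:
            raise InputError("quantile level must be in (0, 1)")
        return EnvelopeFit("upper-quantile", float(np.quantile(rs, level)),
                           len(rs), level)
    raise InputError(f"unknown estimator {estimator!r}")


def cumulative_fractions(records: Sequence[RatioRecord],
                         thresholds: Sequence[float]) -> np.ndarray:
    """Fraction of structures with r ≤ each threshold (a CDF evaluation)."""
    thresholds = np.asarray(thresholds, float)
    if np.any(np.diff(thresholds) < 0):
        raise InputError("thresholds must be sorted ascending")
    rs = np.array([rec.r for rec in records])
    if rs.size == 0:
        return np.zeros_like(thresholds)
    return np.array([np.mean(rs <= t) for t in thresholds])


def intra_linear_fit(partitions: Sequence[EnergyPartition],
                     component: str = "intra_global") -> LinearFit:
    """OLS fit of an intramolecular component against E_inter.

    ``component`` is one of ``intra_global``, ``adjustment``, ``change``.
    For a ratio cloud with mean ratio m the slope is close to −m, since
    E_inter is negative while the penalties are positive.
    """
    if len(partitions) < 3:
        raise InputError("need at least 3 points for a linear fit")
    x = np.array([p.E_inter for p in partitions])
    if np.ptp(x) == 0:
        raise InputError("degenerate fit: E_inter has zero variance")
    y = {
        "intra_global": np.array([p.E_intra_global for p in partitions]),
        "adjustment": np.array([p.E_adjustment for p in partitions]),
        "change": np.array([p.dE_change_global for p in partitions]),
    }[component]
    res = stats.linregress(x, y)
    return LinearFit(float(res.slope), float(res.intercept),
                     float(res.rvalue ** 2), len(x))


def kink_score(p: EnergyPartition, f: float = 0.5) -> float:
    """Net stabilization (kJ·mol⁻¹) of kink-site incorporation.

    ``f·|E_inter| − E_intra-global``: positive means the conformation
    still gains energy when attaching at a kink engaging a fraction f of
    its lattice interactions; at r > f incorporation is energetically
    unfavorable.
    """
    if not 0.0 < f <= 1.0:
        raise InputError(f"site fraction f = {f} outside (0, 1]")
    if p.E_inter >= 0:
        raise InputError(f"{p.structure_id}: E_inter >= 0 (unbound crystal)")
    return f * abs(p.E_inter) - p.E_intra_global


#: ratio above which a structure is flagged as hard to crystallize
HIGH_RATIO_PERCENTILE = 90.0


def crystallizability_report(partitions: Sequence[EnergyPartition],
                             f: float = 0.5,
                             reference_r: np.ndarray | None = None,
                             dataset: str = "") -> pd.DataFrame:
    """Per-structure table of ratios, kink scores and reference percentiles.

    The percentile places each structure's r within a reference ratio
    distribution (by default a large sample from the calibrated synthetic
    generator); structures above the 90th percentile are flagged
    ``high_ratio`` — empirically these are the forms reported as
    difficult to crystallize.
    """
    if not partitions:
        raise InputError("no partitions to report on")
    if reference_r is None:
        from .synthetic import reference_ratio_distribution
        reference_r = reference_ratio_distribution()
    reference_r = np.sort(np.asarray(reference_r, float))
    rows = []
    for p in partitions:
        rec = ratio(p, dataset)
        pct = 100.0 * np.searchsorted(reference_r, rec.r, side="right") / len(
            reference_r)
        score = kink_score(p, f)
        rows.append({
            "structure_id": p.structure_id, "compound_id": p.compound_id,
            "r": rec.r, "r_adj": rec.r_adj, "r_chg": rec.r_chg,
            "kink_score": score, "kink_favorable": score > 0.0,
            "percentile": pct, "high_ratio": pct >= HIGH_RATIO_PERCENTILE,
        })
    return pd.DataFrame(rows)


def ratio_histogram(records: Sequence[RatioRecord], bin_width: float = 0.05,
                    r_max: float = 0.5) -> pd.DataFrame:
    """Binned distribution of r (columns: bin_left, bin_right, count, fraction)."""
    rs = np.array([rec.r for rec in records])
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    counts, _ = np.histogram(rs, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "count": counts,
        "fraction": counts / max(len(rs), 1),
    })
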