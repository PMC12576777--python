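"""Polymorph-pair stability benchmarking.

Relative lattice energies of polymorph pairs (the less stable form
minus the experimentally stable reference form) are compared with
experimental enthalpy differences from thermal analysis, and models are
ranked by their mean absolute deviation (MAD).  Compounds with more than
two known forms contribute one pair per non-reference form, all sharing
the same reference.  The 0 K lattice energies are compared to
~393–433 K enthalpies at face value, since heat-capacity differences
between polymorphs are typically negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BenchmarkError
from .partition import EnergyPartition

__all__ = ["PolymorphPair", "BenchmarkResult", "pair_relative_energies",
           "mad", "mad_by_subset", "model_grid", "sign_inversions"]


@dataclass(frozen=True)
class PolymorphPair:
    """One polymorph pair: alternative form B relative to reference form A.

    ``dH_exp`` is the experimental enthalpy difference (≥ 0 by the
    convention that the reference form is the stable one); ``dE_latt``
    is the computed lattice-energy difference, negative when the model
    inverts the experimental stability order.
    """

    compound: str
    refcode_ref: str
    refcode_alt: str
    dH_exp: float
    dE_latt: float
    subset: str = "all"
    model: str = ""

    def __post_init__(self):
        if self.refcode_ref == self.refcode_alt:
            raise BenchmarkError(
                f"{self.compound}: reference and alternative refcodes coincide")

    @property
    def inverted(self) -> bool:
        """True when the model predicts the wrong stability order."""
        return self.dE_latt < 0


@dataclass(frozen=True)
class BenchmarkResult:
    model: str
    deviations: tuple[float, ...]
    mad: float
    n_pairs: int
    subset: str = "all"

    def __str__(self):
        return (f"{self.model or 'model'} [{self.subset}]: "
                f"MAD = {self.mad:.1f} kJ/mol over {self.n_pairs} pairs")


def pair_relative_energies(
    ledgers: Mapping[str, EnergyPartition],
    pairs_table: pd.DataFrame,
    model: str = "",
) -> list[PolymorphPair]:
    """Build polymorph pairs from partition ledgers and a pairing table.

    ``pairs_table`` needs columns compound, refcode_ref, refcode_alt,
    dH_exp and optionally subset.  ``dE_latt`` is
    E_latt_global(alt) − E_latt_global(ref).
    """
    pairs = []
    for row in pairs_table.itertuples(index=False):
        for code in (row.refcode_ref, row.refcode_alt):
            if code not in ledgers:
                raise BenchmarkError(
                    f"no ledger for refcode {code!r} (model {model!r})")
        d = (ledgers[row.refcode_alt].E_latt_global
             - ledgers[row.refcode_ref].E_latt_global)
        pairs.append(PolymorphPair(
            compound=row.compound, refcode_ref=row.refcode_ref,
            refcode_alt=row.refcode_alt, dH_exp=float(row.dH_exp),
            dE_latt=d, subset=getattr(row, "subset", "all"), model=model,
        ))
    return pairs


def mad(pairs: Sequence[PolymorphPair], subset: str | None = None,
        model: str = "") -> BenchmarkResult:
    """Mean absolute deviation |ΔH_exp − ΔE_latt| over the pairs.

    Full precision is retained; round to 0.1 kJ/mol for display only.
    """
    if subset is not None:
        pairs = [p for p in pairs if p.subset == subset]
    if not pairs:
        raise BenchmarkError(f"no pairs to average (subset={subset!r})")
    dev = tuple(abs(p.dH_exp - p.dE_latt) for p in pairs)
    return BenchmarkResult(model=model or (pairs[0].model if pairs else ""),
                           deviations=dev, mad=float(np.mean(dev)),
                           n_pairs=len(dev), subset=subset or "all")


def mad_by_subset(pairs: Sequence[PolymorphPair],
                  model: str = "") -> dict[str, BenchmarkResult]:
    """MAD for each subset label plus the pooled set under key 'all'."""
    out = {"all": mad(pairs, None, model)}
    for s in sorted({p.subset for p in pairs}):
        out[s] = mad(pairs, s, model)
    return out


def model_grid(
    ledgers_by_model: Mapping[tuple[str, str], Mapping[str, EnergyPartition]],
    pairs_table: pd.DataFrame,
) -> list[BenchmarkResult]:
    """One MAD per (inter model, intra model) cell, sorted ascending.

    The first element is the best lattice-energy model.  An incomplete
    grid (any cell missing a refcode's ledger) fails with the full list
    of missing cells.
    """
    needed = set(pairs_table["refcode_ref"]) | set(pairs_table["refcode_alt"])
    missing = []
    for key, ledgers in ledgers_by_model.items():
        lacking = sorted(needed - set(ledgers))
        if lacking:
            missing.append(f"{key}: missing {', '.join(lacking)}")
    if missing:
        raise BenchmarkError("incomplete model grid: " + "; ".join(missing))
    results = []
    for (inter_m, intra_m), ledgers in ledgers_by_model.items():
        label = f"{inter_m}/{intra_m}"
        pairs = pair_relative_energies(ledgers, pairs_table, model=label)
        results.append(mad(pairs, model=label))
    return sorted(results, key=lambda r: (r.mad, r.model))


def sign_inversions(pairs: Sequence[PolymorphPair]) -> list[PolymorphPair]:
    """Pairs whose computed stability order contradicts experiment."""
    return [p for p in pairs if p.inverted]
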