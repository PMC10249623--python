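"""Homologue-series trend analysis: per-CF2/per-CH2 increments.

Within a homologue series (e.g., the X:2 fluorotelomer alcohols) the
log partition coefficient grows linearly with the number of repeated
chain units.  The per-unit increment — the OLS slope of log K against
the unit count — is remarkably consistent across PFAS classes
(~0.43 log units per CF2 for K_aw, ~0.74 for K_Hxd/w) and lets data
for short-chain members be extrapolated to longer homologues.

Counting convention: ``n_pfc`` counts perfluorinated chain carbons
(carbons carrying two or more fluorines), so the terminal CF3 carbon
counts as one unit and the count equals the X of the X:Y nomenclature.
Only count *differences* enter slopes, so any consistent convention
yields the same increments.  ``n_ch2`` counts sp3 methylene (-CH2-)
units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InconsistentSeriesError,
    InvalidInputError,
    MissingValueError,
    UnderDeterminedError,
)


@dataclass
class HomologueSeries:
    """One homologue group: (compound, unit count, log K) members."""

    label: str
    unit: str  # "CF2" or "CH2"
    members: Sequence[Tuple[str, float, float]]
    quantity: str = "aw"

    def __post_init__(self):
        if self.unit not in ("CF2", "CH2"):
            raise InvalidInputError(f"unknown chain unit {self.unit!r}")
        if len({c for _, c, _ in self.members}) < 2:
            raise UnderDeterminedError(
                f"series {self.label!r} needs >=2 distinct unit counts"
            )

    @property
    def counts(self) -> np.ndarray:
        return np.array([c for _, c, _ in self.members], dtype=float)

    @property
    def log_ks(self) -> np.ndarray:
        return np.array([k for _, _, k in self.members], dtype=float)


@dataclass
class IncrementEstimate:
    """Pooled per-unit increment over several homologue series."""

    mean_slope: float
    se: float
    group_slopes: Dict[str, float]
    n_groups: int
    unit: str
    quantity: str


def count_chain_units(structure: str) -> Tuple[int, int]:
    """Count perfluorinated chain carbons and methylene units in a SMILES.

    n_pfc: carbons bearing >= 2 fluorine substituents (CF2, CF3, and the
    terminal CF2H of omega-H chains).  n_ch2: sp3 carbons with exactly
    two hydrogens.  Requires rdkit.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "count_chain_units requires rdkit (pip install rdkit)"
        ) from exc
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise InvalidInputError(f"unparseable SMILES {structure!r}")
    n_pfc = 0
    n_ch2 = 0
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        n_f = sum(
            1 for nb in atom.GetNeighbors() if nb.GetSymbol() == "F"
        )
        if n_f >= 2:
            n_pfc += 1
        elif (
            atom.GetTotalNumHs() == 2
            and n_f == 0
            and str(atom.GetHybridization()) == "SP3"
        ):
            n_ch2 += 1
    return n_pfc, n_ch2


def series_slope(series: HomologueSeries) -> Tuple[float, float]:
    """OLS slope of log K on unit count, with its standard error.

    For a two-member series the slope is the finite difference and the
    standard error is zero (the fit is exact).
    """
    counts, log_ks = series.counts, series.log_ks
    if len(series.members) == 2:
        slope = (log_ks[1] - log_ks[0]) / (counts[1] - counts[0])
        return float(slope), 0.0
    res = stats.linregress(counts, log_ks)
    return float(res.slope), float(res.stderr)


def pooled_increment(
    series_list: Sequence[HomologueSeries],
    method: str = "mean",
) -> IncrementEstimate:
    """Pool per-series slopes into one per-unit increment.

    ``method="mean"`` (default): unweighted mean of the group slopes,
    with se = SD of the slopes / sqrt(n_groups).  ``method="common"``:
    a single-slope regression with one intercept per group (slightly
    weights longer series).
    """
    if not series_list:
        raise InvalidInputError("need at least one series")
    units = {s.unit for s in series_list}
    quantities = {s.quantity for s in series_list}
    if len(units) > 1 or len(quantities) > 1:
        raise InconsistentSeriesError(
            "all series must share one unit and one quantity"
        )
    group_slopes = {s.label: series_slope(s)[0] for s in series_list}
    slopes = np.array(list(group_slopes.values()))
    if method == "mean":
        mean_slope = float(slopes.mean())
        se = (
            float(slopes.std(ddof=1) / np.sqrt(slopes.size))
            if slopes.size > 1
            else 0.0
        )
    elif method == "common":
        # Common slope, per-group intercept: demean x and y within group.
        xs, ys = [], []
        for s in series_list:
            xs.append(s.counts - s.counts.mean())
            ys.append(s.log_ks - s.log_ks.mean())
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        mean_slope = float(x @ y / (x @ x))
        dof = x.size - 2 * len(series_list)
        resid = y - mean_slope * x
        se = (
            float(np.sqrt((resid @ resid) / dof / (x @ x)))
            if dof > 0
            else 0.0
        )
    else:
        raise InvalidInputError(f"unknown pooling method {method!r}")
    return IncrementEstimate(
        mean_slope=mean_slope,
        se=se,
        group_slopes=group_slopes,
        n_groups=len(group_slopes),
        unit=series_list[0].unit,
        quantity=series_list[0].quantity,
    )


def _lookup(values: pd.DataFrame, compound: str, quantity: str) -> float:
    rows = values[
        (values["compound"] == compound) & (values["quantity"] == quantity)
    ]
    if rows.empty:
        raise MissingValueError(
            f"no {quantity!r} value for compound {compound!r}"
        )
    return float(rows["log_k"].iloc[0])


def substitution_delta(
    values: pd.DataFrame, from_: str, to: str, quantity: str
) -> float:
    """log K(to) - log K(from) for one structural substitution.

    ``values`` holds columns ``compound``, ``quantity``, ``log_k``
    (e.g., the final-value table produced by the pipeline).  Example:
    N-methylation PFBSA -> MeFBSA raises log K_aw by ~2.
    """
    return _lookup(values, to, quantity) - _lookup(values, from_, quantity)


def structural_pair_contrast(
    values: pd.DataFrame, a: str, b: str
) -> Dict[str, float]:
    """Per-quantity log K(a) - log K(b) over all shared quantities."""
    qa = set(values.loc[values["compound"] == a, "quantity"])
    qb = set(values.loc[values["compound"] == b, "quantity"])
    shared = sorted(qa & qb)
    if not shared:
        raise MissingValueError(f"{a!r} and {b!r} share no measured quantity")
    return {
        q: _lookup(values, a, q) - _lookup(values, b, q) for q in shared
    }


def build_series_from_tables(
    registry: pd.DataFrame,
    values: pd.DataFrame,
    quantity: str,
    unit: str = "CF2",
    groups: Optional[Sequence[str]] = None,
) -> list:
    """Assemble homologue series from a registry and a final-value table.

    Compounds are grouped by the registry ``group`` column; the unit
    count comes from ``n_pfc`` (CF2) or ``n_ch2`` (CH2).  Groups with
    fewer than two members carrying a value for ``quantity`` are
    skipped.
    """
    count_col = "n_pfc" if unit == "CF2" else "n_ch2"
    out = []
    labels = (
        groups
        if groups is not None
        else sorted(g for g in registry["group"].dropna().unique() if g)
    )
    for label in labels:
        members = []
        for _, row in registry[registry["group"] == label].iterrows():
            try:
                log_k = _lookup(values, row["abbreviation"], quantity)
            except MissingValueError:
                continue
            members.append((row["abbreviation"], int(row[count_col]), log_k))
        if len({c for _, c, _ in members}) >= 2:
            out.append(
                HomologueSeries(
                    label=label, unit=unit, members=members, quantity=quantity
                )
            )
    return out
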