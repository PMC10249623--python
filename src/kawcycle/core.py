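"""Domain types, the thermodynamic cycle, and mass-balance estimators.

The central relation is the hexadecane/air/water thermodynamic cycle

    log K_aw = log K_Hxd/w - log K_Hxd/air

which converts a hexadecane/water partition coefficient (measurable
without gas-phase quantification) into an air/water partition
coefficient using an independently known hexadecane/air value.  The
module also provides the mass-balance inversions that turn a measured
water-phase concentration from a batch (two-phase) or shared-headspace
(three-phase) equilibration into a linear-space K_Hxd/w, replicate
statistics on log-transformed values, and the policy that picks the
final value when several methods measured the same compound.

Conventions
-----------
* Partition coefficients are carried as log10 values in
  :class:`LogPartitionCoefficient`; the mass-balance estimators work in
  linear space and callers convert at the boundary.
* Amount units are caller-defined but must be consistent between the
  spiked mass and measured concentrations; every formula is a ratio.
* Everything refers to 25 degrees C; no temperature correction exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    InfeasibleMassBalanceError,
    InsufficientReplicatesError,
    InvalidGeometryError,
    InvalidInputError,
    NoDataError,
)

#: Batch-method applicability limit in log10 units: above this K_Hxd/w a
#: 0.006 vol % hexadecane microdroplet contamination biases the batch
#: estimate by more than 0.1 log units (see :mod:`kawcycle.artifacts`).
BATCH_APPLICABILITY_LIMIT = 3.6


class Quantity(str, Enum):
    """Which partition coefficient a log value refers to."""

    AW = "aw"
    HXD_W = "hxd/w"
    HXD_AIR = "hxd/air"


class Method(str, Enum):
    """How a partition coefficient was obtained."""

    BATCH = "batch"
    SHARED_HEADSPACE = "shared_headspace"
    MODIFIED_VPRHS = "modified_vprhs"
    STANDARD_VPRHS = "standard_vprhs"
    CYCLE = "cycle"
    PREDICTED = "predicted"
    LITERATURE = "literature"


@dataclass(frozen=True)
class Compound:
    """One entry of the compound registry.

    ``n_pfc`` is the number of perfluorinated chain carbons (the X of
    the X:Y fluorotelomer nomenclature; the terminal CF3 carbon counts);
    ``n_ch2`` is the number of methylene units.
    """

    abbreviation: str
    name: str = ""
    cas: str = ""
    structure: str = ""
    group: Optional[str] = None
    n_pfc: int = 0
    n_ch2: int = 0

    def __post_init__(self):
        if self.n_pfc < 0 or self.n_ch2 < 0:
            raise InvalidInputError(
                f"{self.abbreviation}: unit counts must be non-negative"
            )


@dataclass(frozen=True)
class LogPartitionCoefficient:
    """A log10 partition coefficient with optional confidence interval."""

    quantity: Quantity
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: Optional[Method] = None
    compound: Optional[str] = None
    temperature: float = 25.0

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise InvalidInputError("log K must be finite")
        if (self.ci_low is None) != (self.ci_high is None):
            raise InvalidInputError("CI must give both bounds or neither")
        if self.ci_low is not None:
            if not self.ci_low <= self.value <= self.ci_high:
                raise InvalidInputError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"value {self.value}"
                )

    @property
    def k(self) -> float:
        """Linear-space partition coefficient 10**value."""
        return 10.0 ** self.value


@dataclass(frozen=True)
class PhaseSystem:
    """Vial geometry and spike for one equilibration experiment.

    Volumes in mL; ``mass`` in any consistent amount unit; ``ph`` is the
    pH of the aqueous phase (3.0 for the 1 mM HCl medium used with
    sulfonamides, 7.0 for unbuffered water).
    """

    v_water: float
    v_hxd: float
    v_air: float = 0.0
    mass: float = 1.0
    ph: float = 7.0

    def __post_init__(self):
        if min(self.v_water, self.v_hxd, self.v_air) < 0:
            raise InvalidGeometryError("phase volumes must be non-negative")
        if self.mass <= 0:
            raise InvalidInputError("spiked mass must be positive")


@dataclass
class ReplicateSet:
    """Replicate log10 measurements with derived summary statistics."""

    values: Sequence[float]
    n: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.size < 2:
            raise InsufficientReplicatesError(
                f"need >=2 replicates, got {vals.size}"
            )
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("replicate values must be finite")
        self.n = int(vals.size)
        self.mean = float(vals.mean())
        self.sd = float(vals.std(ddof=1))


def cycle_log_kaw(
    log_khxdw: float, log_khxdair: float
) -> LogPartitionCoefficient:
    """Combine K_Hxd/w and K_Hxd/air into K_aw via the thermodynamic cycle.

    K_aw = K_Hxd/w / K_Hxd/air, i.e. log K_aw = log K_Hxd/w - log K_Hxd/air.
    Exact at equilibrium: both coefficients share the hexadecane phase.
    """
    if not (math.isfinite(log_khxdw) and math.isfinite(log_khxdair)):
        raise InvalidInputError("cycle inputs must be finite")
    return LogPartitionCoefficient(
        quantity=Quantity.AW,
        value=log_khxdw - log_khxdair,
        method=Method.CYCLE,
    )


def batch_k_from_water_conc(system: PhaseSystem, c_water: float) -> float:
    """Invert the two-phase batch mass balance for linear-space K_Hxd/w.

    All spiked mass not found in water is attributed to hexadecane
    (headspace mass in the 10 mL batch vial is neglected):

        K = (m - c_w * V_w) / (c_w * V_Hxd)

    Raises
    ------
    InfeasibleMassBalanceError
        If the water phase alone would hold at least the spiked mass.
    InvalidGeometryError
        If the hexadecane volume is zero.
    """
    if c_water <= 0:
        raise InvalidInputError("water concentration must be positive")
    if system.v_hxd == 0:
        raise InvalidGeometryError("batch inversion requires v_hxd > 0")
    m_water = c_water * system.v_water
    if m_water >= system.mass:
        raise InfeasibleMassBalanceError(
            f"water phase holds {m_water:.4g} of spiked {system.mass:.4g}"
        )
    return (system.mass - m_water) / (c_water * system.v_hxd)


def shared_headspace_k_from_water_conc(
    system: PhaseSystem,
    c_water: float,
    log_khxdair: Optional[float] = None,
) -> float:
    """Invert the three-phase shared-headspace mass balance for K_Hxd/w.

    Hexadecane and water equilibrate only through a common headspace, so
    spiked mass splits over three phases.  With the air mass expressed
    through K_Hxd/air (C_air = C_hxd / K_Hxd/air):

        K = (m - c_w * V_w) / (c_w * (V_Hxd + V_air / K_Hxd/air))

    With ``log_khxdair`` absent the air term is dropped and the result
    reduces to :func:`batch_k_from_water_conc`; for the volatile,
    hydrophobic compounds this method targets, K_Hxd/air ~ 1e6 makes the
    air term negligible anyway.
    """
    if c_water <= 0:
        raise InvalidInputError("water concentration must be positive")
    if log_khxdair is None:
        return batch_k_from_water_conc(system, c_water)
    if system.v_air <= 0:
        raise InvalidGeometryError("shared-headspace requires v_air > 0")
    m_water = c_water * system.v_water
    denom = c_water * (system.v_hxd + system.v_air / 10.0 ** log_khxdair)
    if m_water >= system.mass or denom <= 0:
        raise InfeasibleMassBalanceError(
            "measured water concentration inconsistent with spiked mass"
        )
    return (system.mass - m_water) / denom


def replicate_mean_ci(
    reps: ReplicateSet,
    confidence: float = 0.95,
    quantity: Quantity = Quantity.HXD_W,
    method: Optional[Method] = None,
    compound: Optional[str] = None,
) -> LogPartitionCoefficient:
    """Mean with a Student-t confidence interval over replicate log values.

    Half-width = t_{1-(1-confidence)/2, n-1} * SD / sqrt(n).  At n = 5
    and 95% confidence the multiplier is 2.776, the familiar
    "x +/- 2.78 SD / sqrt(5)".
    """
    if not 0 < confidence < 1:
        raise InvalidInputError("confidence must be in (0, 1)")
    tq = stats.t.ppf(1 - (1 - confidence) / 2, df=reps.n - 1)
    half = tq * reps.sd / math.sqrt(reps.n)
    return LogPartitionCoefficient(
        quantity=quantity,
        value=reps.mean,
        ci_low=reps.mean - half,
        ci_high=reps.mean + half,
        method=method,
        compound=compound,
    )


def mass_recovery_percent(
    system: PhaseSystem, c_hxd_measured: float, k_assumed: float
) -> float:
    """Percent of the expected hexadecane-phase concentration recovered.

    The expected concentration follows from the two-phase mass balance
    at the assumed K: c_hxd = m * K / (V_w + K * V_Hxd).  The batch and
    shared-headspace procedures report 93-112% and 85-100% recovery
    respectively as a mass-conservation check.
    """
    if k_assumed <= 0:
        raise InvalidInputError("assumed K must be positive")
    denom = system.v_water + k_assumed * system.v_hxd
    if denom == 0:
        raise InvalidInputError("degenerate geometry: no phase volume")
    c_expected = system.mass * k_assumed / denom
    if c_expected == 0:
        raise InvalidInputError("expected concentration is zero")
    return 100.0 * c_hxd_measured / c_expected


@dataclass(frozen=True)
class SelectionPolicy:
    """Policy for choosing the final value among per-method results.

    The default mirrors how complementary methods are combined: the
    shared-headspace value is used whenever present and above the batch
    applicability limit (microdroplet contamination biases batch values
    low above ~3.6) or when no batch value exists; otherwise the batch
    value; the modified VPR-HS value only as a last resort (sorption
    artifacts gave it wide CIs).
    """

    batch_limit: float = BATCH_APPLICABILITY_LIMIT
    preference: Sequence[Method] = (
        Method.SHARED_HEADSPACE,
        Method.BATCH,
        Method.MODIFIED_VPRHS,
    )


def select_final_value(
    per_method: Sequence[LogPartitionCoefficient],
    policy: SelectionPolicy = SelectionPolicy(),
) -> LogPartitionCoefficient:
    """Pick the final partition coefficient among per-method estimates."""
    if not per_method:
        raise NoDataError("no per-method values to select from")
    quantities = {v.quantity for v in per_method}
    compounds = {v.compound for v in per_method}
    if len(quantities) > 1 or len(compounds) > 1:
        raise InvalidInputError(
            "selection requires a single compound and quantity"
        )
    by_method = {v.method: v for v in per_method}
    shared = by_method.get(Method.SHARED_HEADSPACE)
    batch = by_method.get(Method.BATCH)
    if shared is not None and (
        shared.value > policy.batch_limit or batch is None
    ):
        return shared
    if batch is not None:
        return batch
    for m in policy.preference:
        if m in by_method:
            return by_method[m]
    return per_method[0]


def propagate_cycle_ci(
    khxdw: LogPartitionCoefficient, khxdair: LogPartitionCoefficient
) -> LogPartitionCoefficient:
    """Thermodynamic cycle with CI half-widths combined in quadrature.

    An extension beyond the published tables (which report no CI on the
    cycled K_aw): half-widths of the two inputs are treated as
    independent and added in quadrature on the log scale.
    """
    out = cycle_log_kaw(khxdw.value, khxdair.value)
    if khxdw.ci_low is None or khxdair.ci_low is None:
        return replace(out, compound=khxdw.compound)
    hw = math.hypot(
        (khxdw.ci_high - khxdw.ci_low) / 2,
        (khxdair.ci_high - khxdair.ci_low) / 2,
    )
    return replace(
        out,
        compound=khxdw.compound,
        ci_low=out.value - hw,
        ci_high=out.value + hw,
    )
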