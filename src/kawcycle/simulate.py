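"""Forward simulation of the partition experiments.

Generates synthetic measurement tables for every experiment type the
estimators invert — batch, shared-headspace, and the two VPR-HS
designs — plus homologue panels for the trend analysis.  Each simulator
computes exact equilibrium concentrations from the mass balance at a
known true K and then layers on the disturbances real experiments
suffer:

* multiplicative lognormal measurement noise (analytical variability is
  relative), parameterized by a coefficient of variation and scaled so
  the noise factor has mean 1;
* optional hexadecane microdroplet contamination of the sampled water
  (batch only; the shared-headspace phases never touch);
* optional sorptive mass loss to unmodelled sinks (glass wall, septum,
  air/water interface), removed from the spike before equilibrium.

At zero noise/loss/droplet every simulator is exactly inverted by its
paired estimator; that round trip is the backbone of the test suite.
All randomness flows through a mandatory seed.

Default geometries: batch 5 mL water + 5 mL hexadecane in a 10 mL
vial; shared-headspace 1 mL water, 0.35 mL hexadecane, 8.65 mL air;
VPR-HS 20 mL total liquid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import PhaseSystem
from .exceptions import InvalidGeometryError, InvalidInputError
from .headspace import (
    HeadspaceSeries,
    modified_vprhs_predict,
    standard_vprhs_predict,
)
from .trends import HomologueSeries

BATCH_SYSTEM = PhaseSystem(v_water=5.0, v_hxd=5.0, v_air=0.0, mass=1.0)
SHARED_SYSTEM = PhaseSystem(v_water=1.0, v_hxd=0.35, v_air=8.65, mass=1.0)
VPRHS_V_TOT = 20.0


@dataclass
class SimulationConfig:
    """Ground truth and disturbance levels for one simulated experiment."""

    true_log_k: float
    system: PhaseSystem = field(default_factory=lambda: BATCH_SYSTEM)
    noise_cv: float = 0.0
    droplet_f: float = 0.0
    loss_fraction: float = 0.0
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be non-negative")
        if not 0 <= self.loss_fraction < 1:
            raise InvalidInputError("loss_fraction must be in [0, 1)")
        if not 0 <= self.droplet_f < 1:
            raise InvalidInputError("droplet_f must be in [0, 1)")
        if self.n_replicates < 1:
            raise InvalidInputError("need at least one replicate")


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma, size=size)


def simulate_batch(config: SimulationConfig) -> pd.DataFrame:
    """Simulate batch two-phase equilibrations; one row per replicate.

    Columns: ``replicate``, ``c_water`` (the reported, possibly
    droplet-contaminated and noisy water concentration), ``c_hxd``
    (noisy hexadecane concentration, for recovery checks).
    """
    sysm = config.system
    if sysm.v_water <= 0 or sysm.v_hxd <= 0:
        raise InvalidGeometryError("batch needs water and hexadecane")
    k = 10.0 ** config.true_log_k
    mass = sysm.mass * (1.0 - config.loss_fraction)
    c_hxd = mass * k / (sysm.v_water + k * sysm.v_hxd)
    c_water_sampled = c_hxd / k + config.droplet_f * c_hxd
    rng = np.random.default_rng(config.seed)
    n = config.n_replicates
    return pd.DataFrame(
        {
            "replicate": np.arange(1, n + 1),
            "c_water": c_water_sampled * _noise_factors(rng, config.noise_cv, n),
            "c_hxd": c_hxd * _noise_factors(rng, config.noise_cv, n),
        }
    )


def simulate_shared_headspace(
    config: SimulationConfig, log_khxdair: float
) -> pd.DataFrame:
    """Simulate three-phase shared-headspace equilibrations.

    Mass splits over hexadecane, air, and water simultaneously:
    C_w = C_hxd/K_Hxd/w, C_air = C_hxd/K_Hxd/air.  No droplet term —
    water and hexadecane never contact.  Columns: ``replicate``,
    ``c_water``, ``c_hxd``, ``c_air``, ``hxd_mass_fraction`` (fraction
    of the spike residing in hexadecane, the mass-conservation check
    quantity).
    """
    sysm = config.system
    if min(sysm.v_water, sysm.v_hxd, sysm.v_air) <= 0:
        raise InvalidGeometryError("shared-headspace needs three phases")
    k1 = 10.0 ** config.true_log_k
    k2 = 10.0 ** log_khxdair
    mass = sysm.mass * (1.0 - config.loss_fraction)
    c_hxd = mass / (sysm.v_hxd + sysm.v_water / k1 + sysm.v_air / k2)
    rng = np.random.default_rng(config.seed)
    n = config.n_replicates
    return pd.DataFrame(
        {
            "replicate": np.arange(1, n + 1),
            "c_water": (c_hxd / k1) * _noise_factors(rng, config.noise_cv, n),
            "c_hxd": c_hxd * _noise_factors(rng, config.noise_cv, n),
            "c_air": np.full(n, c_hxd / k2),
            "hxd_mass_fraction": np.full(
                n, c_hxd * sysm.v_hxd / sysm.mass
            ),
        }
    )


def simulate_modified_vprhs(
    config: SimulationConfig,
    v_hxd_list: Sequence[float],
    v_tot: float = VPRHS_V_TOT,
    scale: float = 1000.0,
    compound: str = "synthetic",
) -> HeadspaceSeries:
    """Simulate a water+hexadecane VPR-HS peak-area series.

    ``loss_fraction`` models a wall/interface sink proportional to the
    water volume fraction of each vial (loss_i = loss * V_w,i / V_tot),
    so different vials lose different amounts — the vial-dependent
    violation of the mass-balance assumption that produces systematic
    misfit, unlike a uniform loss which would be absorbed into the
    scale parameter.
    """
    v_hxd = np.asarray(v_hxd_list, dtype=float)
    if np.any(v_hxd < 0) or np.any(v_hxd > v_tot):
        raise InvalidInputError("v_hxd values must lie in [0, v_tot]")
    rng = np.random.default_rng(config.seed)
    retained = 1.0 - config.loss_fraction * (v_tot - v_hxd) / v_tot
    pa = (
        modified_vprhs_predict(scale, config.true_log_k, v_tot, v_hxd)
        * retained
        * _noise_factors(rng, config.noise_cv, v_hxd.size)
    )
    return HeadspaceSeries(
        compound=compound,
        points=list(zip(v_hxd, pa)),
        kind="modified",
        v_tot=v_tot,
    )


def simulate_standard_vprhs(
    config: SimulationConfig,
    v_water_list: Sequence[float],
    vial_volume: float = VPRHS_V_TOT,
    scale: float = 1000.0,
    compound: str = "synthetic",
) -> HeadspaceSeries:
    """Simulate a water-only VPR-HS series for direct K_aw measurement."""
    v_water = np.asarray(v_water_list, dtype=float)
    if np.any(v_water < 0) or np.any(v_water >= vial_volume):
        raise InvalidInputError("v_water must lie in [0, vial_volume)")
    rng = np.random.default_rng(config.seed)
    retained = 1.0 - config.loss_fraction * v_water / vial_volume
    pa = (
        standard_vprhs_predict(
            scale, config.true_log_k, vial_volume - v_water, v_water
        )
        * retained
        * _noise_factors(rng, config.noise_cv, v_water.size)
    )
    return HeadspaceSeries(
        compound=compound,
        points=list(zip(v_water, pa)),
        kind="standard",
        vial_volume=vial_volume,
    )


def make_homologue_panel(
    unit: str,
    counts: Sequence[int],
    intercept: float,
    slope: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    quantity: str = "aw",
    label: str = "synthetic panel",
) -> HomologueSeries:
    """Synthetic homologue series: log K = intercept + slope*count + noise."""
    counts = list(counts)
    if len(counts) < 2:
        raise InvalidInputError("need at least two unit counts")
    rng = np.random.default_rng(seed)
    members = [
        (
            f"member-{c}",
            int(c),
            intercept + slope * c + rng.normal(0.0, noise_sd),
        )
        for c in counts
    ]
    return HomologueSeries(
        label=label, unit=unit, members=members, quantity=quantity
    )
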