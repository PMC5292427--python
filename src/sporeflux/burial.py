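"""Burial decay and deposition-flux budget for endospores in sediment.

Culturable endospore abundance decreases with sediment depth. With an
age model attached to each depth, a first-order loss model

    N(age) = N0 * exp(-lambda * age),   half-life = ln2 / lambda

is fit by ordinary least squares of ln(abundance) on age (log-linear,
matching a straight line on a log-axis abundance/age plot; non-detects
are excluded from the fit but should be retained in reports).

The standing inventory in the surface mixed layer, combined with the
sediment accumulation rate omega, yields a deposition flux

    F = N_total [cm^-3] * omega [cm/yr] * 1e4 [cm^2/m^2]   (spores m^-2 yr^-1)

optionally corrected by lambda*T / (1 - e^{-lambda*T}) — the factor that
restores the constant deposition rate which, after first-order decay
over an accumulation horizon of T years, would leave the observed
standing abundance. Dividing the flux by the annual water-column
throughput per m^2 of seafloor (depth * 1e6 mL/m^3 * 365/residence-days)
gives the spore load each mL of inflowing seawater must deliver.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .units import CM2_PER_M2, DAYS_PER_YEAR, ML_PER_M3

__all__ = [
    "DecayFit",
    "BudgetParams",
    "NoDecayError",
    "fit_decay",
    "deposition_flux",
    "seawater_supply",
    "community_fraction",
]


class NoDecayError(ValueError):
    """The fitted decay constant is not positive."""


@dataclass(frozen=True)
class DecayFit:
    n0: float  # abundance at age 0, per mL
    lam: float  # decay constant, 1/yr
    r_squared: float

    @property
    def half_life(self) -> float:
        """Half-life in years, ln2/lambda."""
        return math.log(2.0) / self.lam

    def abundance_at(self, age_yr: float) -> float:
        return self.n0 * math.exp(-self.lam * age_yr)


@dataclass(frozen=True)
class BudgetParams:
    """Constants of the deposition/supply budget (defaults describe a
    shallow depositional coastal basin)."""

    sed_rate: float = 0.09  # omega, cm per year
    srb_abundance: float = 1.0e4  # sulfate-reducer endospores per mL
    water_depth: float = 15.0  # m, basin mean
    residence_days: float = 12.0  # tau, mean water residence time
    horizon_years: float = 100.0  # T, accumulation horizon
    decay: float = math.log(2.0) / 350.0  # lambda, 1/yr

    def __post_init__(self) -> None:
        for name in ("sed_rate", "srb_abundance", "water_depth",
                     "residence_days", "horizon_years", "decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def fit_decay(profile: pd.DataFrame) -> DecayFit:
    """Fit first-order decay to an abundance/age profile.

    ``profile`` needs columns ``age_yr`` and ``abundance_per_ml``; rows
    with ``detected == False`` (when the column is present) or with
    non-positive abundance are excluded. At least two detected records
    with distinct ages are required.
    """
    required = {"age_yr", "abundance_per_ml"}
    if not required.issubset(profile.columns):
        raise ValueError(f"profile requires columns {sorted(required)}")
    df = profile
    if "detected" in df.columns:
        df = df[df["detected"].astype(bool)]
    df = df[df["abundance_per_ml"] > 0]
    ages = df["age_yr"].to_numpy(float)
    abundance = df["abundance_per_ml"].to_numpy(float)
    if len(np.unique(ages)) < 2:
        raise ValueError(
            "need >= 2 detected records with distinct ages and "
            "positive abundance"
        )
    fit = stats.linregress(ages, np.log(abundance))
    lam = -float(fit.slope)
    if lam <= 0:
        raise NoDecayError("no decay: fitted rate constant is not positive")
    return DecayFit(
        n0=float(math.exp(fit.intercept)),
        lam=lam,
        r_squared=float(fit.rvalue**2),
    )


def decay_correction_factor(lam: float, horizon_years: float) -> float:
    """lambda*T / (1 - e^{-lambda*T}), with the lambda -> 0 limit 1."""
    lt = lam * horizon_years
    if lt < 1e-12:
        return 1.0
    return lt / -math.expm1(-lt)


def deposition_flux(
    n_tfe: float,
    params: BudgetParams,
    decay_corrected: bool = False,
) -> float:
    """Deposition flux of thermophilic endospores, spores m^-2 yr^-1.

    The fermentative abundance ``n_tfe`` (per mL of sediment) is summed
    with the sulfate-reducer abundance in ``params`` before multiplying
    by the sedimentation rate. With ``decay_corrected=True`` the flux is
    scaled by lambda*T/(1 - e^{-lambda*T}) to undo first-order loss over
    the accumulation horizon.
    """
    if n_tfe < 0:
        raise ValueError("abundance must be >= 0")
    flux = (n_tfe + params.srb_abundance) * params.sed_rate * CM2_PER_M2
    if decay_corrected:
        flux *= decay_correction_factor(params.decay, params.horizon_years)
    return flux


def seawater_supply(flux: float, params: BudgetParams) -> float:
    """Spores each mL of inflowing seawater must carry to sustain
    ``flux`` (spores m^-2 yr^-1), given the basin's mean depth and water
    residence time."""
    if flux < 0:
        raise ValueError("flux must be >= 0")
    throughput = (
        params.water_depth * ML_PER_M3 * (DAYS_PER_YEAR / params.residence_days)
    )  # mL of water passing over each m^2 of seafloor per year
    return flux / throughput


def community_fraction(n_tfe: float, n_srb: float, n_total: float) -> float:
    """Thermophilic endospores (fermentative + sulfate-reducing) as a
    percentage of the total endospore community."""
    if n_total <= 0:
        raise ValueError("total endospore abundance must be > 0")
    if n_tfe < 0 or n_srb < 0:
        raise ValueError("abundances must be >= 0")
    return 100.0 * (n_tfe + n_srb) / n_total
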