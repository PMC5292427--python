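"""Growth-kinetics enumeration of germinating endospores.

A pasteurized sediment slurry incubated at growth-permissive temperature
shows a lag phase (germination and outgrowth of the surviving endospores)
followed by exponential accumulation of fermentation products — volatile
fatty acids (VFAs) and H2 — once the germinated cells start dividing.
This module turns such an incubation time course into:

* an onset time for detectable VFA production,
* an exponential fit anchored at the pre-onset baseline,
* the initial VFA-carbon production rate and population doubling time,
* a cell-specific production rate (calibrated against FISH counts of
  active cells), and finally
* the density of germinated endospores in the slurry and, via the
  slurry dilution ratio, in the original sediment.

VFA concentrations are combined on a carbon basis ("VFA-carbon"): the
molar concentration of each acid weighted by the number of carbon atoms
per molecule, so that e.g. 1 mM acetate contributes 2 mM C.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import mM_to_mol_per_ml

__all__ = [
    "CARBON_ATOMS",
    "SlurrySpec",
    "TimeCourse",
    "GrowthFit",
    "AbundanceEstimate",
    "OnsetNotDetectedError",
    "NoGrowthError",
    "vfa_carbon",
    "detect_onset",
    "fit_exponential",
    "cell_specific_rate",
    "abundance_from_rate",
    "dilution_consistency",
]

#: Registry of supported VFA species -> carbon atoms per molecule.
CARBON_ATOMS: dict[str, int] = {
    "formate": 1,
    "acetate": 2,
    "propionate": 3,
    "lactate": 3,
    "butyrate": 4,
    "isobutyrate": 4,
    "valerate": 5,
    "isovalerate": 5,
}

#: Non-VFA analyte columns allowed in a time-course table.
AUX_COLUMNS = ("h2_ppm", "dpa_nM", "fish_cells_per_ml")


class OnsetNotDetectedError(ValueError):
    """No sample ever exceeded the baseline threshold."""


class NoGrowthError(ValueError):
    """The fitted exponential rate constant is not positive."""


@dataclass(frozen=True)
class SlurrySpec:
    """How a slurry was mixed: `sediment_parts` volumes of sediment per
    `medium_parts` volumes of medium (a 1:2 slurry has 1 and 2)."""

    sediment_parts: int = 1
    medium_parts: int = 2
    pasteurized: bool = True
    amendments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sediment_parts < 0 or self.medium_parts < 0:
            raise ValueError("slurry parts must be non-negative")

    @property
    def sediment_fraction(self) -> float:
        if self.sediment_parts < 1:
            raise ValueError(
                "sediment_parts must be >= 1 for a sediment conversion"
            )
        return self.sediment_parts / (self.sediment_parts + self.medium_parts)

    @property
    def dilution_factor(self) -> float:
        """Multiplier taking a per-mL-slurry density to per-mL-sediment."""
        return 1.0 / self.sediment_fraction


def vfa_carbon(vfa_map: dict[str, float]) -> float:
    """Total VFA-carbon (mM C) of a map species -> concentration (mM).

    Each concentration is weighted by the carbon atoms per molecule of
    that acid; unknown species are rejected by name.
    """
    total = 0.0
    for species, conc in vfa_map.items():
        if species not in CARBON_ATOMS:
            raise ValueError(f"unknown VFA species: {species!r}")
        total += conc * CARBON_ATOMS[species]
    return total


@dataclass
class TimeCourse:
    """One incubation time course.

    ``data`` holds one row per sampling time with a ``time_h`` column,
    one ``<species>_mM`` column per measured VFA, and optionally
    ``h2_ppm``, ``dpa_nM`` and ``fish_cells_per_ml``.
    """

    data: pd.DataFrame
    slurry: SlurrySpec = field(default_factory=SlurrySpec)

    def __post_init__(self) -> None:
        if "time_h" not in self.data.columns:
            raise ValueError("time course requires a time_h column")
        t = self.data["time_h"].to_numpy(float)
        if len(t) == 0:
            raise ValueError("time course is empty")
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                "times must be strictly ascending (duplicate time points "
                "are rejected, not averaged)"
            )
        if not self.species():
            raise ValueError("time course has no VFA species columns")
        for col in self.data.columns:
            if col == "time_h" or col in AUX_COLUMNS:
                continue
            if col.endswith("_mM"):
                species = col[: -len("_mM")]
                if species not in CARBON_ATOMS:
                    raise ValueError(f"unknown VFA species: {species!r}")
                if np.any(self.data[col].to_numpy(float) < 0):
                    raise ValueError(f"negative concentrations in {col}")

    def species(self) -> list[str]:
        return [
            c[: -len("_mM")]
            for c in self.data.columns
            if c.endswith("_mM") and c[: -len("_mM")] in CARBON_ATOMS
        ]

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    def vfa_carbon_series(self) -> np.ndarray:
        """VFA-carbon (mM C) at every sampling time."""
        total = np.zeros(len(self.data))
        for sp in self.species():
            total += self.data[f"{sp}_mM"].to_numpy(float) * CARBON_ATOMS[sp]
        return total

    def acetate_series(self) -> np.ndarray:
        """Acetate-carbon (mM C), usable as a proxy when acetate dominates."""
        if "acetate_mM" not in self.data.columns:
            raise ValueError("no acetate_mM column in time course")
        return self.data["acetate_mM"].to_numpy(float) * CARBON_ATOMS["acetate"]


@dataclass(frozen=True)
class GrowthFit:
    """Exponential fit C(t) = C0 * exp(k (t - t_on)) anchored at the
    baseline mean C0; rates derive from it analytically."""

    c0: float  # mM C, baseline anchor
    k: float  # 1/h, exponential rate constant
    t_on: float  # h, anchor/onset time (start of fit window)
    window: tuple[float, float]
    rmse_log: float

    @property
    def r_on(self) -> float:
        """Initial production rate dC/dt at t_on (mM C / h) = k*C0."""
        return self.k * self.c0

    @property
    def doubling_time_min(self) -> float:
        """Population doubling time in minutes, 60*ln2/k."""
        return 60.0 * math.log(2.0) / self.k


@dataclass(frozen=True)
class AbundanceEstimate:
    """Endospore density inferred from a production rate (or another
    assay), in the slurry and converted to the undiluted sediment."""

    n_slurry: float  # cells per mL slurry
    n_sediment: float  # cells per mL sediment
    q_used: float  # mol C per cell per h
    method: str = "vfa_rate"


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"empty window {window}")
    return (t >= lo) & (t <= hi)


def detect_onset(
    tc: TimeCourse,
    baseline_window: tuple[float, float] = (0.0, 3.5),
    threshold_sigmas: float = 3.0,
    use_acetate_proxy: bool = False,
) -> float:
    """Estimate the onset time of VFA production.

    The baseline mean and SD are taken over ``baseline_window`` (at least
    three samples); the SD is floored at 5% of the baseline mean so that
    noiseless data still yield a usable threshold. The onset estimate is
    the sampling time *preceding* the first sample whose VFA-carbon
    exceeds mean + ``threshold_sigmas``*SD.
    """
    t = tc.times
    c = tc.acetate_series() if use_acetate_proxy else tc.vfa_carbon_series()
    base = c[_window_mask(t, baseline_window)]
    if len(base) < 3:
        raise ValueError(
            f"need >= 3 samples in baseline window {baseline_window}, "
            f"got {len(base)}"
        )
    mean = float(np.mean(base))
    sd = max(float(np.std(base, ddof=1)), 0.05 * mean)
    threshold = mean + threshold_sigmas * sd
    above = np.nonzero(c > threshold)[0]
    if len(above) == 0:
        raise OnsetNotDetectedError("no onset detected")
    i = int(above[0])
    return float(t[max(i - 1, 0)])


def fit_exponential(
    tc: TimeCourse,
    fit_window: tuple[float, float] = (3.5, 5.0),
    baseline_window: tuple[float, float] = (0.0, 3.5),
    free_intercept: bool = False,
    use_acetate_proxy: bool = False,
) -> GrowthFit:
    """Fit exponential growth of VFA-carbon over ``fit_window``.

    The baseline concentration C0 is the mean over ``baseline_window``
    and is used as the fixed starting point of the fit: the default is a
    single-parameter ordinary least squares of ln(C) against (t - t_on)
    with the intercept pinned at ln(C0), where t_on is the start of the
    fit window. ``free_intercept=True`` instead fits slope and intercept
    jointly and re-derives C0 = exp(intercept).
    """
    t = tc.times
    c = tc.acetate_series() if use_acetate_proxy else tc.vfa_carbon_series()

    base = c[_window_mask(t, baseline_window)]
    if len(base) == 0:
        raise ValueError(f"no samples in baseline window {baseline_window}")
    c0 = float(np.mean(base))
    if c0 <= 0:
        raise ValueError("baseline mean must be positive")

    m = _window_mask(t, fit_window)
    if int(m.sum()) < 2:
        raise ValueError(f"need >= 2 samples in fit window {fit_window}")
    tw, cw = t[m], c[m]
    if np.any(cw <= 0):
        raise ValueError("non-positive concentrations in fit window")

    t_on = float(fit_window[0])
    x = tw - t_on
    y = np.log(cw) - math.log(c0)
    if free_intercept:
        k, b = np.polyfit(x, y, 1)
        k = float(k)
        c0 = c0 * math.exp(float(b))
        resid = y - (k * x + b)
    else:
        # single-parameter regression through the anchored origin
        k = float(np.dot(x, y) / np.dot(x, x))
        resid = y - k * x
    if k <= 0:
        raise NoGrowthError("no exponential growth")
    rmse = float(np.sqrt(np.mean(resid**2)))
    return GrowthFit(c0=c0, k=k, t_on=t_on, window=tuple(fit_window), rmse_log=rmse)


def cell_specific_rate(rate_mM_per_h: float, fish_cells_per_ml: float) -> float:
    """Cell-specific VFA-carbon production rate (mol C per cell per h).

    Divides a bulk production rate by the density of active cells
    counted by FISH at the same time point.
    """
    if fish_cells_per_ml <= 0:
        raise ValueError("fish_cells_per_ml must be > 0")
    return mM_to_mol_per_ml(rate_mM_per_h) / fish_cells_per_ml


def abundance_from_rate(
    r_on_mM_per_h: float,
    q_mol_per_cell_h: float,
    slurry: SlurrySpec,
) -> AbundanceEstimate:
    """Enumerate germinated endospores from the initial production rate.

    n_slurry = (initial rate in mol mL^-1 h^-1) / (cell-specific rate q);
    the sediment density follows from the slurry mixing ratio.
    """
    if q_mol_per_cell_h <= 0:
        raise ValueError("cell-specific rate q must be > 0")
    if r_on_mM_per_h < 0:
        raise ValueError("production rate must be >= 0")
    n_slurry = mM_to_mol_per_ml(r_on_mM_per_h) / q_mol_per_cell_h
    n_sediment = n_slurry * slurry.dilution_factor
    return AbundanceEstimate(
        n_slurry=n_slurry,
        n_sediment=n_sediment,
        q_used=q_mol_per_cell_h,
        method="vfa_rate",
    )


def dilution_consistency(spec_a: SlurrySpec, spec_b: SlurrySpec) -> float:
    """Fold difference in sediment content between two slurry recipes.

    Returns fraction_a / fraction_b where each fraction is the sediment
    volume fraction of the slurry; a 1:2 vs a 1:9 slurry gives 10/3.
    """
    return spec_a.sediment_fraction / spec_b.sediment_fraction
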