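"""Dipicolinic-acid (DPA) quantification and spore-equivalent conversion.

DPA is a chelate stored in the core of bacterial endospores and released
on germination; its dissolved concentration is therefore a proxy for the
number of spores that germinated. Concentrations are measured by
standard addition: known spikes are added to aliquots of the sample
(including an un-amended aliquot), the fluorescence signal is regressed
on the added concentration, and the sample concentration is the
magnitude of the x-axis intercept, |intercept/slope|.

Spore equivalents follow from a fixed per-spore DPA content
(default 2.24e-16 mol per endospore, a literature value that is
species-variable and therefore configurable, not hard-coded).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .units import nM_to_mol_per_ml

__all__ = [
    "DPA_MOL_PER_SPORE",
    "DPAResult",
    "NonResponsiveSeriesError",
    "quantify_standard_addition",
    "spores_from_dpa",
    "germination_fraction",
]

#: Default endospore-specific DPA content, mol per endospore.
DPA_MOL_PER_SPORE = 2.24e-16


class NonResponsiveSeriesError(ValueError):
    """The standard-addition series shows no positive signal response."""


@dataclass(frozen=True)
class DPAResult:
    conc_nM: float  # DPA concentration in the measured solution
    spores_per_ml: float  # spore equivalents
    r_squared: float
    dpa_per_spore: float = DPA_MOL_PER_SPORE


def quantify_standard_addition(
    series: pd.DataFrame,
    dpa_per_spore: float = DPA_MOL_PER_SPORE,
) -> DPAResult:
    """Quantify DPA from a standard-addition series.

    ``series`` needs columns ``added_nM`` and ``signal`` with at least
    two distinct addition levels, one of them the un-amended point.
    Ordinary (unweighted) least squares of signal on added concentration
    gives slope and intercept; the sample concentration is
    intercept/slope. A negative fitted concentration (possible from
    noise around a true blank) is clamped to zero with a warning.
    """
    if not {"added_nM", "signal"}.issubset(series.columns):
        raise ValueError("series requires added_nM and signal columns")
    added = series["added_nM"].to_numpy(float)
    signal = series["signal"].to_numpy(float)
    if np.any(signal < 0):
        raise ValueError("signals must be >= 0")
    if len(np.unique(added)) < 2:
        raise ValueError("need >= 2 distinct addition levels")
    fit = stats.linregress(added, signal)
    if not fit.slope > 0:
        raise NonResponsiveSeriesError(
            "non-responsive series: fitted slope is not positive"
        )
    conc = fit.intercept / fit.slope
    if conc < 0:
        warnings.warn(
            f"fitted concentration {conc:.3g} nM is negative; clamping to 0",
            stacklevel=2,
        )
        conc = 0.0
    conc = float(conc)
    spores = spores_from_dpa(nM_to_mol_per_ml(conc), dpa_per_spore)
    return DPAResult(
        conc_nM=conc,
        spores_per_ml=spores,
        r_squared=float(fit.rvalue**2),
        dpa_per_spore=dpa_per_spore,
    )


def spores_from_dpa(
    dpa_mol_per_ml: float,
    dpa_per_spore: float = DPA_MOL_PER_SPORE,
) -> float:
    """Convert a dissolved DPA amount (mol per mL) to spore equivalents
    per mL via the per-spore DPA content."""
    if dpa_per_spore <= 0:
        raise ValueError("dpa_per_spore must be > 0")
    if dpa_mol_per_ml < 0:
        raise ValueError("dpa amount must be >= 0")
    return dpa_mol_per_ml / dpa_per_spore


def germination_fraction(
    dpa_unpasteurized: float, dpa_pasteurized: float
) -> float:
    """Percent of the pasteurization-inducible DPA release that occurred
    without pasteurization (any consistent units for the two amounts)."""
    if dpa_pasteurized <= 0:
        raise ValueError("pasteurized DPA amount must be > 0")
    if dpa_unpasteurized < 0:
        raise ValueError("unpasteurized DPA amount must be >= 0")
    return 100.0 * dpa_unpasteurized / dpa_pasteurized
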