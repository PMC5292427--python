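"""Centralized unit conversions.

Concentrations are stored in mM (mmol per litre) throughout the package;
cell-specific rates and DPA-per-spore contents are in mol. All conversions
between the two conventions live here so that factors of 10^3/10^6 appear
exactly once.
"""

#: 1 mM = 1e-3 mol L^-1 = 1e-6 mol mL^-1
MM_PER_MOL_PER_ML = 1e6

#: 1 nM = 1e-9 mol L^-1 = 1e-12 mol mL^-1
NM_PER_MOL_PER_ML = 1e12

#: cm^2 per m^2 (areal flux conversion)
CM2_PER_M2 = 1e4

#: mL per m^3 (water-column throughput conversion)
ML_PER_M3 = 1e6

DAYS_PER_YEAR = 365.0


def mM_to_mol_per_ml(c_mM: float) -> float:
    """Convert a concentration in mM to mol per mL."""
    return c_mM / MM_PER_MOL_PER_ML


def mol_per_ml_to_mM(c: float) -> float:
    return c * MM_PER_MOL_PER_ML


def nM_to_mol_per_ml(c_nM: float) -> float:
    """Convert a concentration in nM to mol per mL."""
    return c_nM / NM_PER_MOL_PER_ML


def mol_per_ml_to_nM(c: float) -> float:
    return c * NM_PER_MOL_PER_ML
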