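"""Seeded generators for every input table the pipeline consumes.

The generators emulate the statistical structure the downstream analyses
assume, so that the whole pipeline is testable without external data:

* an incubation time course in which an exponentially growing population
  of freshly germinated endospores accumulates VFA-carbon after a lag
  (germination + outgrowth) phase, partitioned across VFA species;
* two-phase dipicolinic-acid (DPA) release: an instantaneous fraction
  released during pasteurization, the rest saturating exponentially
  during incubation;
* Poisson-seeded replicated serial-dilution (MPN) tube tables with
  acetate/H2 readouts for grown and blank tubes;
* standard-addition signal series for DPA quantification;
* exponentially decaying abundance-vs-depth profiles with multiplicative
  log-normal noise and a linear age model (age = depth / sedimentation
  rate — a stand-in for a radiocarbon age model).

Measurement noise is multiplicative Gaussian with a common coefficient
of variation, truncated at zero. Identical scenario + seed give
bit-identical tables.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import CARBON_ATOMS, SlurrySpec, TimeCourse
from .units import mol_per_ml_to_mM

__all__ = [
    "SlurryScenario",
    "MPNScenario",
    "ProfileScenario",
    "simulate_slurry_timecourse",
    "simulate_mpn_tubes",
    "simulate_depth_profile",
    "simulate_standard_addition",
    "AARHUS_SURFACE",
    "AARHUS_MPN",
    "AARHUS_PROFILE",
]

# Default partition of VFA-carbon across species: acetate dominates the
# fermentation products by roughly an order of magnitude in molar terms.
DEFAULT_VFA_SPLIT: Mapping[str, float] = MappingProxyType(
    {"acetate": 0.80, "propionate": 0.08, "butyrate": 0.05, "formate": 0.04,
     "lactate": 0.03}
)

_DOUBLING_22_MIN = math.log(2.0) / (22.0 / 60.0)  # 1/h


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SlurryScenario:
    """Parameters of the germination/outgrowth incubation model.

    The noiseless VFA-carbon curve is

        C(t) = C_bg                                   for t < t_lag
        C(t) = C_bg + (q N0 / mu) (e^{mu (t-t_lag)} - 1)   for t >= t_lag

    i.e. a population of ``n0`` cells per mL slurry, each producing
    VFA-carbon at ``q`` mol C/cell/h, growing exponentially at rate
    ``mu`` after the lag. When ``c_bg`` is left at its default
    q*N0/mu (expressed in mM), the curve is exactly C_bg e^{mu dt} and
    the baseline-anchored fit recovers (mu, N0) without bias.
    """

    n0: float = 2.0e6  # cells per mL slurry
    q: float = 6.4e-13  # mol C per cell per h (640 fmol)
    t_lag: float = 3.5  # h
    mu: float = _DOUBLING_22_MIN  # 1/h (22-min doubling)
    c_bg: float | None = None  # mM C; None -> q*n0/mu (consistent baseline)
    vfa_split: Mapping[str, float] = field(
        default_factory=lambda: DEFAULT_VFA_SPLIT
    )
    dpa_total: float = 582.4  # nM releasable DPA pool
    f_past: float = 0.7  # fraction released during pasteurization
    tau_dpa: float = 0.15  # h, saturation time constant at 50C
    h2_yield: float = 800.0  # ppm headspace H2 per mM C produced
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n0", "q", "t_lag", "mu", "dpa_total", "tau_dpa",
                     "h2_yield", "noise_cv"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(0.0 <= self.f_past <= 1.0, "f_past must be in [0, 1]")
        if self.c_bg is not None:
            _require(self.c_bg >= 0, "c_bg must be >= 0")
        for sp, frac in self.vfa_split.items():
            _require(sp in CARBON_ATOMS, f"vfa_split: unknown species {sp!r}")
            _require(frac >= 0, f"vfa_split[{sp!r}] must be >= 0")
        _require(
            abs(sum(self.vfa_split.values()) - 1.0) < 1e-9,
            "vfa_split fractions must sum to 1",
        )

    @property
    def c_bg_mM(self) -> float:
        """Baseline VFA-carbon (mM). The default q*N0/mu makes the
        baseline the natural continuation of the exponential."""
        if self.c_bg is not None:
            return self.c_bg
        if self.mu == 0:
            raise ValueError("c_bg must be given explicitly when mu == 0")
        return mol_per_ml_to_mM(self.q * self.n0) / self.mu


@dataclass(frozen=True)
class MPNScenario:
    """Poisson seeding model of a replicated serial-dilution assay.

    Each tube at dilution level i receives ``volumes[i]`` mL of original
    sample; its spore count is Poisson(true_density * volume) and it
    grows if at least one seeded spore succeeds (probability
    ``p_detect`` each). Grown tubes acquire a high acetate signal,
    blanks a low one.
    """

    true_density: float = 4.3e4  # viable culturable spores per mL
    volumes: tuple[float, ...] = tuple(10.0 ** (1 - n) for n in range(1, 8))
    replicates: int = 3
    p_detect: float = 1.0
    acetate_pos_mean: float = 3.0  # mM
    acetate_neg_mean: float = 0.10  # mM
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.true_density >= 0, "true_density must be >= 0")
        _require(len(self.volumes) >= 1, "volumes must be non-empty")
        _require(all(v > 0 for v in self.volumes), "volumes must be > 0")
        _require(
            all(a > b for a, b in zip(self.volumes, self.volumes[1:])),
            "volumes must be strictly decreasing",
        )
        _require(self.replicates >= 1, "replicates must be >= 1")
        _require(0 < self.p_detect <= 1, "p_detect must be in (0, 1]")
        _require(self.acetate_pos_mean >= 0, "acetate_pos_mean must be >= 0")
        _require(self.acetate_neg_mean >= 0, "acetate_neg_mean must be >= 0")


@dataclass(frozen=True)
class ProfileScenario:
    """First-order loss of culturable spores during burial.

    abundance(depth) = N0 * 2^{-age/half_life} * 10^eps with
    eps ~ Normal(0, noise_sd_log10) and a linear age model
    age = depth / sed_rate.
    """

    n0: float = 4.3e4  # spores per mL at age 0
    half_life: float = 350.0  # years
    sed_rate: float = 0.09  # cm per year
    depths: tuple[float, ...] = (4, 25, 70, 120, 170, 220, 270, 370)
    noise_sd_log10: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n0 >= 0, "n0 must be >= 0")
        _require(self.half_life > 0, "half_life must be > 0")
        _require(self.sed_rate > 0, "sed_rate must be > 0")
        _require(len(self.depths) >= 1, "depths must be non-empty")
        _require(all(d >= 0 for d in self.depths), "depths must be >= 0")
        _require(self.noise_sd_log10 >= 0, "noise_sd_log10 must be >= 0")


def _mult_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    """Multiplicative Gaussian noise truncated at zero. Always draws,
    so the random stream does not depend on cv."""
    eps = rng.standard_normal(values.shape)
    if cv == 0:
        return values
    return np.clip(values * (1.0 + cv * eps), 0.0, None)


def noiseless_vfa_carbon(scenario: SlurryScenario, times: np.ndarray) -> np.ndarray:
    """The generating VFA-carbon curve (mM C) without noise."""
    s = scenario
    dt = np.clip(np.asarray(times, float) - s.t_lag, 0.0, None)
    qn0_mM = mol_per_ml_to_mM(s.q * s.n0)  # mM C per h
    if s.mu == 0:
        return s.c_bg_mM + qn0_mM * dt
    return s.c_bg_mM + (qn0_mM / s.mu) * np.expm1(s.mu * dt)


def simulate_slurry_timecourse(
    scenario: SlurryScenario, times: Sequence[float]
) -> TimeCourse:
    """Simulate one incubation time course.

    Returns a :class:`~sporeflux.growth.TimeCourse` with one record per
    requested time: per-species VFA concentrations (the generating
    VFA-carbon split across species and divided by carbon counts), H2,
    DPA and FISH cell counts, each with multiplicative noise.
    """
    s = scenario
    t = np.asarray(list(times), float)
    _require(t.size > 0, "times must be non-empty")
    _require(bool(np.all(t >= 0)), "times must be non-negative")
    _require(bool(np.all(np.diff(t) > 0)), "times must be strictly ascending")

    rng = np.random.default_rng(s.seed)
    c_total = noiseless_vfa_carbon(s, t)
    dt = np.clip(t - s.t_lag, 0.0, None)
    fish = np.where(t >= s.t_lag, s.n0 * np.exp(s.mu * dt), 0.0)
    if s.tau_dpa > 0:
        release = 1.0 - np.exp(-t / s.tau_dpa)
    else:
        release = np.ones_like(t)
    dpa = s.dpa_total * (s.f_past + (1.0 - s.f_past) * release)
    h2 = s.h2_yield * (c_total - s.c_bg_mM)

    cols: dict[str, np.ndarray] = {"time_h": t}
    for sp in sorted(s.vfa_split):
        conc = c_total * s.vfa_split[sp] / CARBON_ATOMS[sp]
        cols[f"{sp}_mM"] = _mult_noise(rng, conc, s.noise_cv)
    cols["h2_ppm"] = _mult_noise(rng, h2, s.noise_cv)
    cols["dpa_nM"] = _mult_noise(rng, dpa, s.noise_cv)
    cols["fish_cells_per_ml"] = _mult_noise(rng, fish, s.noise_cv)

    slurry = SlurrySpec(1, 2, pasteurized=True,
                        amendments=("spirulina", "molybdate"))
    return TimeCourse(data=pd.DataFrame(cols), slurry=slurry)


def simulate_mpn_tubes(scenario: MPNScenario) -> pd.DataFrame:
    """Simulate one MPN dilution experiment.

    Returns a tube table with columns ``level`` (1-based, largest volume
    first), ``volume_ml``, ``acetate_mM`` and ``h2_ppm``. Grown tubes
    draw acetate from Normal(acetate_pos_mean, 10% CV), blanks from
    Normal(acetate_neg_mean, 50% CV), both truncated at zero.
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    rows = []
    for level, v in enumerate(s.volumes, start=1):
        seeded = rng.poisson(s.true_density * v, s.replicates)
        if s.p_detect < 1.0:
            success = rng.binomial(seeded, s.p_detect)
        else:
            success = seeded
        grown = success > 0
        ac_pos = rng.normal(s.acetate_pos_mean, 0.10 * s.acetate_pos_mean,
                            s.replicates)
        ac_neg = rng.normal(s.acetate_neg_mean, 0.50 * s.acetate_neg_mean,
                            s.replicates)
        h2_pos = rng.normal(2000.0, 200.0, s.replicates)
        h2_neg = rng.normal(5.0, 2.5, s.replicates)
        acetate = np.clip(np.where(grown, ac_pos, ac_neg), 0.0, None)
        h2 = np.clip(np.where(grown, h2_pos, h2_neg), 0.0, None)
        for j in range(s.replicates):
            rows.append(
                {"level": level, "volume_ml": v,
                 "acetate_mM": acetate[j], "h2_ppm": h2[j]}
            )
    return pd.DataFrame(rows)


def simulate_depth_profile(scenario: ProfileScenario) -> pd.DataFrame:
    """Simulate an abundance-vs-depth profile under first-order decay.

    Returns columns ``depth_cm``, ``age_yr``, ``abundance_per_ml`` and
    ``detected`` (always True; non-detects are an observational
    annotation, not part of the generating model).
    """
    s = scenario
    rng = np.random.default_rng(s.seed)
    depths = np.asarray(s.depths, float)
    ages = depths / s.sed_rate
    eps = rng.normal(0.0, 1.0, depths.size)
    noise = 10.0 ** (s.noise_sd_log10 * eps)
    abundance = s.n0 * np.power(2.0, -ages / s.half_life) * noise
    return pd.DataFrame(
        {
            "depth_cm": depths,
            "age_yr": ages,
            "abundance_per_ml": abundance,
            "detected": np.ones(depths.size, dtype=bool),
        }
    )


def simulate_standard_addition(
    true_conc: float,
    slope: float,
    additions: Sequence[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a standard-addition series.

    signal_i = slope * (true_conc + addition_i) * (1 + eps_i), with the
    un-amended point (addition 0) required. Returns columns
    ``added_nM`` and ``signal``.
    """
    _require(slope > 0, "slope must be > 0")
    _require(true_conc >= 0, "true_conc must be >= 0")
    adds = np.asarray(list(additions), float)
    _require(adds.size >= 1, "additions must be non-empty")
    _require(bool(np.any(adds == 0)), "additions must include the un-amended point (0)")
    rng = np.random.default_rng(seed)
    signal = _mult_noise(rng, slope * (true_conc + adds), noise_cv)
    return pd.DataFrame({"added_nM": adds, "signal": signal})


# --- Study-condition scenarios -------------------------------------------
# Defaults mirror the surface-sediment incubation conditions: 2e6 germinated
# cells per mL of a 1:2 slurry, 640 fmol C/cell/h, 3.5 h lag, 22-min
# doubling, and a DPA pool equivalent to 2.6e6 spores/mL at
# 2.24e-16 mol DPA per spore (582.4 nM).
AARHUS_SURFACE = SlurryScenario()
AARHUS_MPN = MPNScenario()
AARHUS_PROFILE = ProfileScenario()
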