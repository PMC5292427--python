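"""Most-probable-number (MPN) enumeration from serial-dilution assays.

A dilution-to-extinction assay inoculates replicated tubes with
decreasing volumes of sample and scores each tube as growth-positive or
negative. Under Poisson seeding, a tube receiving volume v of a sample
with density D spores/mL grows with probability p = 1 - e^{-D v}, so the
positive/negative pattern across levels carries a binomial likelihood

    L(D) = prod_i C(n_i, x_i) p_i^{x_i} (1 - p_i)^{n_i - x_i},
    p_i = 1 - e^{-D v_i},

maximized over D > 0. Confidence intervals come from the profile
likelihood (log-likelihood drop of chi2_1(0.95)/2 = 1.92 for a two-sided
95% interval); Cochran's classical log10-normal interval is available as
an alternative.

Tubes are scored positive on acetate strictly above a threshold
(default 0.60 mM); a high H2 reading (default above 1000 ppm) raises a
"growth suspected" advisory only — in the assay design it is the signal
used to decide when to terminate an incubation, not the scoring signal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from math import lgamma
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "TubeReading",
    "TubeScore",
    "MPNDesign",
    "MPNEstimate",
    "score_tube",
    "mpn_ml",
    "mpn_from_tubes",
    "informative_triplet",
    "round_for_report",
]

ACETATE_THRESHOLD_MM = 0.60
H2_THRESHOLD_PPM = 1000.0

# two-sided 95%: chi2_1(0.95)/2; one-sided 95%: chi2_1(0.90)/2
_DROP_TWO_SIDED = 1.9207
_DROP_ONE_SIDED = 1.3529


@dataclass(frozen=True)
class TubeReading:
    """One incubated tube: the volume (mL) of original sample it
    received and its chemical readouts."""

    volume: float  # mL of original sample in the tube
    acetate: float  # mM
    h2: float | None = None  # ppm headspace
    dilution_level: int | None = None

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be > 0")
        if self.acetate < 0:
            raise ValueError("acetate must be >= 0")
        if self.h2 is not None and self.h2 < 0:
            raise ValueError("h2 must be >= 0")


@dataclass(frozen=True)
class TubeScore:
    positive: bool
    growth_suspected: bool  # H2 advisory flag only


def score_tube(
    reading: TubeReading,
    acetate_threshold: float = ACETATE_THRESHOLD_MM,
    h2_threshold: float = H2_THRESHOLD_PPM,
) -> TubeScore:
    """Score a tube: positive iff acetate is *strictly* above the
    threshold. H2 above its threshold only flags growth as suspected."""
    positive = reading.acetate > acetate_threshold
    suspected = reading.h2 is not None and reading.h2 > h2_threshold
    return TubeScore(positive=positive, growth_suspected=suspected)


@dataclass(frozen=True)
class MPNDesign:
    """A scored dilution design: per level, the per-tube sample volume
    (mL), the number of tubes, and the number of positives."""

    volumes: tuple[float, ...]
    tubes: tuple[int, ...]
    positives: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.volumes) == len(self.tubes) == len(self.positives)):
            raise ValueError("volumes, tubes and positives must align")
        if len(self.volumes) == 0:
            raise ValueError("design must have at least one row")
        if any(v <= 0 for v in self.volumes):
            raise ValueError("volumes must be > 0")
        if any(n < 1 for n in self.tubes):
            raise ValueError("tube counts must be >= 1")
        if any(not 0 <= x <= n for x, n in zip(self.positives, self.tubes)):
            raise ValueError("positives must satisfy 0 <= positives <= tubes")

    def scaled(self, f: float) -> "MPNDesign":
        """The same outcome pattern with all volumes multiplied by f."""
        if f <= 0:
            raise ValueError("scale factor must be > 0")
        return MPNDesign(
            tuple(v * f for v in self.volumes), self.tubes, self.positives
        )


@dataclass(frozen=True)
class MPNEstimate:
    density: float  # spores per mL (ML estimate)
    ci_low: float
    ci_high: float
    loglik: float
    status: str  # "ok" | "all_negative" | "all_positive"
    ci_method: str = "profile"


def _loglik(design: MPNDesign, d: float) -> float:
    """Binomial log-likelihood at density d (includes the C(n,x) term)."""
    if d < 0:
        return -math.inf
    ll = 0.0
    for v, n, x in zip(design.volumes, design.tubes, design.positives):
        ll += lgamma(n + 1) - lgamma(x + 1) - lgamma(n - x + 1)
        dv = d * v
        if x > 0:
            if dv == 0:
                return -math.inf
            ll += x * math.log(-math.expm1(-dv))
        if n - x > 0:
            ll += -(n - x) * dv
    return ll


def _score(design: MPNDesign, d: float) -> float:
    """d(loglik)/dD; zero at the maximum-likelihood density."""
    s = 0.0
    for v, n, x in zip(design.volumes, design.tubes, design.positives):
        dv = d * v
        if x > 0:
            s += x * v * math.exp(-dv) / -math.expm1(-dv)
        s -= (n - x) * v
    return s


def _mle(design: MPNDesign) -> float:
    """Maximize the log-likelihood over D > 0: bounded search in log
    space, then polish by solving the score equation (relative
    precision far below 1e-6)."""
    # Crude moment-style starting scale: positives per total inoculated volume
    total_v = sum(v * n for v, n in zip(design.volumes, design.tubes))
    total_x = sum(design.positives)
    d0 = max(total_x / total_v, 1e-300)
    lo, hi = math.log(d0) - 12.0, math.log(d0) + 12.0
    res = minimize_scalar(
        lambda u: -_loglik(design, math.exp(u)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    d_hat = float(math.exp(res.x))
    # The score is positive below and negative above the optimum.
    a, b = d_hat / 2, d_hat * 2
    while _score(design, a) < 0:
        a /= 10.0
    while _score(design, b) > 0:
        b *= 10.0
    return float(brentq(lambda d: _score(design, d), a, b, rtol=1e-14))


def _profile_root(design: MPNDesign, target: float, lo: float, hi: float) -> float:
    return float(brentq(lambda d: _loglik(design, d) - target, lo, hi,
                        xtol=1e-300, rtol=1e-12))


def mpn_ml(design: MPNDesign, ci_method: str = "profile") -> MPNEstimate:
    """Maximum-likelihood MPN estimate with a 95% confidence interval.

    Degenerate patterns are reported by status: ``all_negative`` gives
    density 0 with a one-sided upper bound, ``all_positive`` an infinite
    estimate with a one-sided lower bound. Otherwise the 95% interval is
    the set of densities whose profile log-likelihood lies within 1.92
    of the maximum; ``ci_method="cochran"`` instead uses Cochran's
    log10-normal approximation (SE = 0.58/sqrt(tubes per level) for a
    10-fold series).
    """
    total_pos = sum(design.positives)
    total_neg = sum(n - x for n, x in zip(design.tubes, design.positives))

    if total_pos == 0:
        # L(D) = exp(-D sum(n v)); drop of 1.35 below the maximum at D=0
        sum_nv = sum(n * v for n, v in zip(design.tubes, design.volumes))
        return MPNEstimate(
            density=0.0,
            ci_low=0.0,
            ci_high=_DROP_ONE_SIDED / sum_nv,
            loglik=0.0,
            status="all_negative",
            ci_method="profile",
        )
    if total_neg == 0:
        # Likelihood increases monotonically in D; sup loglik = 0 at D=inf
        lo_bracket = 1e-12 / max(design.volumes)
        hi_bracket = 1e12 / min(design.volumes)
        ci_low = _profile_root(design, -_DROP_ONE_SIDED, lo_bracket, hi_bracket)
        return MPNEstimate(
            density=math.inf,
            ci_low=ci_low,
            ci_high=math.inf,
            loglik=0.0,
            status="all_positive",
            ci_method="profile",
        )

    d_hat = _mle(design)
    ll_hat = _loglik(design, d_hat)

    if ci_method == "profile":
        target = ll_hat - _DROP_TWO_SIDED
        lo_bracket = d_hat
        while _loglik(design, lo_bracket) > target:
            lo_bracket /= 10.0
        ci_low = _profile_root(design, target, lo_bracket, d_hat)
        hi_bracket = d_hat
        while _loglik(design, hi_bracket) > target:
            hi_bracket *= 10.0
        ci_high = _profile_root(design, target, d_hat, hi_bracket)
    elif ci_method == "cochran":
        n_bar = sum(design.tubes) / len(design.tubes)
        se_log10 = 0.58 / math.sqrt(n_bar)
        factor = 10.0 ** (1.96 * se_log10)
        ci_low, ci_high = d_hat / factor, d_hat * factor
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")

    return MPNEstimate(
        density=d_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        loglik=ll_hat,
        status="ok",
        ci_method=ci_method,
    )


def mpn_from_tubes(
    readings: Sequence[TubeReading],
    acetate_threshold: float = ACETATE_THRESHOLD_MM,
    h2_threshold: float = H2_THRESHOLD_PPM,
    ci_method: str = "profile",
) -> MPNEstimate:
    """Score raw tube readings and estimate density: the composition of
    :func:`score_tube` (per tube) and :func:`mpn_ml` (on the scored
    design). Tubes are grouped by their sample volume."""
    if len(readings) == 0:
        raise ValueError("no tube readings")
    groups: dict[float, list[TubeReading]] = {}
    for r in readings:
        groups.setdefault(r.volume, []).append(r)
    volumes = sorted(groups, reverse=True)
    tubes = tuple(len(groups[v]) for v in volumes)
    positives = tuple(
        sum(score_tube(r, acetate_threshold, h2_threshold).positive
            for r in groups[v])
        for v in volumes
    )
    design = MPNDesign(tuple(volumes), tubes, positives)
    return mpn_ml(design, ci_method=ci_method)


def informative_triplet(design: MPNDesign) -> MPNDesign:
    """Extract the three-level sub-design used for classical MPN table
    look-ups: the most dilute level with all tubes positive plus the
    next two more dilute levels (falling back to the three largest
    volumes when no level is all-positive, and to the last three levels
    when the all-positive level is too deep)."""
    k = len(design.volumes)
    if k <= 3:
        return design
    all_pos = [i for i in range(k)
               if design.positives[i] == design.tubes[i]]
    start = max(all_pos) if all_pos else 0
    start = min(start, k - 3)
    sl = slice(start, start + 3)
    return MPNDesign(design.volumes[sl], design.tubes[sl], design.positives[sl])


def round_for_report(density: float) -> float:
    """House rounding for reported densities: nearest integer below 100,
    two significant figures otherwise."""
    if not math.isfinite(density):
        return density
    if density < 100:
        return float(round(density))
    exponent = math.floor(math.log10(density))
    scale = 10.0 ** (exponent - 1)
    return round(density / scale) * scale
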