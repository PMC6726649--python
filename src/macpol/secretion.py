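"""Phenotype-dependent cytokine production by mass-action kinetics.

The mediators IL12 and IL10 relay the drive from the transcription-factor
abundances (NFkB, STAT1, STAT6) to the secreted cytokines IFNg and IL4:

    d(IFNg)/dt = e*IL12 - j*IFNg
    d(IL12)/dt = d*STAT1 + b*NFkB - c*IL10 - f*IL12 - e*IL12
    d(IL10)/dt = a*NFkB - 2c*IL10 + h*STAT6
    d(IL4)/dt  = g*STAT6 - i*IL4 - f*IL12

Because the system is linear in the cytokines, the steady state has the
closed form

    IL4*  = (g/i + f h / (2 i (e+f))) STAT6 - f d / (i (e+f)) STAT1
            - f (2b - a) / (2 i (e+f)) NFkB          (clamped at 0)
    IFNg* = e d / ((e+f) j) STAT1 + e (2b - a) / (2 (e+f) j) NFkB
            - e h / (2 (e+f) j) STAT6                (clamped at 0)

With the literature rates the numeric coefficients are ~2, ~808 h, ~0.223,
~0.0090 and ~32.7 h.  The STAT6->IL10 rate ``h`` is not available from the
literature; it is bounded by requiring that a mixed M1/M2 cell (STAT1 and
STAT6 both active, NFkB low) secretes both cytokines simultaneously, which
pins h to an open interval around the default 0.002.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateSet",
    "AbundanceTable",
    "SecretionState",
    "CoefficientSet",
    "production_rhs",
    "integrate_production",
    "closed_form_secretion",
    "unclamped_secretion",
    "compute_coefficients",
    "estimate_h",
    "state_to_abundance",
]

CYTOKINE_ORDER = ("IFNg", "IL12", "IL10", "IL4")
DRIVER_ORDER = ("NFkB", "STAT1", "STAT6")


@dataclass(frozen=True)
class RateSet:
    """First-order rate constants (per minute) of the production network."""

    a: float = 4.15e-4
    b: float = 4.15e-4
    c: float = 1.587e-4
    d: float = 1.38e-4
    e: float = 1.157e-5
    f: float = 9.26e-5
    g: float = 1.1e-3
    h: float = 2e-3
    i: float = 5.5e-4
    j: float = 1.7e-3

    def __post_init__(self) -> None:
        for name in "abcdefghij":
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name!r} must be finite and nonnegative, got {v!r}")

    def replace(self, **kwargs) -> "RateSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class AbundanceTable:
    """Normal protein abundances in ppm (proteomics database values).

    The NFkB figure is the RELA (p65) abundance, the rate-limiting family
    member in macrophage signaling.
    """

    STAT1: float = 531.0
    STAT6: float = 41.3
    NFkB: float = 26.5

    def __post_init__(self) -> None:
        for name in ("STAT1", "STAT6", "NFkB"):
            if getattr(self, name) <= 0:
                raise ValueError(f"abundance {name} must be positive")

    def as_driver_array(self) -> np.ndarray:
        """(NFkB, STAT1, STAT6) in the internal-state ordering."""
        return np.array([self.NFkB, self.STAT1, self.STAT6])


@dataclass(frozen=True)
class SecretionState:
    """Concentrations of the production network species (abundance units)."""

    IFNg: float = 0.0
    IL12: float = 0.0
    IL10: float = 0.0
    IL4: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.IFNg, self.IL12, self.IL10, self.IL4])


@dataclass(frozen=True)
class CoefficientSet:
    """Closed-form steady-state coefficients in the Table-of-rates algebra."""

    il4_stat6_const: float   # g/i
    il4_stat6_h_slope: float  # f/(2 i (e+f)), multiplies h*STAT6
    il4_stat1: float          # f d/(i (e+f))
    il4_nfkb: float           # f (2b-a)/(2 i (e+f))
    ifng_stat1: float         # e d/((e+f) j)
    ifng_nfkb: float          # e (2b-a)/(2 (e+f) j)
    ifng_stat6_h_slope: float  # e/(2 (e+f) j), multiplies h*STAT6


def compute_coefficients(rates: RateSet | None = None) -> CoefficientSet:
    """Evaluate the closed-form coefficients from the kinetic rates."""
    r = rates or RateSet()
    ef = r.e + r.f
    if ef <= 0 or r.i <= 0 or r.j <= 0:
        raise ValueError("closed form requires e+f > 0, i > 0 and j > 0")
    return CoefficientSet(
        il4_stat6_const=r.g / r.i,
        il4_stat6_h_slope=r.f / (2 * r.i * ef),
        il4_stat1=r.f * r.d / (r.i * ef),
        il4_nfkb=r.f * (2 * r.b - r.a) / (2 * r.i * ef),
        ifng_stat1=r.e * r.d / (ef * r.j),
        ifng_nfkb=r.e * (2 * r.b - r.a) / (2 * ef * r.j),
        ifng_stat6_h_slope=r.e / (2 * ef * r.j),
    )


def production_rhs(state, drivers, rates: RateSet | None = None) -> np.ndarray:
    """Mass-action derivatives of (IFNg, IL12, IL10, IL4).

    ``drivers`` is the (NFkB, STAT1, STAT6) abundance triple held constant on
    the fast intracellular time scale.  No clamping is applied here; the
    closed-form outputs are clamped instead.
    """
    r = rates or RateSet()
    if isinstance(state, SecretionState):
        state = state.as_array()
    ifng, il12, il10, il4 = np.asarray(state, dtype=float)
    nfkb, stat1, stat6 = np.asarray(drivers, dtype=float)
    return np.array(
        [
            r.e * il12 - r.j * ifng,
            r.d * stat1 + r.b * nfkb - r.c * il10 - r.f * il12 - r.e * il12,
            r.a * nfkb - 2 * r.c * il10 + r.h * stat6,
            r.g * stat6 - r.i * il4 - r.f * il12,
        ]
    )


def integrate_production(
    drivers,
    rates: RateSet | None = None,
    state0=None,
    horizon: float = 2e5,
) -> np.ndarray:
    """Long-time numeric integration of the production ODEs (no clamping).

    Serves as the dynamic counterpart of :func:`closed_form_secretion`; the
    slowest relaxation rate is 2c ~ 3e-4/min, so the default horizon covers
    ~30 relaxation times.
    """
    r = rates or RateSet()
    y0 = np.zeros(4) if state0 is None else np.asarray(state0, dtype=float)
    sol = solve_ivp(
        lambda t, y: production_rhs(y, drivers, r),
        (0.0, horizon),
        y0,
        method="LSODA",
        rtol=3e-14,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"production integration failed: {sol.message}")
    return sol.y[:, -1]


def closed_form_secretion(drivers, rates: RateSet | None = None) -> tuple[float, float]:
    """Steady-state (IL4, IFNg) secretion, each clamped at zero.

    ``drivers`` may be a single (NFkB, STAT1, STAT6) triple or a batch of
    shape (m, 3); outputs broadcast accordingly.
    """
    r = rates or RateSet()
    co = compute_coefficients(r)
    d = np.asarray(drivers, dtype=float)
    nfkb, stat1, stat6 = d[..., 0], d[..., 1], d[..., 2]
    il4 = (
        (co.il4_stat6_const + co.il4_stat6_h_slope * r.h) * stat6
        - co.il4_stat1 * stat1
        - co.il4_nfkb * nfkb
    )
    ifng = (
        co.ifng_stat1 * stat1
        + co.ifng_nfkb * nfkb
        - co.ifng_stat6_h_slope * r.h * stat6
    )
    il4 = np.maximum(il4, 0.0)
    ifng = np.maximum(ifng, 0.0)
    if d.ndim == 1:
        return float(il4), float(ifng)
    return il4, ifng


def unclamped_secretion(drivers, rates: RateSet | None = None) -> tuple[float, float]:
    """Closed-form steady-state (IL4, IFNg) without the zero clamp."""
    r = rates or RateSet()
    co = compute_coefficients(r)
    nfkb, stat1, stat6 = np.asarray(drivers, dtype=float)
    il4 = (
        (co.il4_stat6_const + co.il4_stat6_h_slope * r.h) * stat6
        - co.il4_stat1 * stat1
        - co.il4_nfkb * nfkb
    )
    ifng = (
        co.ifng_stat1 * stat1 + co.ifng_nfkb * nfkb - co.ifng_stat6_h_slope * r.h * stat6
    )
    return float(il4), float(ifng)


def estimate_h(
    rates: RateSet | None = None,
    abundances: AbundanceTable | None = None,
) -> tuple[float, float]:
    """Feasible open interval for the STAT6->IL10 rate ``h``.

    A cell exposed to high IFNg and IL4 simultaneously sits in the
    (Low, High, High) state and must secrete both cytokines.  With NFkB at
    zero and STAT1/STAT6 at their normal abundances, IL4-positivity yields the
    lower bound and IFNg-positivity the upper bound.
    """
    r = rates or RateSet()
    ab = abundances or AbundanceTable()
    co = compute_coefficients(r)
    s1, s6 = ab.STAT1, ab.STAT6
    # (g/i + slope*h)*S6 - c_S1*S1 > 0   =>   h > (c_S1*S1 - (g/i)*S6) / (slope*S6)
    h_lo = (co.il4_stat1 * s1 - co.il4_stat6_const * s6) / (co.il4_stat6_h_slope * s6)
    # c_S1'*S1 - slope'*h*S6 > 0         =>   h < c_S1'*S1 / (slope'*S6)
    h_hi = co.ifng_stat1 * s1 / (co.ifng_stat6_h_slope * s6)
    h_lo = max(h_lo, 0.0)
    if h_lo >= h_hi:
        raise ValueError(
            f"infeasible h interval: lower bound {h_lo:g} >= upper bound {h_hi:g}"
        )
    return float(h_lo), float(h_hi)


def state_to_abundance(x, abundances: AbundanceTable | None = None) -> np.ndarray:
    """Map normalized internal states to driver abundances.

    Linear scaling with x = 0.5 at the normal abundance: Low (0) -> 0,
    Medium (0.5) -> normal, High (1) -> twice normal.  Batched input (m, 3)
    returns (m, 3); ordering is (NFkB, STAT1, STAT6).
    """
    ab = abundances or AbundanceTable()
    x = np.asarray(x, dtype=float)
    return x * 2.0 * ab.as_driver_array()
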