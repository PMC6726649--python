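"""Shared fixtures and the independent scalar-reduction oracle.

The oracle exploits the chain structure of the default macrophage circuit:
at any equilibrium STAT6 is an explicit function of STAT1, NFkB an explicit
function of (STAT1, STAT6), and STAT1 solves a scalar fixed-point equation.
Scanning that scalar residual on a fine lattice and polishing sign changes
with Brent's method enumerates *all* equilibria without multi-start Newton
or branch tracking, giving an independent cross-check for the package's
solvers and fold locations.
"""

import numpy as np
import pytest
from scipy.optimize import brentq

from macpol import AbundanceTable, NetworkSpec, RateSet

SIGMA = 8.0


@pytest.fixture(scope="session")
def spec():
    return NetworkSpec.macrophage()


@pytest.fixture(scope="session")
def rates():
    return RateSet()


@pytest.fixture(scope="session")
def abundances():
    return AbundanceTable()


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def oracle_equilibria(lps, ifng, il4, n=2001):
    """All equilibria of the default circuit via the scalar reduction."""

    def stat6(s1):
        return _sigmoid(SIGMA * (0.05 - s1 + il4))

    def nfkb(s1, s6):
        return _sigmoid(SIGMA * (-1.4 + lps + s1 - s6))

    def resid(s1):
        s6 = stat6(s1)
        return _sigmoid(SIGMA * (ifng + nfkb(s1, s6) - s6)) - s1

    xs = np.linspace(0.0, 1.0, n)
    fs = resid(xs)
    roots = []
    for k in range(n - 1):
        if fs[k] == 0.0:
            roots.append(xs[k])
        elif fs[k] * fs[k + 1] < 0:
            roots.append(brentq(resid, xs[k], xs[k + 1], xtol=1e-14))
    out = []
    for s1 in roots:
        s6 = stat6(s1)
        out.append(np.array([nfkb(s1, s6), s1, s6]))
    return out


def oracle_count(lps, ifng=0.0, il4=0.0):
    return len(oracle_equilibria(lps, ifng, il4))


def oracle_fold(lo, hi, param="LPS", tol=1e-4):
    """Bisect an equilibrium-count change bracketed by [lo, hi]."""

    def count(v):
        args = {"LPS": (v, 0, 0), "IFNg": (0, v, 0), "IL4": (0, 0, v)}[param]
        return oracle_count(*args)

    n_lo = count(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if count(mid) == n_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
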