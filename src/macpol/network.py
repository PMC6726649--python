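"""Intracellular signaling circuit: a three-node NFkB/STAT1/STAT6 network.

The dynamics follow the transformed Wilson-Cowan form

    dx_i/dt = gamma_i * (A_i (1 - x_i) - B_i x_i) / (A_i + B_i),

with exponential activation/inhibition rates ``A_i = exp(sigma_i * u_i)`` and
``B_i = exp(sigma_i * v_i)``, where ``u_i``/``v_i`` are affine in the node
states and the external stimuli (LPS, IFNg, IL4).  Because

    (A (1 - x) - B x) / (A + B) = sigmoid(sigma (u - v)) - x,

states are confined to the open unit cube and every equilibrium solves the
fixed-point equation ``x = sigmoid(sigma (u(x) - v(x)))``.  The steep default
slope (sigma = 8) produces saddle-node bifurcations and multistability in the
stimulus ranges explored by :mod:`macpol.bifurcation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NODE_NAMES",
    "STIM_NAMES",
    "ConvergenceError",
    "StimulusInput",
    "NetworkSpec",
    "Equilibrium",
    "rhs",
    "jacobian",
    "integrate",
    "relax_batch",
    "find_equilibria",
    "default_seed_lattice",
]

logger = logging.getLogger(__name__)

NODE_NAMES = ("NFkB", "STAT1", "STAT6")
STIM_NAMES = ("LPS", "IFNg", "IL4")


class ConvergenceError(RuntimeError):
    """Raised when relaxation to a steady state does not converge."""


@dataclass(frozen=True)
class StimulusInput:
    """External stimulus levels (dimensionless, nonnegative)."""

    LPS: float = 0.0
    IFNg: float = 0.0
    IL4: float = 0.0

    def __post_init__(self) -> None:
        arr = np.array([self.LPS, self.IFNg, self.IL4], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("stimulus components must be finite")
        if np.any(arr < 0):
            raise ValueError("stimulus components must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.LPS, self.IFNg, self.IL4], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "StimulusInput":
        lps, ifng, il4 = np.asarray(arr, dtype=float)
        return cls(LPS=lps, IFNg=ifng, IL4=il4)

    def replace(self, **kwargs) -> "StimulusInput":
        return replace(self, **kwargs)


def _default_act_weights():
    # node-to-node activation: STAT1 -> NFkB, NFkB -> STAT1
    w = np.zeros((3, 3))
    w[0, 1] = 1.0
    w[1, 0] = 1.0
    return w


def _default_inh_weights():
    # node-to-node inhibition: STAT6 -| NFkB, STAT6 -| STAT1, STAT1 -| STAT6
    w = np.zeros((3, 3))
    w[0, 2] = 1.0
    w[1, 2] = 1.0
    w[2, 1] = 1.0
    return w


def _default_stim_act_weights():
    # stimulus activation: LPS -> NFkB, IFNg -> STAT1, IL4 -> STAT6
    return np.eye(3)


@dataclass
class NetworkSpec:
    """Weights, offsets and rate parameters of the signaling circuit.

    The defaults reproduce the macrophage network: activation offsets
    (-1.5, -0.5, 0), inhibition offsets (-0.1, -0.5, -0.05), unit weights on
    every interaction arc, sigma_i = 8 and gamma_i = 1.
    """

    act_weights: np.ndarray = field(default_factory=_default_act_weights)
    inh_weights: np.ndarray = field(default_factory=lambda: _default_inh_weights())
    stim_act_weights: np.ndarray = field(default_factory=_default_stim_act_weights)
    stim_inh_weights: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    act_offsets: np.ndarray = field(default_factory=lambda: np.array([-1.5, -0.5, 0.0]))
    inh_offsets: np.ndarray = field(default_factory=lambda: np.array([-0.1, -0.5, -0.05]))
    steepness: np.ndarray = field(default_factory=lambda: np.full(3, 8.0))
    rate_scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        for name in (
            "act_weights",
            "inh_weights",
            "stim_act_weights",
            "stim_inh_weights",
            "act_offsets",
            "inh_offsets",
            "steepness",
            "rate_scale",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.n_nodes
        for name in ("act_weights", "inh_weights", "stim_act_weights", "stim_inh_weights"):
            if getattr(self, name).shape != (n, n):
                raise ValueError(f"{name} must have shape ({n}, {n})")
        for name, mat in (("act_weights", self.act_weights), ("inh_weights", self.inh_weights)):
            if np.any(mat < 0) or np.any(mat > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if np.any(self.act_offsets < -1.5) or np.any(self.act_offsets > 0):
            raise ValueError("activation offsets must lie in [-1.5, 0]")
        if np.any(self.inh_offsets < -0.5) or np.any(self.inh_offsets > 0):
            raise ValueError("inhibition offsets must lie in [-0.5, 0]")
        if np.any(self.steepness <= 0):
            raise ValueError("steepness must be positive")
        if np.any(self.rate_scale <= 0):
            raise ValueError("rate_scale must be positive")

    @property
    def n_nodes(self) -> int:
        return self.act_offsets.shape[0]

    @classmethod
    def macrophage(cls) -> "NetworkSpec":
        """The default three-node macrophage circuit."""
        return cls()


@dataclass(frozen=True)
class Equilibrium:
    """A steady state with its linear-stability classification."""

    state: np.ndarray
    stable: bool
    eigenvalue_max_real: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", np.asarray(self.state, dtype=float))


def _validate_state(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("state components must be finite")
    return x


def _stim_array(stim) -> np.ndarray:
    if isinstance(stim, StimulusInput):
        return stim.as_array()
    s = np.asarray(stim, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("stimulus components must be finite")
    if np.any(s < 0):
        raise ValueError("stimulus components must be nonnegative")
    return s


def _activation_gap(x: np.ndarray, s: np.ndarray, spec: NetworkSpec) -> np.ndarray:
    """sigma_i * (u_i - v_i): log-ratio of activation to inhibition rate.

    Batched: ``x`` may be (3,) or (m, 3); ``s`` likewise.
    """
    u = spec.act_offsets + x @ spec.act_weights.T + s @ spec.stim_act_weights.T
    v = spec.inh_offsets + x @ spec.inh_weights.T + s @ spec.stim_inh_weights.T
    return spec.steepness * (u - v)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def rhs(state, stim, spec: NetworkSpec | None = None) -> np.ndarray:
    """Time derivative of the node states.

    Evaluates ``gamma_i (A_i (1 - x_i) - B_i x_i) / (A_i + B_i)`` in the
    overflow-safe sigmoid form.  Accepts a single state (shape (3,)) or a
    batch (shape (m, 3)); ``stim`` broadcasts accordingly.
    """
    spec = spec or NetworkSpec.macrophage()
    x = _validate_state(state)
    s = _stim_array(stim)
    p = _sigmoid(_activation_gap(x, s, spec))
    return spec.rate_scale * (p - x)


def jacobian(state, stim, spec: NetworkSpec | None = None) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to the state.

    ``J_ij = gamma_i (p_i (1 - p_i) sigma_i (a_ij - b_ij) - delta_ij)`` where
    ``p_i`` is the activation sigmoid.  Batched input (m, 3) returns (m, 3, 3).
    """
    spec = spec or NetworkSpec.macrophage()
    x = _validate_state(state)
    s = _stim_array(stim)
    p = _sigmoid(_activation_gap(x, s, spec))
    w = spec.act_weights - spec.inh_weights
    gain = p * (1.0 - p) * spec.steepness  # (..., 3)
    J = gain[..., :, None] * w - np.eye(3)
    return spec.rate_scale[:, None] * J


def _classify(state: np.ndarray, stim_arr: np.ndarray, spec: NetworkSpec,
              stability_eps: float = 1e-9) -> Equilibrium:
    eigs = np.linalg.eigvals(jacobian(state, stim_arr, spec))
    emax = float(eigs.real.max())
    return Equilibrium(state=state, stable=emax < -stability_eps, eigenvalue_max_real=emax)


def _newton_batch(x0, stim_arr, spec, tol=1e-12, max_iter=100):
    """Damped multi-start Newton on the equilibrium residual.

    Returns (states, converged_mask).  Seeds whose 3x3 Jacobian becomes
    numerically singular (near fold points) are marked unconverged and skipped
    by the caller.
    """
    x = np.array(x0, dtype=float)
    m = x.shape[0]
    done = np.zeros(m, dtype=bool)
    failed = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        f = rhs(x, stim_arr, spec)
        res = np.abs(f).max(axis=1)
        done |= res < tol
        active = ~(done | failed)
        if not active.any():
            break
        s_active = stim_arr[active] if np.ndim(stim_arr) == 2 else stim_arr
        J = jacobian(x[active], s_active, spec)
        # explicit 3x3 solve via adjugate; avoids LinAlgError on singular rows
        det = (
            J[:, 0, 0] * (J[:, 1, 1] * J[:, 2, 2] - J[:, 1, 2] * J[:, 2, 1])
            - J[:, 0, 1] * (J[:, 1, 0] * J[:, 2, 2] - J[:, 1, 2] * J[:, 2, 0])
            + J[:, 0, 2] * (J[:, 1, 0] * J[:, 2, 1] - J[:, 1, 1] * J[:, 2, 0])
        )
        sing = np.abs(det) < 1e-14
        adj = np.empty_like(J)
        adj[:, 0, 0] = J[:, 1, 1] * J[:, 2, 2] - J[:, 1, 2] * J[:, 2, 1]
        adj[:, 0, 1] = J[:, 0, 2] * J[:, 2, 1] - J[:, 0, 1] * J[:, 2, 2]
        adj[:, 0, 2] = J[:, 0, 1] * J[:, 1, 2] - J[:, 0, 2] * J[:, 1, 1]
        adj[:, 1, 0] = J[:, 1, 2] * J[:, 2, 0] - J[:, 1, 0] * J[:, 2, 2]
        adj[:, 1, 1] = J[:, 0, 0] * J[:, 2, 2] - J[:, 0, 2] * J[:, 2, 0]
        adj[:, 1, 2] = J[:, 0, 2] * J[:, 1, 0] - J[:, 0, 0] * J[:, 1, 2]
        adj[:, 2, 0] = J[:, 1, 0] * J[:, 2, 1] - J[:, 1, 1] * J[:, 2, 0]
        adj[:, 2, 1] = J[:, 0, 1] * J[:, 2, 0] - J[:, 0, 0] * J[:, 2, 1]
        adj[:, 2, 2] = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.einsum("mij,mj->mi", adj, f[active]) / det[:, None]
        step = np.clip(step, -0.5, 0.5)
        idx = np.flatnonzero(active)
        failed[idx[sing]] = True
        ok = idx[~sing]
        x[ok] = np.clip(x[ok] - step[~sing], -0.25, 1.25)
    f = rhs(x, stim_arr, spec)
    conv = (np.abs(f).max(axis=1) < tol) & ~failed
    if failed.any():
        logger.debug("newton: %d/%d seeds failed (singular Jacobian)", failed.sum(), m)
    return x, conv


def default_seed_lattice(points_per_axis: int = 5) -> np.ndarray:
    """Regular seed lattice covering the unit cube (default 5^3 = 125 seeds)."""
    g = np.linspace(0.0, 1.0, points_per_axis)
    return np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T


def find_equilibria(
    stim,
    spec: NetworkSpec | None = None,
    seeds: np.ndarray | None = None,
    tol: float = 1e-9,
    dedupe_tol: float = 1e-6,
    stability_eps: float = 1e-9,
) -> list[Equilibrium]:
    """All equilibria (stable and unstable) found by multi-start root finding.

    Runs a damped Newton iteration from every seed of a lattice covering
    [0, 1]^3, keeps converged roots inside the unit cube, and merges
    duplicates closer than ``dedupe_tol`` in the infinity norm.  Results are
    sorted by the STAT1 component for reproducibility.
    """
    spec = spec or NetworkSpec.macrophage()
    s = _stim_array(stim)
    if seeds is None:
        seeds = default_seed_lattice()
    roots, conv = _newton_batch(seeds, s, spec, tol=min(tol, 1e-12))
    roots = roots[conv]
    inside = np.all((roots > -1e-9) & (roots < 1 + 1e-9), axis=1)
    roots = np.clip(roots[inside], 0.0, 1.0)
    uniq: list[np.ndarray] = []
    for r in roots:
        if not any(np.abs(r - u).max() < dedupe_tol for u in uniq):
            uniq.append(r)
    uniq.sort(key=lambda r: r[1])
    out = [_classify(r, s, spec, stability_eps) for r in uniq]
    for eq in out:
        if np.abs(rhs(eq.state, s, spec)).max() >= tol:
            raise AssertionError("equilibrium residual exceeds tolerance")
    return out


def relax_batch(
    states,
    stims,
    spec: NetworkSpec | None = None,
    tol: float = 1e-9,
    chunk: float = 25.0,
    max_chunks: int = 12,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Relax a batch of states to their reachable stable equilibria.

    Integrates the (decoupled) batch as one ODE system in chunks until every
    row is near-stationary, then polishes with Newton.  The polished root is
    accepted only when it lies close to the integration endpoint, which keeps
    the result on the branch reachable from the initial state (hysteresis).
    """
    spec = spec or NetworkSpec.macrophage()
    x = np.atleast_2d(np.asarray(states, dtype=float)).copy()
    s = np.atleast_2d(np.asarray(stims, dtype=float))
    if s.shape[0] == 1 and x.shape[0] > 1:
        s = np.broadcast_to(s, x.shape)
    m = x.shape[0]
    settled = np.zeros(m, dtype=bool)
    result = np.empty_like(x)

    def fun(t, y):
        return rhs(y.reshape(m, 3), s, spec).ravel()

    t_used = 0.0
    for _ in range(max_chunks):
        sol = solve_ivp(fun, (0.0, chunk), x.ravel(), method="LSODA", rtol=rtol, atol=1e-10)
        if not sol.success:
            raise ConvergenceError(f"ODE integration failed: {sol.message}")
        x = np.clip(sol.y[:, -1].reshape(m, 3), 0.0, 1.0)
        t_used += chunk
        near = np.abs(rhs(x, s, spec)).max(axis=1) < 1e-5
        idx = np.flatnonzero(near & ~settled)
        if idx.size:
            polished, conv = _newton_batch(x[idx], np.array(s[idx]), spec, tol=min(tol, 1e-12))
            close = np.abs(polished - x[idx]).max(axis=1) < 0.05
            ok = conv & close
            result[idx[ok]] = np.clip(polished[ok], 0.0, 1.0)
            settled[idx[ok]] = True
        if settled.all():
            return result
    raise ConvergenceError(
        f"{(~settled).sum()} of {m} states did not reach a steady state within t={t_used:g}"
    )


def integrate(
    state0,
    stim,
    spec: NetworkSpec | None = None,
    horizon: float = 300.0,
    tol: float = 1e-9,
    stability_eps: float = 1e-9,
) -> Equilibrium:
    """Relax a single state to the stable equilibrium it converges to.

    Uses a stiff-capable adaptive integrator with a Newton polish; raises
    :class:`ConvergenceError` when no steady state is reached within
    ``horizon`` time units.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    spec = spec or NetworkSpec.macrophage()
    x0 = _validate_state(state0)
    s = _stim_array(stim)
    chunk = min(25.0, horizon)
    state = relax_batch(
        x0[None, :], s[None, :], spec, tol=tol, chunk=chunk,
        max_chunks=max(1, int(np.ceil(horizon / chunk))),
    )[0]
    return _classify(state, s, spec, stability_eps)
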