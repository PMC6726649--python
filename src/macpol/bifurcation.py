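"""Bifurcation sweeps, phenotype classification and reachability analysis.

One-parameter sweeps locate saddle-node (fold) points as changes in the
equilibrium count, refined by bisection.  Steady-state triplets
(NFkB, STAT1, STAT6) are discretized into Low/Medium/High activity levels;
the named profiles follow the conventional attributions

    (High, High, Low)    -> M1
    (Low,  Low,  High)   -> M2a
    (High, Medium, High) -> M2b

and the remaining profiles are reported as ``unnamed-k`` in lexicographic
order.  Multi-parameter analyses are grids of the one-parameter logic; the
reachability graph records which profile a cell relaxes into when a single
stimulus is switched, with annotations for transitions that require another
stimulus to stay low.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .network import (
    Equilibrium,
    NetworkSpec,
    StimulusInput,
    find_equilibria,
    integrate,
    relax_batch,
)

__all__ = [
    "LEVELS",
    "NAMED_PROFILES",
    "DEFAULT_THRESHOLDS",
    "Branch",
    "FoldPoint",
    "BifurcationDiagram",
    "PhenotypeProfile",
    "classify_level",
    "profile_from_state",
    "profile_at",
    "sweep_1d",
    "enumerate_phenotypes",
    "profile_occurrences",
    "default_stimulus_grid",
    "reachability_graph",
]

LEVELS = ("Low", "Medium", "High")
DEFAULT_THRESHOLDS = (0.25, 0.75)

NAMED_PROFILES = {
    ("High", "High", "Low"): "M1",
    ("Low", "Low", "High"): "M2a",
    ("High", "Medium", "High"): "M2b",
}


def classify_level(value: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Discretize a normalized concentration into Low/Medium/High."""
    if not np.isfinite(value) or value < 0 or value > 1:
        raise ValueError(f"value must lie in [0, 1], got {value!r}")
    lo, hi = thresholds
    if value < lo:
        return "Low"
    if value > hi:
        return "High"
    return "Medium"


@dataclass(frozen=True)
class PhenotypeProfile:
    """A Low/Medium/High triplet for (NFkB, STAT1, STAT6) with optional label."""

    levels: tuple[str, str, str]
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.levels) != 3 or any(l not in LEVELS for l in self.levels):
            raise ValueError(f"levels must be a triple from {LEVELS}")
        if self.label is None and self.levels in NAMED_PROFILES:
            object.__setattr__(self, "label", NAMED_PROFILES[self.levels])

    @property
    def short(self) -> str:
        return "".join(l[0] for l in self.levels)

    def __str__(self) -> str:
        s = "/".join(self.levels)
        return f"{s} ({self.label})" if self.label else s


def profile_from_state(state, thresholds=DEFAULT_THRESHOLDS) -> PhenotypeProfile:
    levels = tuple(classify_level(float(v), thresholds) for v in np.asarray(state))
    return PhenotypeProfile(levels=levels)


@dataclass
class Branch:
    """A continuation branch of a one-parameter sweep."""

    param_name: str
    samples: list[tuple[float, Equilibrium]]
    stable: bool

    def param_values(self) -> np.ndarray:
        return np.array([p for p, _ in self.samples])

    def states(self) -> np.ndarray:
        return np.array([eq.state for _, eq in self.samples])


@dataclass(frozen=True)
class FoldPoint:
    """A saddle-node point: the equilibrium count changes by +-2 across it."""

    param_name: str
    param_value: float
    state: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "state", np.asarray(self.state, dtype=float))


@dataclass
class BifurcationDiagram:
    param_name: str
    fixed_stimuli: StimulusInput
    param_values: np.ndarray
    equilibria: list[list[Equilibrium]]
    branches: list[Branch]
    folds: list[FoldPoint]

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(e.stable for e in eqs) for eqs in self.equilibria])

    def multistable_window(self) -> tuple[float, float] | None:
        """Parameter interval bounded by the outermost folds, if any."""
        if not self.folds:
            return None
        vals = sorted(f.param_value for f in self.folds)
        return vals[0], vals[-1]


def _stim_with(fixed: StimulusInput, name: str, value: float) -> StimulusInput:
    return fixed.replace(**{name: float(value)})


def _count_equilibria(name, value, fixed, spec, **kw) -> int:
    return len(find_equilibria(_stim_with(fixed, name, value), spec, **kw))


def _refine_fold(name, lo, hi, n_lo, fixed, spec, ptol, **kw):
    """Bisect on the equilibrium count until the bracket is below ``ptol``."""
    while hi - lo > ptol:
        mid = 0.5 * (lo + hi)
        if _count_equilibria(name, mid, fixed, spec, **kw) == n_lo:
            lo = mid
        else:
            hi = mid
    value = 0.5 * (lo + hi)
    # fold state: midpoint of the closest pair on the side with more equilibria
    side = lo if _count_equilibria(name, lo, fixed, spec, **kw) > _count_equilibria(
        name, hi, fixed, spec, **kw
    ) else hi
    eqs = find_equilibria(_stim_with(fixed, name, side), spec, **kw)
    states = np.array([e.state for e in eqs])
    if len(states) >= 2:
        d = np.linalg.norm(states[:, None] - states[None, :], axis=2, ord=np.inf)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        fold_state = 0.5 * (states[i] + states[j])
    else:
        fold_state = states[0]
    return FoldPoint(param_name=name, param_value=value, state=fold_state)


def _link_branches(name, values, eq_lists) -> list[Branch]:
    """Nearest-state continuation linking; a branch keeps one stability flag."""
    open_branches: list[dict] = []
    closed: list[Branch] = []
    for v, eqs in zip(values, eq_lists):
        taken: set[int] = set()
        assignment: list[tuple[dict | None, Equilibrium]] = []
        for eq in eqs:
            best, best_d = None, np.inf
            for br in open_branches:
                if id(br) in taken or br["stable"] != eq.stable:
                    continue
                d = np.abs(br["last"] - eq.state).max()
                if d < best_d:
                    best, best_d = br, d
            if best is not None and best_d < 0.2:
                taken.add(id(best))
                assignment.append((best, eq))
            else:
                assignment.append((None, eq))
        for br in open_branches:
            if id(br) not in taken:
                closed.append(Branch(name, br["samples"], br["stable"]))
        open_branches = [br for br in open_branches if id(br) in taken]
        for br, eq in assignment:
            if br is None:
                open_branches.append(
                    {"samples": [(float(v), eq)], "last": eq.state, "stable": eq.stable}
                )
            else:
                br["samples"].append((float(v), eq))
                br["last"] = eq.state
    closed.extend(Branch(name, br["samples"], br["stable"]) for br in open_branches)
    return closed


def sweep_1d(
    param_name: str,
    param_range=(0.0, 2.0),
    n_points: int = 201,
    fixed: StimulusInput | None = None,
    spec: NetworkSpec | None = None,
    fold_tol: float = 1e-3,
    **find_kw,
) -> BifurcationDiagram:
    """One-parameter bifurcation sweep with fold refinement.

    Samples ``n_points`` values of the swept stimulus, enumerates all
    equilibria at each, links them into branches by nearest-state
    continuation and refines every change in the equilibrium count to a
    :class:`FoldPoint` by bisection (parameter tolerance ``fold_tol``).
    """
    if param_name not in ("LPS", "IFNg", "IL4"):
        raise ValueError(f"unknown stimulus parameter {param_name!r}")
    lo, hi = param_range
    if not (0 <= lo < hi):
        raise ValueError("parameter range must be nonnegative with lo < hi")
    if n_points < 50:
        raise ValueError("n_points must be at least 50")
    fixed = fixed or StimulusInput()
    spec = spec or NetworkSpec.macrophage()
    values = np.linspace(lo, hi, n_points)
    eq_lists = [find_equilibria(_stim_with(fixed, param_name, v), spec, **find_kw) for v in values]
    folds = []
    for k in range(n_points - 1):
        if len(eq_lists[k]) != len(eq_lists[k + 1]):
            folds.append(
                _refine_fold(
                    param_name, values[k], values[k + 1], len(eq_lists[k]),
                    fixed, spec, fold_tol, **find_kw,
                )
            )
    branches = _link_branches(param_name, values, eq_lists)
    return BifurcationDiagram(
        param_name=param_name,
        fixed_stimuli=fixed,
        param_values=values,
        equilibria=eq_lists,
        branches=branches,
        folds=folds,
    )


def profile_at(
    stim,
    from_state=(0.0, 0.0, 0.0),
    spec: NetworkSpec | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> PhenotypeProfile:
    """Profile of the stable steady state reached from ``from_state``.

    Relaxation from the current state preserves hysteresis: inside a
    multistable window the branch the history selects is the one classified.
    """
    eq = integrate(np.asarray(from_state, dtype=float), stim, spec)
    return profile_from_state(eq.state, thresholds)


def default_stimulus_grid(hi: float = 2.0, n: int = 21) -> np.ndarray:
    """Cartesian (LPS, IFNg, IL4) grid over [0, hi]^3, shape (n^3, 3)."""
    g = np.linspace(0.0, hi, n)
    return np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T


def profile_occurrences(
    grid: np.ndarray | None = None,
    spec: NetworkSpec | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    chunk: int = 200,
    stability_eps: float = 1e-9,
) -> dict[tuple[str, str, str], list[tuple[np.ndarray, np.ndarray]]]:
    """Map each profile to the (stimulus, state) pairs where a stable
    equilibrium with that profile exists on the grid.

    Runs the multi-start Newton solver batched over (grid point, seed) pairs;
    duplicate roots at a point collapse to the same profile so no per-point
    deduplication is needed here.
    """
    from .network import _newton_batch, default_seed_lattice, jacobian

    spec = spec or NetworkSpec.macrophage()
    if grid is None:
        grid = default_stimulus_grid()
    grid = np.asarray(grid, dtype=float)
    seeds = default_seed_lattice()
    n_seeds = seeds.shape[0]
    occ: dict[tuple[str, str, str], list] = {}
    for start in range(0, grid.shape[0], chunk):
        pts = grid[start : start + chunk]
        m = pts.shape[0]
        x0 = np.tile(seeds, (m, 1))
        stims = np.repeat(pts, n_seeds, axis=0)
        roots, conv = _newton_batch(x0, stims, spec, tol=1e-12)
        inside = np.all((roots > -1e-9) & (roots < 1 + 1e-9), axis=1)
        keep = conv & inside
        if not keep.any():
            continue
        roots = np.clip(roots[keep], 0.0, 1.0)
        stims = stims[keep]
        pt_idx = np.repeat(np.arange(m), n_seeds)[keep]
        # one entry per distinct root per grid point (1e-6 dedupe)
        key = np.column_stack([pt_idx, np.round(roots / 1e-6).astype(np.int64)])
        _, uniq_idx = np.unique(key, axis=0, return_index=True)
        roots, stims = roots[uniq_idx], stims[uniq_idx]
        eigs = np.linalg.eigvals(jacobian(roots, stims, spec))
        stable = eigs.real.max(axis=1) < -stability_eps
        roots, stims = roots[stable], stims[stable]
        lo, hi = thresholds
        codes = np.where(roots < lo, 0, np.where(roots > hi, 2, 1))
        for r, s, code in zip(roots, stims, codes):
            levels = tuple(LEVELS[c] for c in code)
            occ.setdefault(levels, []).append((s, r))
    return occ


def enumerate_phenotypes(
    grid: np.ndarray | None = None,
    spec: NetworkSpec | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> list[PhenotypeProfile]:
    """Distinct profiles of all stable equilibria across a stimulus grid.

    Profiles without a conventional name are labeled ``unnamed-k`` in
    lexicographic order of their level triple.
    """
    occ = profile_occurrences(grid, spec, thresholds)
    named = sorted(l for l in occ if l in NAMED_PROFILES)
    unnamed = sorted(l for l in occ if l not in NAMED_PROFILES)
    out = [PhenotypeProfile(levels=l) for l in named]
    out += [
        PhenotypeProfile(levels=l, label=f"unnamed-{k}") for k, l in enumerate(unnamed, start=1)
    ]
    return out


def _representative(stims: list[np.ndarray], states: list[np.ndarray]):
    """Grid point of a profile's region closest to the region centroid."""
    S = np.array(stims)
    centroid = S.mean(axis=0)
    i = int(np.argmin(np.linalg.norm(S - centroid, axis=1)))
    return S[i], states[i]


def reachability_graph(
    profiles: list[PhenotypeProfile] | None = None,
    grid: np.ndarray | None = None,
    spec: NetworkSpec | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    probe_levels=(0.0, 2.0),
) -> nx.DiGraph:
    """Directed graph of stimulus-induced phenotype transitions.

    For each profile's representative (stimulus, state), each single stimulus
    is switched to each probe level and the cell relaxed from the
    representative state; a change of profile becomes an edge labeled with the
    switched cytokine.  If forcing another stimulus high alters the outcome,
    the edge carries the condition ``"<other> low"``.
    """
    spec = spec or NetworkSpec.macrophage()
    occ = profile_occurrences(grid, spec, thresholds)
    if profiles is None:
        profiles = enumerate_phenotypes(grid, spec, thresholds)
    by_levels = {p.levels: p for p in profiles}
    G = nx.DiGraph()
    for p in profiles:
        G.add_node(p.levels, label=p.label)
    names = ("LPS", "IFNg", "IL4")
    for levels, pairs in occ.items():
        if levels not in by_levels:
            continue
        stim_rep, state_rep = _representative([s for s, _ in pairs], [x for _, x in pairs])
        for ax, name in enumerate(names):
            for v in probe_levels:
                if abs(stim_rep[ax] - v) < 1e-12:
                    continue
                s_new = stim_rep.copy()
                s_new[ax] = v
                eq = integrate(state_rep, s_new, spec)
                q = profile_from_state(eq.state, thresholds).levels
                if q == levels or q not in by_levels:
                    continue
                conditions = []
                for ox, oname in enumerate(names):
                    if ox == ax:
                        continue
                    s_cond = s_new.copy()
                    s_cond[ox] = max(probe_levels)
                    if abs(s_cond[ox] - s_new[ox]) < 1e-12:
                        continue
                    eq_c = integrate(state_rep, s_cond, spec)
                    if profile_from_state(eq_c.state, thresholds).levels != q:
                        conditions.append(f"{oname} low")
                if G.has_edge(levels, q):
                    data = G.edges[levels, q]
                    if name not in data["stimuli"]:
                        data["stimuli"].append(name)
                    for c in conditions:
                        if c not in data["conditions"]:
                            data["conditions"].append(c)
                else:
                    G.add_edge(
                        levels, q, stimuli=[name], level=float(v), conditions=conditions
                    )
    return G
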