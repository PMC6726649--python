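"""Two-layer tissue simulation: macrophage agents coupled to cytokine fields.

Every sampling interval Ts each agent senses the local IL4/IFNg
concentrations (plus any scheduled ambient stimulus), relaxes its internal
signaling circuit to the stable steady state reachable from its current
state (fast intracellular kinetics, hysteresis preserved), secretes IL4 and
IFNg according to the closed-form mass-action steady state of its new state,
and takes a bounded random step.  Between decisions the secreted cytokines
diffuse over the circular tissue domain with an absorbing boundary.

The sensing gain ``kappa`` converts field concentration into the
dimensionless stimulus of the signaling circuit.  It is calibrated so that a
single maximally secreting cell produces a neighbor stimulus of order one at
the placement scale sigma after one sampling interval, which places
cell-cell signaling inside the responsive range of the bifurcation diagrams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bifurcation import (
    DEFAULT_THRESHOLDS,
    PhenotypeProfile,
    profile_from_state,
)
from .network import (
    NetworkSpec,
    StimulusInput,
    integrate,
    relax_batch,
)
from .secretion import (
    AbundanceTable,
    RateSet,
    closed_form_secretion,
    state_to_abundance,
)
from .tissue import D_DEFAULT, DiffusionParams, Field, SourceMap, rasterize_sources, step_field

__all__ = [
    "Agent",
    "SimConfig",
    "Trajectory",
    "Case2Result",
    "AmbientPulse",
    "EquilibriumCache",
    "calibrate_kappa",
    "spin_up_fields",
    "polarized_state",
    "initialize_population",
    "sense",
    "decide_and_secrete",
    "move",
    "run_simulation",
    "scenario_case2",
]


@dataclass(frozen=True)
class AmbientPulse:
    """A uniform ambient stimulus held between two times (minutes)."""

    cytokine: str  # LPS | IFNg | IL4
    amplitude: float
    start: float = 0.0
    stop: float = math.inf

    def __post_init__(self) -> None:
        if self.cytokine not in ("LPS", "IFNg", "IL4"):
            raise ValueError(f"unknown cytokine {self.cytokine!r}")
        if self.amplitude < 0:
            raise ValueError("ambient amplitude must be nonnegative")


@dataclass(frozen=True)
class Bolus:
    """An initial Gaussian cytokine deposit, in post-sensing stimulus units."""

    cytokine: str  # IFNg | IL4 (the diffusible cytokines)
    amplitude: float = 2.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.cytokine not in ("IFNg", "IL4"):
            raise ValueError("bolus cytokine must be a diffusible one (IFNg or IL4)")


@dataclass
class SimConfig:
    """Tissue-level run parameters.

    Defaults are the study conditions: 30 cells placed around the origin with
    per-axis variance 0.25, moving at most 2*sigma^2 = 0.5 units per
    interval, sampling interval Ts = 0.1 min, domain radius 4 (400 um) on an
    81x81 grid, diffusion coefficient 0.18 units^2/min.
    """

    n_agents: int = 30
    placement_var: float = 0.25
    move_max: float = 0.5
    Ts: float = 0.1
    n_steps: int = 100
    seed: int = 0
    radius: float = 4.0
    grid_n: int = 81
    D: float = D_DEFAULT
    kappa: float | tuple[float, float] | None = None
    sensing_reference: float = 2.0
    stimulus_cap: float = 4.0
    secretion_scale: float = 1.0
    deposit_mode: str = "footprint"
    source_width: float = 0.25
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
    ambient: tuple[AmbientPulse, ...] = ()
    boluses: tuple[Bolus, ...] = ()
    record_fields: bool = False
    use_cache: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be at least 1")
        if self.Ts <= 0:
            raise ValueError("Ts must be positive")
        if self.move_max < 0:
            raise ValueError("move_max must be nonnegative")
        if self.placement_var <= 0:
            raise ValueError("placement_var must be positive")

    def ambient_at(self, t: float) -> np.ndarray:
        amb = np.zeros(3)
        idx = {"LPS": 0, "IFNg": 1, "IL4": 2}
        for p in self.ambient:
            if p.start <= t < p.stop:
                amb[idx[p.cytokine]] += p.amplitude
        return amb

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class Agent:
    """A macrophage with position, internal signaling state and secretion."""

    id: int
    position: np.ndarray
    internal: np.ndarray
    profile: PhenotypeProfile
    secretion: tuple[float, float] = (0.0, 0.0)  # (IL4, IFNg) rates


def calibrate_kappa(
    cfg: SimConfig,
    rates: RateSet | None = None,
    abundances: AbundanceTable | None = None,
) -> tuple[float, float]:
    """Per-cytokine sensing gains (kappa_IFNg, kappa_IL4).

    Fields accumulate toward a diffusive quasi-steady state, so the gain is
    set at the population scale: a population of ``n_agents`` cells secreting
    a cytokine at its maximal closed-form rate Q produces a center-of-cluster
    quasi-steady concentration of about n Q G(sigma), with the 2-D Green's
    factor G = ln(R / sigma) / (2 pi D) and sigma the placement scale.  The
    gain maps that concentration to the top of the responsive stimulus range
    (``sensing_reference``).  The gains are per cytokine because the maximal
    IL4 and IFNg secretion rates differ ~30-fold.
    """
    rates = rates or RateSet()
    abundances = abundances or AbundanceTable()
    corners = np.array(
        [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=float
    )
    il4, ifng = closed_form_secretion(state_to_abundance(corners, abundances), rates)
    sigma = math.sqrt(cfg.placement_var)
    green = math.log(cfg.radius / sigma) / (2.0 * math.pi * cfg.D)
    def gain(q_max: float) -> float:
        phi = cfg.n_agents * q_max * cfg.secretion_scale * green
        return cfg.sensing_reference / phi
    return gain(float(np.max(ifng))), gain(float(np.max(il4)))


def _resolve_kappa(cfg, rates, abundances) -> tuple[float, float]:
    if cfg.kappa is None:
        return calibrate_kappa(cfg, rates, abundances)
    if np.isscalar(cfg.kappa):
        return float(cfg.kappa), float(cfg.kappa)
    k_ifng, k_il4 = cfg.kappa
    return float(k_ifng), float(k_il4)


_CANONICAL_STIMULI = {
    "M0": (0.0, 0.0, 0.0),
    "rest": (0.0, 0.0, 0.0),
    "M1": (2.0, 2.0, 0.0),
    "M1_IFNg": (0.0, 2.0, 0.0),  # IFNg-only induction (no LPS): STAT1-high state
    "M2a": (0.0, 0.0, 2.0),
    "M2": (0.0, 0.0, 2.0),
}


def polarized_state(name: str, spec: NetworkSpec | None = None) -> np.ndarray:
    """Internal state obtained by relaxing a naive cell under a canonical
    polarizing stimulus (M1: LPS+IFNg, M2a: IL4, M0: none)."""
    try:
        stim = _CANONICAL_STIMULI[name]
    except KeyError as exc:
        raise ValueError(f"unknown polarization state {name!r}") from exc
    return integrate(np.zeros(3), StimulusInput(*stim), spec).state


def initialize_population(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    spec: NetworkSpec | None = None,
    composition: list[tuple[int, object]] | None = None,
) -> list[Agent]:
    """Place agents around the origin; internal states at rest by default.

    ``composition`` is a list of (count, state) pairs where state is a name
    understood by :func:`polarized_state` or an explicit 3-vector; counts
    must sum to ``cfg.n_agents``.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    sd = math.sqrt(cfg.placement_var)
    positions = []
    while len(positions) < cfg.n_agents:
        p = rng.normal(0.0, sd, size=2)
        if p @ p < cfg.radius**2:
            positions.append(p)
    if composition is None:
        composition = [(cfg.n_agents, "rest")]
    states: list[np.ndarray] = []
    for count, state in composition:
        x = polarized_state(state, spec) if isinstance(state, str) else np.asarray(state, float)
        states.extend([x.copy() for _ in range(count)])
    if len(states) != cfg.n_agents:
        raise ValueError("composition counts must sum to n_agents")
    return [
        Agent(
            id=k,
            position=positions[k],
            internal=states[k],
            profile=profile_from_state(states[k], cfg.thresholds),
        )
        for k in range(cfg.n_agents)
    ]


def sense(
    agent: Agent,
    il4_field: Field,
    ifng_field: Field,
    ambient,
    cfg: SimConfig,
    kappa: tuple[float, float],
) -> StimulusInput:
    """Local stimulus: kappa_c * sampled field + scheduled ambient, capped."""
    from .tissue import sample_field

    k_ifng, k_il4 = kappa
    amb = np.asarray(ambient, dtype=float)
    s = np.array(
        [
            amb[0],
            k_ifng * sample_field(ifng_field, agent.position) + amb[1],
            k_il4 * sample_field(il4_field, agent.position) + amb[2],
        ]
    )
    s = np.clip(s, 0.0, cfg.stimulus_cap)
    return StimulusInput.from_array(s)


class EquilibriumCache:
    """Optional memo for fate decisions, keyed by quantized (state, stimulus).

    Quantization is fine (1e-4 by default) so cached results agree with
    direct relaxation away from basin boundaries.
    """

    def __init__(self, quantum: float = 1e-4):
        self.quantum = quantum
        self._store: dict[tuple, np.ndarray] = {}

    def key(self, state: np.ndarray, stim: np.ndarray) -> tuple:
        q = self.quantum
        return tuple(int(round(v / q)) for v in np.concatenate([state, stim]))

    def lookup(self, state, stim):
        return self._store.get(self.key(state, stim))

    def store(self, state, stim, result) -> None:
        self._store[self.key(state, stim)] = np.asarray(result, dtype=float)


def decide_and_secrete(
    agent: Agent,
    stim: StimulusInput,
    spec: NetworkSpec | None = None,
    rates: RateSet | None = None,
    abundances: AbundanceTable | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    secretion_scale: float = 1.0,
    cache: EquilibriumCache | None = None,
) -> Agent:
    """Relax the agent's circuit under ``stim`` and update its secretion."""
    s = stim.as_array()
    cached = cache.lookup(agent.internal, s) if cache is not None else None
    if cached is None:
        new_state = integrate(agent.internal, stim, spec).state
        if cache is not None:
            cache.store(agent.internal, s, new_state)
    else:
        new_state = cached
    drivers = state_to_abundance(new_state, abundances)
    il4, ifng = closed_form_secretion(drivers, rates)
    return replace(
        agent,
        internal=new_state,
        profile=profile_from_state(new_state, thresholds),
        secretion=(il4 * secretion_scale, ifng * secretion_scale),
    )


def move(agent: Agent, cfg: SimConfig, rng: np.random.Generator) -> Agent:
    """Bounded random step; draws landing outside the domain are resampled
    (up to 10 tries, otherwise the agent stays put)."""
    if cfg.move_max == 0:
        return agent
    for _ in range(10):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dist = rng.uniform(0.0, cfg.move_max)
        new = agent.position + dist * np.array([math.cos(theta), math.sin(theta)])
        if new @ new < cfg.radius**2:
            return replace(agent, position=new)
    return agent


@dataclass
class Trajectory:
    """Per-step record of a tissue simulation."""

    config: SimConfig
    agents: pd.DataFrame  # step, time, agent, x, y, NFkB, STAT1, STAT6, profile, label
    counts: pd.DataFrame  # step, time, profile, count
    fields: list[dict] | None = None
    final_agents: list[Agent] | None = None
    final_fields: dict[str, Field] | None = None

    def profile_fraction(self, short: str) -> pd.Series:
        """Fraction of agents in profile ``short`` (e.g. 'LLH') per step."""
        n = self.config.n_agents
        sub = self.counts[self.counts["profile"] == short]
        frac = sub.set_index("step")["count"] / n
        steps = sorted(self.counts["step"].unique())
        return frac.reindex(steps, fill_value=0.0)


def _record(records, counts, step, t, agents):
    from collections import Counter

    for a in agents:
        records.append(
            (
                step,
                t,
                a.id,
                a.position[0],
                a.position[1],
                a.internal[0],
                a.internal[1],
                a.internal[2],
                a.profile.short,
                a.profile.label or "",
            )
        )
    for short, c in sorted(Counter(a.profile.short for a in agents).items()):
        counts.append((step, t, short, c))


def run_simulation(
    cfg: SimConfig,
    spec: NetworkSpec | None = None,
    rates: RateSet | None = None,
    abundances: AbundanceTable | None = None,
    composition: list[tuple[int, object]] | None = None,
    init_agents: list[Agent] | None = None,
    init_fields: dict[str, Field] | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run the sense -> decide/secrete -> diffuse -> move loop of the
    two-layer model.  Fully reproducible from ``cfg.seed``."""
    spec = spec or NetworkSpec.macrophage()
    rates = rates or RateSet()
    abundances = abundances or AbundanceTable()
    rng = rng or np.random.default_rng(cfg.seed)
    kappa = _resolve_kappa(cfg, rates, abundances)

    if init_agents is not None:
        agents = [replace(a) for a in init_agents]
    else:
        agents = initialize_population(cfg, rng, spec, composition)

    if init_fields is not None:
        il4_field = init_fields["IL4"].copy()
        ifng_field = init_fields["IFNg"].copy()
    else:
        il4_field = Field.create(cfg.radius, cfg.grid_n)
        ifng_field = Field.create(cfg.radius, cfg.grid_n)
        for b in cfg.boluses:
            fld = il4_field if b.cytokine == "IL4" else ifng_field
            k_c = kappa[1] if b.cytokine == "IL4" else kappa[0]
            xx, yy = np.meshgrid(fld.coords, fld.coords, indexing="ij")
            fld.values += (
                (b.amplitude / k_c) * np.exp(-(xx**2 + yy**2) / (2.0 * b.width**2))
            )
            fld.values[~fld.mask] = 0.0

    params = DiffusionParams(D=cfg.D, dt=cfg.Ts)
    cache = EquilibriumCache() if cfg.use_cache else None
    records: list = []
    count_rows: list = []
    snapshots: list[dict] | None = [] if cfg.record_fields else None

    for step in range(cfg.n_steps):
        t = step * cfg.Ts
        ambient = cfg.ambient_at(t)
        stims = np.array(
            [sense(a, il4_field, ifng_field, ambient, cfg, kappa).as_array() for a in agents]
        )
        internals = np.array([a.internal for a in agents])
        if cache is not None:
            new_internals = np.empty_like(internals)
            misses = []
            for k, a in enumerate(agents):
                hit = cache.lookup(internals[k], stims[k])
                if hit is None:
                    misses.append(k)
                else:
                    new_internals[k] = hit
            if misses:
                relaxed = relax_batch(internals[misses], stims[misses], spec)
                for kk, k in enumerate(misses):
                    new_internals[k] = relaxed[kk]
                    cache.store(internals[k], stims[k], relaxed[kk])
        else:
            new_internals = relax_batch(internals, stims, spec)
        drivers = state_to_abundance(new_internals, abundances)
        il4_rates, ifng_rates = closed_form_secretion(drivers, rates)
        agents = [
            replace(
                a,
                internal=new_internals[k],
                profile=profile_from_state(new_internals[k], cfg.thresholds),
                secretion=(
                    float(il4_rates[k]) * cfg.secretion_scale,
                    float(ifng_rates[k]) * cfg.secretion_scale,
                ),
            )
            for k, a in enumerate(agents)
        ]
        il4_sources, ifng_sources = SourceMap(), SourceMap()
        for a in agents:
            il4_sources.add(a.position, a.secretion[0])
            ifng_sources.add(a.position, a.secretion[1])
        kw = dict(mode=cfg.deposit_mode, width=cfg.source_width)
        il4_dens = rasterize_sources(il4_sources, il4_field, **kw)
        ifng_dens = rasterize_sources(ifng_sources, ifng_field, **kw)
        il4_field = step_field(il4_field, il4_dens, params)
        ifng_field = step_field(ifng_field, ifng_dens, params)
        agents = [move(a, cfg, rng) for a in agents]
        _record(records, count_rows, step, t, agents)
        if snapshots is not None:
            snapshots.append(
                {"step": step, "IL4": il4_field.values.copy(), "IFNg": ifng_field.values.copy()}
            )

    agents_df = pd.DataFrame(
        records,
        columns=["step", "time", "agent", "x", "y", "NFkB", "STAT1", "STAT6", "profile", "label"],
    )
    counts_df = pd.DataFrame(count_rows, columns=["step", "time", "profile", "count"])
    return Trajectory(
        config=cfg,
        agents=agents_df,
        counts=counts_df,
        fields=snapshots,
        final_agents=agents,
        final_fields={"IL4": il4_field, "IFNg": ifng_field},
    )


def spin_up_fields(
    agents: list[Agent],
    cfg: SimConfig,
    rates: RateSet | None = None,
    abundances: AbundanceTable | None = None,
    steps: int = 380,
) -> dict[str, Field]:
    """Fields accumulated by a population with frozen internal states.

    Runs diffusion with the agents' current secretion rates held fixed for
    ``steps`` macro intervals (default ~2.5 field relaxation times), giving
    the deterministic quasi-steady field of the composition.
    """
    rates = rates or RateSet()
    abundances = abundances or AbundanceTable()
    il4_field = Field.create(cfg.radius, cfg.grid_n)
    ifng_field = Field.create(cfg.radius, cfg.grid_n)
    params = DiffusionParams(D=cfg.D, dt=cfg.Ts)
    internals = np.array([a.internal for a in agents])
    il4_rates, ifng_rates = closed_form_secretion(
        state_to_abundance(internals, abundances), rates
    )
    il4_sources, ifng_sources = SourceMap(), SourceMap()
    for k, a in enumerate(agents):
        il4_sources.add(a.position, float(il4_rates[k]) * cfg.secretion_scale)
        ifng_sources.add(a.position, float(ifng_rates[k]) * cfg.secretion_scale)
    kw = dict(mode=cfg.deposit_mode, width=cfg.source_width)
    il4_dens = rasterize_sources(il4_sources, il4_field, **kw)
    ifng_dens = rasterize_sources(ifng_sources, ifng_field, **kw)
    for _ in range(steps):
        il4_field = step_field(il4_field, il4_dens, params)
        ifng_field = step_field(ifng_field, ifng_dens, params)
    return {"IL4": il4_field, "IFNg": ifng_field}


@dataclass
class Case2Result:
    """Outcome of a repolarization scenario."""

    direction: str
    phase1: Trajectory | None
    phase2: Trajectory
    dominant: str  # initially dominant profile (short levels)
    target: str  # profile the opposite stimulus drives toward
    dominant_fraction: pd.Series
    target_fraction: pd.Series
    crossover_step: int | None
    flipped: bool


def scenario_case2(
    direction: str = "M1_to_M2",
    cfg: SimConfig | None = None,
    m0_count: int = 0,
    phase1_steps: int = 50,
    phase2_steps: int = 400,
    spec: NetworkSpec | None = None,
    rates: RateSet | None = None,
    abundances: AbundanceTable | None = None,
    init: str = "bolus",
    spinup_steps: int = 380,
) -> Case2Result:
    """Repolarize a dominant population with the opposite stimulus.

    With ``init='bolus'`` phase 1 polarizes a naive population with a high
    initial bolus of the inducing cytokine (IFNg for an M1-dominant start,
    IL4 for M2-dominant) and lets it accumulate its own field; with
    ``init='composition'`` the population starts pre-polarized (with
    ``m0_count`` naive cells mixed in) over the deterministic quasi-steady
    field of that composition.  Phase 2 applies the opposite sustained
    ambient stimulus (IL4, or LPS+IFNg respectively).  The crossover step is
    the first phase-2 step at which the target profile holds the majority.
    """
    if direction not in ("M1_to_M2", "M2_to_M1"):
        raise ValueError("direction must be 'M1_to_M2' or 'M2_to_M1'")
    if init not in ("bolus", "composition"):
        raise ValueError("init must be 'bolus' or 'composition'")
    cfg = cfg or SimConfig()
    spec = spec or NetworkSpec.macrophage()
    rates = rates or RateSet()
    abundances = abundances or AbundanceTable()
    rng = np.random.default_rng(cfg.seed)

    if direction == "M1_to_M2":
        bolus = Bolus(cytokine="IFNg")
        polarized = "M1_IFNg"
        opposite = (AmbientPulse("IL4", 2.0),)
        target = "LLH"  # M2a
    else:
        bolus = Bolus(cytokine="IL4")
        polarized = "M2a"
        opposite = (AmbientPulse("LPS", 2.0), AmbientPulse("IFNg", 2.0))
        target = "HHL"  # M1

    from collections import Counter

    if init == "bolus":
        cfg1 = cfg.replace(n_steps=phase1_steps, boluses=(bolus,), ambient=())
        phase1 = run_simulation(cfg1, spec, rates, abundances, rng=rng)
        agents = phase1.final_agents
        fields = phase1.final_fields
        if m0_count:
            rest = polarized_state("rest", spec)
            step_every = max(1, cfg.n_agents // m0_count)
            reset_ids = [a.id for a in agents][::step_every][:m0_count]
            agents = [
                replace(
                    a,
                    internal=rest.copy(),
                    profile=profile_from_state(rest, cfg.thresholds),
                    secretion=(0.0, 0.0),
                )
                if a.id in reset_ids
                else a
                for a in agents
            ]
    else:
        phase1 = None
        composition = [(cfg.n_agents - m0_count, polarized)]
        if m0_count:
            composition.append((m0_count, "rest"))
        agents = initialize_population(cfg, rng, spec, composition)
        il4_r, ifng_r = closed_form_secretion(
            state_to_abundance(np.array([a.internal for a in agents]), abundances), rates
        )
        agents = [
            replace(a, secretion=(float(il4_r[k]) * cfg.secretion_scale,
                                  float(ifng_r[k]) * cfg.secretion_scale))
            for k, a in enumerate(agents)
        ]
        fields = spin_up_fields(agents, cfg, rates, abundances, steps=spinup_steps)

    dominant = Counter(a.profile.short for a in agents).most_common(1)[0][0]

    cfg2 = cfg.replace(n_steps=phase2_steps, boluses=(), ambient=opposite)
    phase2 = run_simulation(
        cfg2,
        spec,
        rates,
        abundances,
        init_agents=agents,
        init_fields=fields,
        rng=rng,
    )
    dom_frac = phase2.profile_fraction(dominant)
    tgt_frac = phase2.profile_fraction(target)
    above = tgt_frac[tgt_frac > 0.5]
    crossover = int(above.index[0]) if len(above) else None
    flipped = bool(dom_frac.iloc[-1] < 0.5)
    return Case2Result(
        direction=direction,
        phase1=phase1,
        phase2=phase2,
        dominant=dominant,
        target=target,
        dominant_fraction=dom_frac,
        target_fraction=tgt_frac,
        crossover_step=crossover,
        flipped=flipped,
    )
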