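"""Agent-based tissue layer: placement, sensing, movement, the coupled loop
and the repolarization scenarios."""

import numpy as np
import pandas as pd
import pytest

from macpol import Agent, Field, SimConfig, StimulusInput, integrate, run_simulation
from macpol.abm import (
    AmbientPulse,
    EquilibriumCache,
    calibrate_kappa,
    decide_and_secrete,
    initialize_population,
    move,
    polarized_state,
    scenario_case2,
    sense,
)
from macpol.bifurcation import profile_from_state


@pytest.fixture(scope="module")
def small_cfg():
    return SimConfig(n_agents=5, grid_n=41, n_steps=5, seed=12)


class TestInitializePopulation:
    def test_placement_is_deterministic(self, small_cfg, spec):
        a = initialize_population(small_cfg, np.random.default_rng(3), spec)
        b = initialize_population(small_cfg, np.random.default_rng(3), spec)
        assert all(np.array_equal(x.position, y.position) for x, y in zip(a, b))

    def test_placement_variance_and_domain(self, spec):
        cfg = SimConfig(n_agents=10000, grid_n=41)
        agents = initialize_population(cfg, np.random.default_rng(0), spec)
        pos = np.array([a.position for a in agents])
        assert np.all(np.sum(pos**2, axis=1) < cfg.radius**2)
        var = pos.var(axis=0)
        assert np.all(np.abs(var - 0.25) < 0.05 * 0.25)

    def test_composition_sets_internal_states(self, small_cfg, spec):
        agents = initialize_population(
            small_cfg, np.random.default_rng(0), spec, [(3, "M2a"), (2, "rest")]
        )
        labels = [a.profile.label for a in agents]
        assert labels[:3] == ["M2a"] * 3 and labels[3:] == [None, None]
        with pytest.raises(ValueError):
            initialize_population(small_cfg, np.random.default_rng(0), spec, [(1, "rest")])


class TestSense:
    def test_zero_everything_is_zero(self, small_cfg):
        f = Field.create(4.0, 41)
        agent = Agent(0, np.zeros(2), np.zeros(3), profile_from_state(np.zeros(3)))
        s = sense(agent, f, f, np.zeros(3), small_cfg, (1.0, 1.0))
        assert s.as_array() == pytest.approx([0, 0, 0])

    def test_ambient_passes_through(self, small_cfg):
        f = Field.create(4.0, 41)
        agent = Agent(0, np.zeros(2), np.zeros(3), profile_from_state(np.zeros(3)))
        s = sense(agent, f, f, np.array([0, 0, 2.0]), small_cfg, (1.0, 1.0))
        assert s.IL4 == 2.0 and s.LPS == 0.0

    def test_gain_scales_field_contribution_linearly(self, small_cfg):
        il4 = Field.create(4.0, 41)
        ifng = Field.create(4.0, 41)
        il4.values[il4.mask] = 0.5
        agent = Agent(0, np.zeros(2), np.zeros(3), profile_from_state(np.zeros(3)))
        s1 = sense(agent, il4, ifng, np.zeros(3), small_cfg, (1.0, 1.0))
        s2 = sense(agent, il4, ifng, np.zeros(3), small_cfg, (2.0, 2.0))
        assert s2.IL4 == pytest.approx(2 * s1.IL4)

    def test_cap_applies(self, small_cfg):
        il4 = Field.create(4.0, 41)
        ifng = Field.create(4.0, 41)
        il4.values[il4.mask] = 100.0
        agent = Agent(0, np.zeros(2), np.zeros(3), profile_from_state(np.zeros(3)))
        s = sense(agent, il4, ifng, np.zeros(3), small_cfg, (1.0, 1.0))
        assert s.IL4 == small_cfg.stimulus_cap


class TestMove:
    def test_zero_move_max_is_identity(self, spec):
        cfg = SimConfig(move_max=0.0)
        agent = Agent(0, np.array([1.0, 1.0]), np.zeros(3), profile_from_state(np.zeros(3)))
        assert np.array_equal(move(agent, cfg, np.random.default_rng(0)).position, [1.0, 1.0])

    def test_displacements_bounded_and_inside_domain(self):
        cfg = SimConfig()
        rng = np.random.default_rng(1)
        agent = Agent(0, np.array([3.7, 0.0]), np.zeros(3), profile_from_state(np.zeros(3)))
        for _ in range(10000):
            new = move(agent, cfg, rng)
            d = np.linalg.norm(new.position - agent.position)
            assert d <= cfg.move_max + 1e-12  # max distance 2*sigma^2 = 0.5
            assert new.position @ new.position < cfg.radius**2
            agent = new


class TestDecideAndSecrete:
    def test_rest_under_il4_becomes_m2a_and_secretes_il4_only(self, spec, rates, abundances):
        agent = Agent(0, np.zeros(2), np.zeros(3), profile_from_state(np.zeros(3)))
        out = decide_and_secrete(agent, StimulusInput(IL4=2.0), spec, rates, abundances)
        assert out.profile.label == "M2a"
        assert out.secretion[0] > 0 and out.secretion[1] == 0.0

    def test_mixed_state_secretes_both_cytokines(self, spec, rates, abundances):
        agent = Agent(0, np.zeros(2), np.array([0.0, 1.0, 1.0]), profile_from_state([0, 1, 1]))
        out = decide_and_secrete(agent, StimulusInput(IFNg=2.0, IL4=2.0), spec, rates, abundances)
        assert out.secretion[0] > 0 and out.secretion[1] > 0

    def test_m2a_persists_under_sustained_il4(self, spec, rates, abundances):
        agent = Agent(0, np.zeros(2), polarized_state("M2a", spec), None)
        out = decide_and_secrete(agent, StimulusInput(IL4=2.0), spec, rates, abundances)
        assert out.profile.label == "M2a"

    def test_cache_agrees_with_direct_relaxation(self, spec, rates, abundances):
        """The quantized lookup cache returns the same fate as relaxation on
        100 random (state, stimulus) pairs, including on cache hits at nearby
        quantized inputs."""
        rng = np.random.default_rng(9)
        cache = EquilibriumCache()
        for _ in range(100):
            x = rng.random(3)
            s = StimulusInput.from_array(rng.random(3) * 2)
            agent = Agent(0, np.zeros(2), x, profile_from_state(x))
            direct = decide_and_secrete(agent, s, spec, rates, abundances)
            cached = decide_and_secrete(agent, s, spec, rates, abundances, cache=cache)
            assert np.abs(direct.internal - cached.internal).max() < 1e-9
            # perturb below the quantum: the cached entry must still apply
            x2 = np.clip(x + rng.uniform(-4e-5, 4e-5, 3), 0, 1)
            agent2 = Agent(0, np.zeros(2), x2, profile_from_state(x2))
            hit = decide_and_secrete(agent2, s, spec, rates, abundances, cache=cache)
            fresh = decide_and_secrete(agent2, s, spec, rates, abundances)
            assert np.abs(hit.internal - fresh.internal).max() < 1e-6


class TestRunSimulation:
    def test_identical_seed_gives_identical_trajectory(self):
        cfg = SimConfig(n_agents=8, grid_n=41, n_steps=8, seed=5)
        t1 = run_simulation(cfg)
        t2 = run_simulation(cfg)
        pd.testing.assert_frame_equal(t1.agents, t2.agents)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)

    def test_phenotype_counts_conserve_agent_number(self):
        cfg = SimConfig(n_agents=12, grid_n=41, n_steps=10, seed=2)
        traj = run_simulation(cfg)
        sums = traj.counts.groupby("step")["count"].sum()
        assert (sums == 12).all()

    def test_no_spontaneous_switching_with_zero_fields(self, spec):
        """With secretion decoupled (fields stay zero) and no ambient
        stimulus, no agent ever changes profile."""
        cfg = SimConfig(
            n_agents=10, grid_n=41, n_steps=20, seed=4, secretion_scale=0.0, kappa=(1.0, 1.0)
        )
        traj = run_simulation(cfg, spec)
        per_agent = traj.agents.groupby("agent")["profile"].nunique()
        assert (per_agent == 1).all()
        assert (traj.agents["profile"] == "LLM").all()

    def test_zero_secretion_keeps_fields_zero(self):
        cfg = SimConfig(
            n_agents=4, grid_n=41, n_steps=5, seed=4, secretion_scale=0.0, kappa=(1.0, 1.0)
        )
        traj = run_simulation(cfg)
        assert traj.final_fields["IL4"].values.max() == 0.0
        assert traj.final_fields["IFNg"].values.max() == 0.0

    def test_single_m1_agent_builds_centered_ifng_field(self, spec, rates, abundances):
        """A lone M1 cell (held by sustaining LPS/IFNg ambient) sources a
        centered, radially decaying IFNg bump and no IL4."""
        cfg = SimConfig(
            n_agents=1,
            grid_n=41,
            n_steps=12,
            seed=0,
            move_max=0.0,
            kappa=(1e-4, 1e-4),
            ambient=(AmbientPulse("LPS", 2.0), AmbientPulse("IFNg", 2.0)),
        )
        m1 = polarized_state("M1", spec)
        agents = [Agent(0, np.zeros(2), m1, profile_from_state(m1))]
        traj = run_simulation(cfg, spec, rates, abundances, init_agents=agents)
        ifng = traj.final_fields["IFNg"]
        from macpol import sample_field

        center = sample_field(ifng, [0.0, 0.0])
        assert center > 0
        assert center > sample_field(ifng, [1.0, 0.0]) > sample_field(ifng, [2.0, 0.0])
        assert traj.final_fields["IL4"].values.max() == 0.0


class TestCase2:
    def test_m2_population_repolarizes_toward_m1(self):
        cfg = SimConfig(grid_n=41, seed=0)
        res = scenario_case2(
            "M2_to_M1", cfg, phase2_steps=120, init="composition", spinup_steps=200
        )
        assert res.dominant == "LLH"
        assert res.flipped
        # the shift is gradual: the target majority emerges over several steps
        assert res.crossover_step is not None and res.crossover_step >= 5
        assert res.target_fraction.iloc[0] < 0.5

    def test_grid_refinement_leaves_trajectory_nearly_unchanged(self):
        """Halving the grid spacing changes the target-phenotype fraction by
        at most 5% at each sampled time (grid convergence)."""
        results = {}
        for n in (41, 81):
            cfg = SimConfig(grid_n=n, seed=1)
            results[n] = scenario_case2(
                "M2_to_M1", cfg, phase2_steps=100, init="composition", spinup_steps=200
            )
        f41 = results[41].target_fraction.to_numpy()
        f81 = results[81].target_fraction.to_numpy()
        assert np.abs(f41[::10] - f81[::10]).max() <= 0.05 + 1e-9
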