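"""Sweeps, fold detection, phenotype classification and reachability."""

import numpy as np
import pytest

from macpol import (
    NetworkSpec,
    StimulusInput,
    classify_level,
    enumerate_phenotypes,
    profile_at,
    reachability_graph,
    sweep_1d,
)
from macpol.bifurcation import (
    NAMED_PROFILES,
    PhenotypeProfile,
    default_stimulus_grid,
    profile_from_state,
)

from conftest import oracle_count, oracle_fold


@pytest.fixture(scope="module")
def lps_diagram(spec):
    return sweep_1d("LPS", (0.0, 2.0), 201, StimulusInput(), spec)


@pytest.fixture(scope="module")
def profiles_11(spec):
    return enumerate_phenotypes(default_stimulus_grid(2.0, 11), spec)


@pytest.fixture(scope="module")
def graph(spec):
    grid = default_stimulus_grid(2.0, 11)
    profiles = enumerate_phenotypes(grid, spec)
    return reachability_graph(profiles, grid, spec), profiles


class TestClassifyLevel:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, "Low"), (0.2499, "Low"), (0.5, "Medium"), (0.7501, "High"), (1.0, "High")],
    )
    def test_thresholds(self, value, expected):
        assert classify_level(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_level(-0.1)
        with pytest.raises(ValueError):
            classify_level(1.1)

    def test_custom_thresholds(self):
        assert classify_level(0.5, thresholds=(0.45, 0.55)) == "Medium"
        assert classify_level(0.5, thresholds=(0.6, 0.8)) == "Low"


class TestLpsSweep:
    def test_switching_window_matches_reported_critical_values(self, lps_diagram):
        """The multistable LPS window is bounded by folds at ~0.37 and ~1.64."""
        window = lps_diagram.multistable_window()
        assert window is not None
        assert window[0] == pytest.approx(0.37, abs=0.02)
        assert window[1] == pytest.approx(1.64, abs=0.02)

    def test_up_to_three_stable_and_two_unstable_states(self, lps_diagram):
        """Counts reach 3 stable + 2 unstable inside the window."""
        totals = np.array([len(e) for e in lps_diagram.equilibria])
        stables = lps_diagram.stable_counts()
        assert totals.max() == 5
        assert stables.max() == 3
        assert (totals - stables).max() == 2

    def test_stable_count_constant_between_consecutive_folds(self, lps_diagram):
        fold_vals = sorted(f.param_value for f in lps_diagram.folds)
        edges = [-np.inf] + fold_vals + [np.inf]
        stables = lps_diagram.stable_counts()
        for lo, hi in zip(edges[:-1], edges[1:]):
            inside = (lps_diagram.param_values > lo + 1e-6) & (
                lps_diagram.param_values < hi - 1e-6
            )
            if inside.any():
                assert len(set(stables[inside])) == 1

    def test_folds_invariant_under_resolution_and_direction(self, spec, lps_diagram):
        ref = sorted(f.param_value for f in lps_diagram.folds)
        finer = sweep_1d("LPS", (0.0, 2.0), 401, StimulusInput(), spec)
        vals = sorted(f.param_value for f in finer.folds)
        assert len(vals) == len(ref)
        assert np.abs(np.array(vals) - np.array(ref)).max() < 1e-3
        # detection from per-point equilibrium counts is direction-free by
        # construction; an offset subsampled sweep must agree as well
        shifted = sweep_1d("LPS", (0.01, 1.99), 100, StimulusInput(), spec)
        svals = sorted(f.param_value for f in shifted.folds)
        assert np.abs(np.array(svals) - np.array(ref)).max() < 2e-3

    def test_folds_match_brute_force_oracle(self, lps_diagram):
        """Fold parameters agree with count-bisection on the independent
        scalar-reduction oracle."""
        brackets = [(0.3, 0.4), (0.4, 0.46), (0.46, 0.52), (1.6, 1.7)]
        oracle = [oracle_fold(lo, hi, "LPS") for lo, hi in brackets]
        found = sorted(f.param_value for f in lps_diagram.folds)
        assert len(found) == len(oracle)
        assert np.abs(np.array(found) - np.array(oracle)).max() < 1.5e-3

    def test_fold_states_lie_on_colliding_branches(self, lps_diagram):
        for f in lps_diagram.folds:
            assert np.all(f.state >= 0) and np.all(f.state <= 1)


class TestOtherSweeps:
    def test_il4_sweep_has_no_folds(self, spec):
        d = sweep_1d("IL4", (0.0, 2.0), 101, StimulusInput(), spec)
        assert len(d.folds) == 0
        assert set(d.stable_counts()) == {1}

    def test_ifng_sweep_has_folds_moving_stat1_and_stat6(self, spec):
        d = sweep_1d("IFNg", (0.0, 2.0), 101, StimulusInput(), spec)
        assert len(d.folds) >= 1
        assert oracle_count(0, 0.05, 0) > 1  # oracle agrees the window exists
        # the coexisting stable states differ in STAT1 and STAT6
        spreads = []
        for eqs in d.equilibria:
            stable_states = [e.state for e in eqs if e.stable]
            if len(stable_states) > 1:
                spreads.append(np.ptp(np.array(stable_states), axis=0))
        spread = np.max(spreads, axis=0)
        assert spread[1] > 0.5 and spread[2] > 0.3

    def test_invalid_sweep_arguments(self, spec):
        with pytest.raises(ValueError):
            sweep_1d("TNF", (0, 2), 101, StimulusInput(), spec)
        with pytest.raises(ValueError):
            sweep_1d("LPS", (2.0, 0.0), 101, StimulusInput(), spec)
        with pytest.raises(ValueError):
            sweep_1d("LPS", (0.0, 2.0), 10, StimulusInput(), spec)


class TestHysteresis:
    def test_branch_selection_depends_on_history(self, spec):
        """Inside the bistable LPS window the profile depends on whether the
        cell arrived from low or high LPS (the switch-like memory)."""
        from macpol import integrate

        up = profile_at((1.0, 0.0, 0.0), from_state=(0, 0, 0), spec=spec)
        high_state = integrate(np.zeros(3), StimulusInput(LPS=2.0), spec).state
        down = profile_at((1.0, 0.0, 0.0), from_state=high_state, spec=spec)
        assert up.levels != down.levels
        assert down.levels == ("High", "High", "Low")


class TestProfiles:
    def test_named_profile_attributions(self, spec):
        assert profile_at((0.0, 0.0, 2.0), spec=spec).label == "M2a"
        assert profile_at((2.0, 2.0, 0.0), spec=spec).label == "M1"
        assert profile_at((2.5, 0.0, 2.0), spec=spec).label == "M2b"

    def test_resting_profile_is_unlabeled_and_idempotent(self, spec):
        p1 = profile_at((0.0, 0.0, 0.0), spec=spec)
        p2 = profile_at((0.0, 0.0, 0.0), spec=spec)
        assert p1 == p2
        assert p1.label is None
        assert p1.levels == ("Low", "Low", "Medium")

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            PhenotypeProfile(levels=("Low", "Low", "Extreme"))
        p = profile_from_state([0.9, 0.9, 0.1])
        assert p.label == "M1"


class TestEnumeration:
    def test_contains_named_polarization_profiles(self, profiles_11):
        labels = {p.label for p in profiles_11}
        assert {"M1", "M2a"} <= labels

    def test_within_combinatorial_bound(self, profiles_11):
        assert len(profiles_11) <= 27

    def test_unnamed_profiles_get_systematic_names(self, profiles_11):
        unnamed = [p for p in profiles_11 if p.label and p.label.startswith("unnamed-")]
        ks = sorted(int(p.label.split("-")[1]) for p in unnamed)
        assert ks == list(range(1, len(unnamed) + 1))
        # lexicographic ordering of the level triples
        triples = [p.levels for p in sorted(unnamed, key=lambda p: int(p.label.split("-")[1]))]
        assert triples == sorted(triples)

    def test_m2b_requires_stronger_lps(self, spec):
        """(High, Medium, High) needs LPS beyond ~2.4 to overcome the
        STAT6-mediated inhibition of NFkB."""
        wide = enumerate_phenotypes(default_stimulus_grid(4.0, 11), spec)
        assert "M2b" in {p.label for p in wide}


class TestReachability:
    def test_nodes_match_enumerated_profiles(self, graph):
        G, profiles = graph
        assert G.number_of_nodes() == len(profiles)

    def test_il4_switch_conditional_on_low_ifng(self, graph):
        """An IL4-labeled transition exists that requires IFNg to stay low."""
        G, _ = graph
        assert any(
            "IL4" in d["stimuli"] and "IFNg low" in d["conditions"]
            for _, _, d in G.edges(data=True)
        )

    def test_ifng_switch_conditional_on_low_lps(self, graph):
        G, _ = graph
        assert any(
            "IFNg" in d["stimuli"] and "LPS low" in d["conditions"]
            for _, _, d in G.edges(data=True)
        )

    def test_edges_are_real_transitions(self, graph):
        G, _ = graph
        for u, v in G.edges:
            assert u != v
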