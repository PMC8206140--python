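"""Microscopic processes, MC stepping, determinism and conservation laws."""

import math

import numpy as np
import pytest
import scipy.stats

from mayleonard import (SPECIES_LABELS, Action, attempt_predation,
                        attempt_reproduction, default_params, desk_params,
                        elementary_step, init_population,
                        make_planted_configuration, mc_step, move,
                        prey_species, run, validate)
from mayleonard.spatial import build_grid, torus_distance


class CountingRNG:
    """Duck-typed Generator proxy that counts actor selections."""

    def __init__(self, rng):
        self._rng = rng
        self.actor_draws = 0

    def integers(self, *a, **kw):
        self.actor_draws += 1
        return self._rng.integers(*a, **kw)

    def random(self, *a, **kw):
        return self._rng.random(*a, **kw)


def _micro_params(**over):
    base = dict(box_length=1.0, pred_radius=0.02, repro_radius=0.02,
                move_length=0.01, offspring_radius=0.01, capacity=10,
                init_per_species=10, relax_steps=0, measure_steps=10, seed=0)
    base.update(over)
    return validate(default_params().replace(**base))


# ---------------------------------------------------------------------------
# cyclic dominance
# ---------------------------------------------------------------------------

def test_prey_cycle():
    assert prey_species("A") == "B"
    assert prey_species("B") == "C"
    assert prey_species("C") == "A"
    for s in SPECIES_LABELS:
        assert prey_species(prey_species(prey_species(s))) == s
    with pytest.raises(ValueError):
        prey_species("D")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def test_init_population_counts_and_determinism(rng):
    p = _micro_params(init_per_species=100)
    state = init_population(p, np.random.default_rng(3))
    assert state.n == 300
    assert state.counts.tolist() == [100, 100, 100]
    assert np.array_equal(state.counts, state.tally())
    state2 = init_population(p, np.random.default_rng(3))
    assert np.array_equal(state.x[:300], state2.x[:300])
    assert np.array_equal(state.sp[:300], state2.sp[:300])

    solo = init_population(_micro_params(init_per_species=1),
                           np.random.default_rng(0))
    assert solo.n == 3 and solo.counts.tolist() == [1, 1, 1]


# ---------------------------------------------------------------------------
# predation
# ---------------------------------------------------------------------------

def test_predation_kills_prey_in_range():
    state = make_planted_configuration([("A", 0.5, 0.5), ("B", 0.51, 0.5)])
    assert attempt_predation(state, 0, _micro_params())
    assert state.n == 1
    assert state.counts.tolist() == [1, 0, 0]


def test_predation_out_of_range_does_nothing():
    state = make_planted_configuration([("A", 0.5, 0.5), ("B", 0.55, 0.5)])
    assert not attempt_predation(state, 0, _micro_params())
    assert state.n == 2


def test_predation_takes_the_closest_prey():
    state = make_planted_configuration(
        [("A", 0.5, 0.5), ("B", 0.512, 0.5), ("B", 0.518, 0.5)])
    assert attempt_predation(state, 0, _micro_params())
    assert state.n == 2
    # the survivor is the farther prey, now at torus distance 0.018
    survivors = [torus_distance(state.x[i], state.y[i], 0.5, 0.5, 1.0)
                 for i in range(state.n) if state.sp[i] == 1]
    assert survivors == [pytest.approx(0.018)]


def test_predation_respects_the_cycle_not_just_any_species():
    # C sits within range of A, but A's prey is B: nothing happens
    state = make_planted_configuration([("A", 0.5, 0.5), ("C", 0.51, 0.5)])
    assert not attempt_predation(state, 0, _micro_params())
    assert state.n == 2


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

def test_reproduction_lone_parent_succeeds(rng):
    state = make_planted_configuration([("A", 0.5, 0.5)])
    assert attempt_reproduction(state, 0, _micro_params(capacity=2), rng)
    assert state.n == 2
    assert state.counts.tolist() == [2, 0, 0]
    d = torus_distance(state.x[1], state.y[1], 0.5, 0.5, 1.0)
    assert d <= _micro_params().offspring_radius + 1e-12


def test_reproduction_blocked_at_capacity(rng):
    # actor plus M-1 others inside the range: count == M, strictly-below fails
    M = 5
    others = [("B", 0.5 + 0.002 * (k + 1), 0.5) for k in range(M - 1)]
    state = make_planted_configuration([("A", 0.5, 0.5)] + others)
    assert not attempt_reproduction(state, 0, _micro_params(capacity=M), rng)
    assert state.n == M


def test_capacity_one_forbids_all_reproduction(rng):
    # the actor counts itself, so M=1 can never admit a birth
    state = make_planted_configuration([("A", 0.5, 0.5)])
    assert not attempt_reproduction(state, 0, _micro_params(capacity=1), rng)
    assert state.n == 1


def test_offspring_lands_in_the_disk_and_same_species(rng):
    p = _micro_params(capacity=1000, offspring_radius=0.03)
    state = make_planted_configuration([("C", 0.2, 0.9)])
    for _ in range(200):
        attempt_reproduction(state, 0, p, rng)
    assert state.counts.tolist() == [0, 0, 201]
    for i in range(1, state.n):
        assert torus_distance(state.x[i], state.y[i], 0.2, 0.9, 1.0) <= 0.03 + 1e-12


# ---------------------------------------------------------------------------
# movement
# ---------------------------------------------------------------------------

def test_move_has_exact_length_and_wraps(rng):
    p = _micro_params(move_length=0.01)
    state = make_planted_configuration([("A", 0.005, 0.5)])
    for _ in range(50):
        ox, oy = state.x[0], state.y[0]
        move(state, 0, p, rng)
        assert torus_distance(state.x[0], state.y[0], ox, oy, 1.0) == pytest.approx(
            0.01, abs=1e-12)
        assert 0 <= state.x[0] < 1 and 0 <= state.y[0] < 1


def test_move_angles_are_uniform(rng):
    p = _micro_params(move_length=0.01)
    state = make_planted_configuration([("A", 0.5, 0.5)])
    angles = []
    for _ in range(10_000):
        ox, oy = state.x[0], state.y[0]
        move(state, 0, p, rng)
        dx = state.x[0] - ox
        dy = state.y[0] - oy
        dx -= round(dx)
        dy -= round(dy)
        angles.append(math.atan2(dy, dx) % (2 * math.pi))
    counts, _ = np.histogram(angles, bins=36, range=(0, 2 * math.pi))
    assert scipy.stats.chisquare(counts).pvalue > 0.001


# ---------------------------------------------------------------------------
# elementary and full MC steps
# ---------------------------------------------------------------------------

def test_forced_predation_decrements_n(rng):
    # a tight cyclic triple: every possible actor has its prey in range
    p = _micro_params(prob_move=0.0, prob_predate=1.0, prob_reproduce=0.0)
    state = make_planted_configuration(
        [("A", 0.5, 0.5), ("B", 0.51, 0.5), ("C", 0.505, 0.508)])
    action = elementary_step(state, p, rng)
    assert action is Action.PREDATE
    assert state.n == 2


def test_movement_only_conserves_population(rng):
    p = _micro_params(prob_move=1.0, prob_predate=0.0, prob_reproduce=0.0,
                      init_per_species=40)
    state = init_population(p, rng)
    for _ in range(200):
        elementary_step(state, p, rng)
    assert state.n == 120
    assert state.counts.tolist() == [40, 40, 40]


def test_action_frequencies_match_probabilities(rng):
    p = _micro_params(init_per_species=100, box_length=0.25, capacity=10)
    state = init_population(p, rng)
    n_steps = 100_000
    tallies = {Action.MOVE: 0, Action.PREDATE: 0, Action.REPRODUCE: 0}
    for _ in range(n_steps):
        tallies[elementary_step(state, p, rng)] += 1
    for action, prob in [(Action.MOVE, 0.5), (Action.PREDATE, 0.25),
                         (Action.REPRODUCE, 0.25)]:
        sigma = math.sqrt(prob * (1 - prob) / n_steps)
        assert abs(tallies[action] / n_steps - prob) < 3 * sigma


def test_population_change_per_elementary_step_is_bounded(rng):
    p = _micro_params(init_per_species=60, box_length=0.25, capacity=8)
    state = init_population(p, rng)
    for _ in range(2000):
        before = state.n
        elementary_step(state, p, rng)
        assert state.n - before in (-1, 0, 1)
        assert np.array_equal(state.counts, state.tally())


def test_mc_step_runs_n0_elementary_steps(rng):
    p = _micro_params(prob_move=1.0, prob_predate=0.0, prob_reproduce=0.0)
    state = make_planted_configuration(
        [("A", x, y) for x, y in np.random.default_rng(0).random((100, 2))])
    counting = CountingRNG(rng)
    mc_step(state, p, counting)
    assert counting.actor_draws == 100


def test_mc_step_on_empty_population_is_a_no_op(rng):
    state = make_planted_configuration([])
    mc_step(state, _micro_params(), rng)
    assert state.n == 0


def test_grid_membership_consistent_after_stepping(rng):
    p = _micro_params(init_per_species=50, box_length=0.25, capacity=8)
    state = init_population(p, rng)
    for _ in range(20):
        mc_step(state, p, rng)
    pos = {i: (state.x[i], state.y[i]) for i in range(state.n)}
    fresh = build_grid(pos, max(p.pred_radius, p.repro_radius), p.box_length)
    assert state.grid.members() == fresh.members()
    for i in pos:
        assert state.grid.cell_of(i) == fresh.cell_of(i)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def test_run_length_and_determinism(tiny_params):
    s1 = run(tiny_params)
    s2 = run(tiny_params)
    assert len(s1) == tiny_params.measure_steps
    assert np.array_equal(s1.n_a, s2.n_a)
    assert np.array_equal(s1.n_total, s2.n_total)
    assert np.array_equal(s1.n_total, s1.n_a + s1.n_b + s1.n_c)


def test_backends_produce_identical_trajectories(tiny_params):
    s_cell = run(tiny_params, backend="cell")
    s_brute = run(tiny_params, backend="brute")
    s_ref = run(tiny_params, backend="reference")
    for other in (s_brute, s_ref):
        assert np.array_equal(s_cell.n_a, other.n_a)
        assert np.array_equal(s_cell.n_b, other.n_b)
        assert np.array_equal(s_cell.n_c, other.n_c)
        assert s_cell.extinction_step == other.extinction_step


def test_movement_only_run_conserves_n_exactly(tiny_params):
    p = tiny_params.replace(prob_move=1.0, prob_predate=0.0, prob_reproduce=0.0)
    s = run(p)
    assert set(np.unique(s.n_total)) == {3 * p.init_per_species}


def test_no_reproduction_means_non_increasing_population(tiny_params):
    p = tiny_params.replace(prob_move=0.5, prob_predate=0.5, prob_reproduce=0.0,
                            measure_steps=100)
    s = run(p)
    assert np.all(np.diff(s.n_total) <= 0)


def test_no_predation_means_non_decreasing_population(tiny_params):
    p = tiny_params.replace(prob_move=0.5, prob_predate=0.0, prob_reproduce=0.5,
                            measure_steps=100)
    s = run(p)
    assert np.all(np.diff(s.n_total) >= 0)


def test_well_mixed_movement_breaks_symmetry():
    p = desk_params(0.25, capacity=5, init_per_species=100, move_length=0.8,
                    relax_steps=0, measure_steps=500, seed=11)
    s = run(p)
    assert s.symmetry_broken
    first = min(v for v in s.extinction_step.values() if v is not None)
    assert 1 <= first <= 500
    # counts stay zero from the extinction step on
    label = [k for k, v in s.extinction_step.items() if v == first][0]
    assert np.all(s.counts_of(label)[first - 1:] == 0)


def test_species_symmetry_in_ensemble_means():
    # exchangeability of the three labels: across an ensemble of seeds no
    # species develops a systematic advantage.  The window starts late:
    # launching every run from exactly equal counts synchronises the
    # composition oscillation across seeds, so early windows show a
    # coherent (but transient) common phase; by ~15 oscillation periods
    # the phases have decohered.
    means = []
    for seed in range(16):
        p = desk_params(0.25, capacity=30, init_per_species=625,
                        relax_steps=1500, measure_steps=750, seed=seed)
        s = run(p)
        means.append([s.n_a.mean(), s.n_b.mean(), s.n_c.mean()])
    means = np.array(means)
    grand = means.mean()
    for col in range(3):
        se = means[:, col].std(ddof=1) / math.sqrt(len(means))
        assert abs(means[:, col].mean() - grand) < 3 * se
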