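"""Agent dynamics: movement, stops, pauses, transfers, jams, reproducibility."""

import math

import numpy as np
import pytest
from scipy import stats

from termite_transport import (
    AgentState,
    BehaviorParams,
    build_tunnel,
    curvature_stop_draw,
    deposit_value,
    draw_pause,
    init_world,
    jam_phase,
    place_irregularities,
    step,
    transfer_phase,
)
from termite_transport import dynamics

from conftest import make_world


# --------------------------------------------------------------------------
# initialization


def test_init_world_contract(default_tunnel, rng):
    layout = place_irregularities(default_tunnel, 6, 4, rng)
    w = init_world(BehaviorParams(), default_tunnel, layout, rng)
    assert w.n_agents == 100
    assert np.all(w.cargo == -1)
    assert np.all((w.pos >= 1) & (w.pos <= 999))
    assert set(np.unique(w.dirn)) <= {-1, 1}
    assert np.all(w.state == AgentState.MOVING)
    assert w.clock == 0


def test_init_world_deterministic_and_scalable(small_tunnel):
    layout = place_irregularities(small_tunnel, 1, 2, np.random.default_rng(3))
    w1 = init_world(BehaviorParams(), small_tunnel, layout, np.random.default_rng(9), n_agents=10)
    w2 = init_world(BehaviorParams(), small_tunnel, layout, np.random.default_rng(9), n_agents=10)
    assert w1.n_agents == 10
    assert np.array_equal(w1.pos, w2.pos) and np.array_equal(w1.dirn, w2.dirn)


# --------------------------------------------------------------------------
# stochastic primitives


def test_curvature_stop_probability_levels(rng):
    assert not any(
        curvature_stop_draw(BehaviorParams(k1=1), rng) for _ in range(10_000)
    )
    n = 100_000
    hits = sum(curvature_stop_draw(BehaviorParams(k1=6), rng) for _ in range(n))
    p = (6 - 1) * 0.05
    sigma = math.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 3 * sigma
    assert BehaviorParams(k1=11).stop_prob == pytest.approx(0.5)


def test_pause_degenerate_and_mean(rng):
    assert all(draw_pause(BehaviorParams(k2=1), rng) == 0 for _ in range(100))
    n = 20_000
    lam = BehaviorParams(k2=4).lam
    assert lam == 15.0
    mean = np.mean([draw_pause(BehaviorParams(k2=4), rng) for _ in range(n)])
    assert abs(mean - lam) < 3 * math.sqrt(lam / n)


@pytest.mark.parametrize("k2,lam", [(4, 15.0), (8, 35.0)])
def test_pause_distribution_matches_closed_form(k2, lam, rng):
    """Chi-square goodness of fit of drawn pauses against exp(-lam)*lam^t/t!."""
    n = 20_000
    draws = np.array([draw_pause(BehaviorParams(k2=k2), rng) for _ in range(n)])
    assert draws.mean() == pytest.approx(lam, rel=0.05)
    hi = int(lam + 6 * math.sqrt(lam))
    observed = np.bincount(draws, minlength=hi + 1)[: hi + 1].astype(float)
    # closed-form pmf, tail mass folded into the last bin
    pmf = np.array(
        [math.exp(-lam) * lam**t / math.factorial(t) for t in range(hi + 1)]
    )
    observed = np.append(observed, n - observed.sum())
    pmf = np.append(pmf, 1.0 - pmf.sum())
    keep = pmf * n >= 5
    stat, p = stats.chisquare(observed[keep], pmf[keep] / pmf[keep].sum() * observed[keep].sum())
    assert p > 0.01


# --------------------------------------------------------------------------
# movement and endpoint events


def test_unit_speed_and_degenerate_pause(small_tunnel, rng):
    w = make_world(small_tunnel, [50, 60], [1, -1], irregular_sites={51})
    step(w, rng)   # k2=1: pause draw degenerates to zero
    assert list(w.pos) == [51, 59]
    assert np.all(w.state == AgentState.MOVING)
    assert w.n_pauses == 0


def test_pause_holds_agent_for_tau_steps(small_tunnel):
    rng = np.random.default_rng(1)
    w = make_world(
        small_tunnel, [50], [1], params=BehaviorParams(k2=11), irregular_sites={51}
    )
    step(w, rng)
    assert w.pos[0] == 51 and w.state[0] == AgentState.PAUSED
    tau = int(w.timer[0])
    assert tau > 0
    for _ in range(tau):
        step(w, rng)
        assert w.pos[0] == 51
    step(w, rng)
    assert w.pos[0] == 52  # re-walks one step after the timer expires


def test_endpoint_pickup_and_deposit_values(small_tunnel, rng):
    w = make_world(small_tunnel, [99, 1, 1], [1, -1, -1], cargo=[-1, 0, 12])
    step(w, rng)
    # empty agent reaching the food site picks up a fresh particle and reverses
    assert w.pos[0] == 100 and w.cargo[0] == 0 and w.dirn[0] == -1
    # carriers reaching the nest deposit max(0, 1 - 0.09 n) and reverse
    assert w.ledger.values == pytest.approx([1.0, 0.0])
    assert np.all(w.cargo[1:] == -1) and np.all(w.dirn[1:] == 1)


@pytest.mark.parametrize("n,value", [(0, 1.0), (1, 0.91), (5, 0.55), (11, 0.01), (12, 0.0), (40, 0.0)])
def test_deposit_value_formula(n, value):
    assert deposit_value(n) == pytest.approx(value)


def test_wrong_configuration_arrivals_reverse(small_tunnel, rng):
    # a carrier arriving at the food end and an empty agent at the nest only turn
    w = make_world(small_tunnel, [99, 1], [1, -1], cargo=[3, -1])
    step(w, rng)
    assert w.cargo[0] == 3 and w.dirn[0] == -1
    assert w.cargo[1] == -1 and w.dirn[1] == 1
    assert len(w.ledger) == 0


# --------------------------------------------------------------------------
# transfers


def co_located_pair(tunnel, cargo, dirs=(1, -1), p=1.0, rule="encounter"):
    return make_world(
        tunnel, [50, 50], list(dirs), cargo=list(cargo),
        params=BehaviorParams(p_transfer=p, meeting_rule=rule),
    )


def test_transfer_moves_particle_with_loss_and_reversal(small_tunnel, rng):
    w = co_located_pair(small_tunnel, [2, -1])
    transfer_phase(w, rng)
    assert list(w.cargo) == [-1, 3]
    assert list(w.dirn) == [-1, 1]
    assert w.n_transfers == 1


def test_transfer_chain_value_at_nest(small_tunnel):
    """A particle handed over once deposits 0.91."""
    rng = np.random.default_rng(2)
    w = make_world(
        small_tunnel, [5, 3], [-1, 1], cargo=[0, -1],
        params=BehaviorParams(p_transfer=1.0),
    )
    step(w, rng)  # agents at 4,4: handoff, both reverse
    assert list(w.cargo) == [-1, 1]
    for _ in range(10):
        step(w, rng)
    assert w.ledger.values == pytest.approx([0.91])


def test_multi_neighbor_transfer_selects_one_recipient(small_tunnel, rng):
    w = make_world(
        small_tunnel, [50, 50, 50, 50], [1, -1, -1, -1], cargo=[4, -1, -1, -1],
        params=BehaviorParams(p_transfer=1.0),
    )
    transfer_phase(w, rng)
    carried = w.cargo >= 0
    assert carried.sum() == 1 and w.cargo[carried][0] == 5
    assert w.n_transfers == 1


def test_carrier_carrier_meetings_never_transfer(small_tunnel, rng):
    w = co_located_pair(small_tunnel, [0, 3])
    transfer_phase(w, rng)
    assert list(w.cargo) == [0, 3]
    assert list(w.dirn) == [1, -1]
    assert w.n_transfers == 0


def test_jammed_agents_do_not_transfer(small_tunnel, rng):
    w = co_located_pair(small_tunnel, [2, -1])
    w.state[1] = AgentState.JAMMED
    w.timer[1] = 50
    transfer_phase(w, rng)
    assert list(w.cargo) == [2, -1]


def test_encounter_rule_attempts_once_per_contact(small_tunnel):
    """A pair that stays in contact does not re-attempt every step."""
    rng = np.random.default_rng(0)
    w = make_world(
        small_tunnel, [50, 50], [1, 1], cargo=[0, -1],
        params=BehaviorParams(p_transfer=1e-12),  # never fires, pair stays lockstep
    )
    # register the first contact, then raise p: no new meeting, no transfer
    transfer_phase(w, rng)
    object.__setattr__(w.params, "p_transfer", 1.0)
    transfer_phase(w, rng)   # same contact persists: no new meeting, no transfer
    assert w.n_transfers == 0


def test_crossing_pass_counts_as_meeting(small_tunnel):
    """Odd-gap opposite walkers swap sites without co-locating yet still meet."""
    rng = np.random.default_rng(0)
    w = make_world(
        small_tunnel, [50, 51], [1, -1], cargo=[0, -1],
        params=BehaviorParams(p_transfer=1.0),
    )
    step(w, rng)
    assert list(w.pos) == [51, 50]   # passed each other
    assert w.n_transfers == 1
    assert list(w.cargo) == [-1, 1]


# --------------------------------------------------------------------------
# jams


@pytest.mark.parametrize(
    "dirs,expected_events",
    [((1, 1, -1, -1), 1), ((1, -1), 0), ((1, 1, 1, -1), 0),
     ((1, 1, 1, -1, -1, -1), 1), ((1, 1, 1, 1, -1, -1, -1, -1), 2)],
)
def test_jam_formation_zero_sum_groups(small_tunnel, rng, dirs, expected_events):
    w = make_world(small_tunnel, [50] * len(dirs), list(dirs))
    jam_phase(w, rng)
    assert len(w.jam_log) == expected_events
    assert (w.state == AgentState.JAMMED).sum() == 4 * expected_events
    for t, site, size in w.jam_log.events:
        assert site == 50 and size == 4


def test_jam_freeze_lasts_jam_duration_then_disperses(small_tunnel):
    rng = np.random.default_rng(4)
    params = BehaviorParams(p_transfer=0.0, jam_duration=100)
    # arranged to co-locate at site 50 after one move
    w = make_world(small_tunnel, [49, 49, 51, 51], [1, 1, -1, -1], params=params)
    step(w, rng)
    assert np.all(w.pos == 50) and np.all(w.state == AgentState.JAMMED)
    for _ in range(100):
        step(w, rng)
        assert np.all(w.pos == 50)
    assert np.all(w.state == AgentState.MOVING)
    step(w, rng)
    assert sorted(w.pos) == [49, 49, 51, 51]   # released group disperses, no re-jam
    assert len(w.jam_log) == 1


def test_two_agents_head_on_pass_without_jam(small_tunnel):
    """Brute-force trace: an even-gap head-on pair co-occupies then passes."""
    rng = np.random.default_rng(0)
    w = make_world(
        small_tunnel, [40, 44], [1, -1], params=BehaviorParams(p_transfer=0.0)
    )
    trace = []
    for _ in range(6):
        step(w, rng)
        trace.append(tuple(w.pos))
    assert trace == [(41, 43), (42, 42), (43, 41), (44, 40), (45, 39), (46, 38)]
    assert len(w.jam_log) == 0


# --------------------------------------------------------------------------
# whole-run invariants


def run_world(k1=1, k2=1, k3=6, k4=1, T=1200, seed=11, n_agents=40, **kw):
    rng = np.random.default_rng(seed)
    spec = build_tunnel()
    lay = place_irregularities(spec, k3, k4, rng)
    w = init_world(BehaviorParams(k1=k1, k2=k2, **kw), spec, lay, rng, n_agents=n_agents)
    dynamics.run(w, rng, T)
    return w


def test_agent_count_and_value_conservation():
    w = run_world(k1=6, k2=4, k4=5, T=1500)
    assert w.n_agents == 40
    assert w.ledger.total <= w.n_pickups
    # every deposited value sits on the 1 - 0.09 n grid (clipped at zero)
    for v in w.ledger.values:
        if v > 0:
            n = round((1.0 - v) / 0.09)
            assert v == pytest.approx(max(0.0, 1.0 - 0.09 * n))


def test_no_stop_or_pause_mechanisms_at_baseline_levels():
    """k1=1 and k4=1: no curvature stop and no pause over a full run."""
    w = run_world(k1=1, k2=8, k4=1, T=2000)
    assert w.n_curvature_stops == 0
    assert w.n_pauses == 0


def test_seed_reproducibility_of_full_runs():
    w1 = run_world(k1=4, k2=4, k4=4, seed=5)
    w2 = run_world(k1=4, k2=4, k4=4, seed=5)
    w3 = run_world(k1=4, k2=4, k4=4, seed=6)
    assert w1.ledger.times == w2.ledger.times
    assert w1.ledger.values == w2.ledger.values
    assert w1.jam_log.events == w2.jam_log.events
    assert np.array_equal(w1.pos, w2.pos)
    assert (w1.ledger.values, w1.jam_log.events) != (w3.ledger.values, w3.jam_log.events)


def test_step_past_limit_rejected(small_tunnel, rng):
    w = make_world(small_tunnel, [50], [1])
    step(w, rng, T=1)
    with pytest.raises(ValueError):
        step(w, rng, T=1)


def test_behavior_params_validation():
    with pytest.raises(ValueError):
        BehaviorParams(k1=0)
    with pytest.raises(ValueError):
        BehaviorParams(p_transfer=1.5)
    with pytest.raises(ValueError):
        BehaviorParams(meeting_rule="telepathy")
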