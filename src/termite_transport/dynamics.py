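"""Agent dynamics: one-step world updates for the food-transport model.

Each of the N0 agents occupies a lattice site, faces the nest (-1) or the food
end (+1), optionally carries one food particle (tracked by its transfer-loss
count n), and is in one of three activity states:

* MOVING  — advances one site per step in its facing direction,
* PAUSED  — inspecting a surface irregularity for a Poisson(lambda) number of
  steps,
* JAMMED  — frozen for ``jam_duration`` steps after a four-agent stand-off.

A step applies, in order: timer decrement (expired agents resume movement the
*next* step) -> movement with curvature stops, endpoint pickup/deposit and
irregularity pauses -> bucket-brigade transfers -> jam formation -> metrics
recording.  All randomness flows through a single numpy Generator, so a run is
bit-reproducible from its seed.

The state lives in flat numpy arrays inside :class:`WorldState`; per-agent
``Termite`` snapshots are available through :attr:`WorldState.agents` for
inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .metrics import FoodLedger, JamLog
from .tunnel import IrregularityLayout, TunnelSpec


class AgentState(IntEnum):
    MOVING = 0
    PAUSED = 1
    JAMMED = 2


@dataclass(frozen=True)
class BehaviorParams:
    """Behavioral constants, with the curvature/pause levels mapped to rates.

    ``stop_prob = (k1-1)*0.05`` is the per-step probability that an agent inside
    a high-curvature zone stops instead of walking; ``lam = (k2-1)*5`` is the
    mean of the Poisson pause drawn on arrival at an irregularity site.
    """

    k1: int = 1
    k2: int = 1
    p_transfer: float = 0.2
    loss_per_transfer: float = 0.09
    jam_group: int = 4
    jam_duration: int = 100
    meeting_rule: str = "encounter"

    def __post_init__(self) -> None:
        for name in ("k1", "k2"):
            v = getattr(self, name)
            if v not in range(1, 12):
                raise ValueError(f"{name} must be in 1..11, got {v!r}")
        if not 0.0 <= self.p_transfer <= 1.0:
            raise ValueError("p_transfer must be a probability")
        if self.meeting_rule not in ("encounter", "site_encounter", "colocated"):
            raise ValueError(
                "meeting_rule must be 'encounter', 'site_encounter' or 'colocated'"
            )
        if self.jam_group != 4:
            # the zero-sum rule below hard-codes 2+2 groups
            raise ValueError("jam_group other than 4 is not supported")

    @property
    def stop_prob(self) -> float:
        return (self.k1 - 1) * 0.05

    @property
    def lam(self) -> float:
        return (self.k2 - 1) * 5.0


@dataclass(frozen=True)
class Termite:
    """Read-only snapshot of one agent."""

    position: int
    direction: int          # -1 toward nest, +1 toward food
    cargo: int | None       # None if empty, else the particle's loss count n
    state: AgentState
    remaining: int          # steps left in PAUSED/JAMMED, 0 when MOVING


@dataclass
class WorldState:
    """Full simulation state: geometry, layout, agent arrays, logs, clock."""

    tunnel: TunnelSpec
    layout: IrregularityLayout
    params: BehaviorParams
    pos: np.ndarray          # int64[N] site index
    dirn: np.ndarray         # int64[N] in {-1, +1}
    cargo: np.ndarray        # int64[N]; -1 = empty, else loss count n >= 0
    state: np.ndarray        # uint8[N] AgentState codes
    timer: np.ndarray        # int64[N] remaining frozen steps
    clock: int = 0
    ledger: FoodLedger = field(default_factory=FoodLedger)
    jam_log: JamLog = field(default_factory=JamLog)
    # event counters (diagnostics and invariants)
    n_pickups: int = 0
    n_deposits: int = 0
    n_transfers: int = 0
    n_curvature_stops: int = 0
    n_pauses: int = 0
    # cached site masks and last pre-move positions
    _zone_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _irr_mask: np.ndarray = field(default=None, repr=False)   # type: ignore[assignment]
    _prev_pos: np.ndarray = field(default=None, repr=False)   # type: ignore[assignment]
    _prev_contacts: set = field(default_factory=set, repr=False)
    _just_released: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self._zone_mask is None:
            self._zone_mask = self.tunnel.curvature_mask()
        if self._irr_mask is None:
            self._irr_mask = self.layout.site_mask(self.tunnel)

    @property
    def n_agents(self) -> int:
        return self.pos.size

    @property
    def agents(self) -> list[Termite]:
        """Per-agent snapshots (ordered by agent index)."""
        return [
            Termite(
                position=int(self.pos[i]),
                direction=int(self.dirn[i]),
                cargo=None if self.cargo[i] < 0 else int(self.cargo[i]),
                state=AgentState(int(self.state[i])),
                remaining=int(self.timer[i]),
            )
            for i in range(self.n_agents)
        ]


def init_world(
    params: BehaviorParams,
    tunnel: TunnelSpec,
    layout: IrregularityLayout,
    rng: np.random.Generator,
    n_agents: int = 100,
) -> WorldState:
    """Place ``n_agents`` cargo-free agents uniformly at random interior sites.

    Directions are uniform random +/-1; all agents start MOVING at clock 0.
    """
    if n_agents < 1:
        raise ValueError("n_agents must be positive")
    pos = rng.integers(1, tunnel.length_cells - 1, size=n_agents)
    dirn = rng.integers(0, 2, size=n_agents) * 2 - 1
    return WorldState(
        tunnel=tunnel,
        layout=layout,
        params=params,
        pos=pos.astype(np.int64),
        dirn=dirn.astype(np.int64),
        cargo=np.full(n_agents, -1, dtype=np.int64),
        state=np.zeros(n_agents, dtype=np.uint8),
        timer=np.zeros(n_agents, dtype=np.int64),
    )


def curvature_stop_draw(params: BehaviorParams, rng: np.random.Generator) -> bool:
    """One in-zone stop decision: True (stop) iff U(0,1) < (k1-1)*0.05."""
    return bool(rng.random() < params.stop_prob)


def draw_pause(params: BehaviorParams, rng: np.random.Generator) -> int:
    """Pause length tau ~ Poisson(lambda), lambda=(k2-1)*5; 0 without sampling
    when lambda = 0."""
    if params.lam == 0.0:
        return 0
    return int(rng.poisson(params.lam))


def deposit_value(n: int, loss_per_transfer: float = 0.09) -> float:
    """Value of a particle transferred n times: max(0, 1 - loss*n)."""
    return max(0.0, 1.0 - loss_per_transfer * n)


# ---------------------------------------------------------------------------
# phases


def _timer_phase(world: WorldState) -> np.ndarray:
    """Decrement PAUSED/JAMMED timers; return the pre-decrement MOVING mask.

    Agents whose timer reaches zero become MOVING but only walk again on the
    following step, so a freeze of duration d suppresses exactly d moves.
    """
    moving = world.state == AgentState.MOVING
    frozen = ~moving
    if frozen.any():
        world.timer[frozen] -= 1
        freed = frozen & (world.timer <= 0)
        world.state[freed] = AgentState.MOVING
        world.timer[freed] = 0
        world._just_released = freed
    else:
        world._just_released = None
    return moving


def move_phase(world: WorldState, rng: np.random.Generator) -> None:
    """Timers, movement with curvature stops, endpoint events, pauses."""
    moving = _timer_phase(world)
    params, t = world.params, world.clock + 1
    world._prev_pos = world.pos.copy()

    walkers = moving.copy()
    in_zone = moving & world._zone_mask[world.pos]
    nz = int(in_zone.sum())
    if nz:
        # one uniform draw per in-zone agent per step
        stops = np.zeros_like(walkers)
        stops[in_zone] = rng.random(nz) < params.stop_prob
        world.n_curvature_stops += int(stops.sum())
        walkers &= ~stops

    world.pos[walkers] += world.dirn[walkers]

    arrived = np.flatnonzero(walkers)
    if arrived.size == 0:
        return
    ap = world.pos[arrived]

    at_food = arrived[ap == world.tunnel.food_x]
    if at_food.size:
        picker = at_food[world.cargo[at_food] < 0]
        world.cargo[picker] = 0
        world.n_pickups += picker.size
        world.dirn[at_food] *= -1        # carriers arriving "wrong" just reverse

    at_nest = arrived[ap == world.tunnel.nest_x]
    if at_nest.size:
        dep = at_nest[world.cargo[at_nest] >= 0]
        if dep.size:
            values = np.clip(
                1.0 - world.params.loss_per_transfer * world.cargo[dep], 0.0, None
            )
            world.ledger.record_many(t, values)
            world.n_deposits += dep.size
            world.cargo[dep] = -1
        world.dirn[at_nest] *= -1

    if params.lam > 0.0:
        hit = arrived[world._irr_mask[world.pos[arrived]]]
        if hit.size:
            tau = rng.poisson(params.lam, size=hit.size)
            pausing = hit[tau > 0]
            world.state[pausing] = AgentState.PAUSED
            world.timer[pausing] = tau[tau > 0]
            world.n_pauses += pausing.size


def endpoint_update(world: WorldState, agent: int) -> None:
    """Apply the pickup/deposit/reversal rule to one agent at an endpoint.

    ``move_phase`` handles endpoint arrivals in bulk; this scalar form exists
    for inspection and testing.
    """
    x = int(world.pos[agent])
    if x == world.tunnel.food_x:
        if world.cargo[agent] < 0:
            world.cargo[agent] = 0
            world.n_pickups += 1
        world.dirn[agent] *= -1
    elif x == world.tunnel.nest_x:
        if world.cargo[agent] >= 0:
            world.ledger.record(
                world.clock + 1,
                deposit_value(int(world.cargo[agent]), world.params.loss_per_transfer),
            )
            world.n_deposits += 1
            world.cargo[agent] = -1
        world.dirn[agent] *= -1
    else:
        raise ValueError(f"agent {agent} at x={x} is not at an endpoint")


# integer state codes for hot paths (AgentState is the public face)
_MOVING, _PAUSED, _JAMMED = 0, 1, 2


def _colocated_groups(pos: np.ndarray, min_size: int = 2):
    """List of (site, member_indices) for every site holding >= min_size agents."""
    order = np.argsort(pos, kind="stable")
    sp = pos[order]
    boundaries = np.flatnonzero(sp[1:] != sp[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [sp.size]))
    return [
        (int(sp[a]), order[a:b]) for a, b in zip(starts, ends) if b - a >= min_size
    ]


def _current_contacts(
    world: WorldState, groups, include_crossings: bool = True
) -> set[tuple[int, int]]:
    """Unordered agent pairs in contact this step.

    A pair is in contact if the two agents occupy the same site, or if they
    swapped adjacent sites during the last move (they passed each other on the
    connecting edge; such passes never co-locate when the gap parity is odd).
    """
    contacts: set[tuple[int, int]] = set()
    for _site, members in groups:
        ms = np.sort(members).tolist()
        for a in range(len(ms)):
            for b in range(a + 1, len(ms)):
                contacts.add((ms[a], ms[b]))
    if include_crossings and world._prev_pos is not None:
        moved_idx = np.flatnonzero(world.pos != world._prev_pos)
        if moved_idx.size >= 2:
            # agents traversing the same edge share pos + prev (odd, unique)
            edge = world.pos[moved_idx] + world._prev_pos[moved_idx]
            for _eid, local in _colocated_groups(edge):
                members = moved_idx[local]
                heads = world.pos[members] > world._prev_pos[members]
                fwd = members[heads].tolist()
                bwd = members[~heads].tolist()
                for i in fwd:
                    for j in bwd:
                        contacts.add((i, j) if i < j else (j, i))
    return contacts


def transfer_phase(world: WorldState, rng: np.random.Generator, groups=None) -> None:
    """Bucket-brigade hand-offs between carriers and cargo-free agents.

    Under the default ``meeting_rule="encounter"``, a carrier and an empty
    agent meet when they come into *new* contact: they arrive on a shared site
    or pass each other on an edge, and were not already in contact on the
    previous step.  Each non-jammed carrier with at least one newly met,
    non-jammed, cargo-free partner attempts one transfer with probability
    ``p_transfer``; on success one partner is chosen uniformly at random, the
    particle moves with loss count n+1, and both parties reverse direction.
    Carrier-carrier meetings never transfer; an agent takes part in at most
    one transfer per step.

    ``meeting_rule="colocated"`` instead treats persistent same-site
    co-location as a meeting every step (one attempt per carrier per step),
    ignoring edge crossings.
    """
    p = world.params.p_transfer
    if p <= 0.0:
        return
    if groups is None:
        groups = _colocated_groups(world.pos)
    used = np.zeros(world.n_agents, dtype=bool)
    if world.params.meeting_rule == "colocated":
        for _site, members in groups:
            free = members[(world.state[members] != _JAMMED) & ~used[members]]
            if free.size < 2:
                continue
            has_cargo = world.cargo[free] >= 0
            _attempt(world, free[has_cargo], list(free[~has_cargo]), used, rng)
        return

    contacts = _current_contacts(
        world, groups, include_crossings=world.params.meeting_rule == "encounter"
    )
    new_pairs = contacts - world._prev_contacts if world._prev_contacts else contacts
    world._prev_contacts = contacts
    if not new_pairs:
        return
    # group newly met empties by carrier
    partners: dict[int, list[int]] = {}
    for a, b in sorted(new_pairs):
        if world.state[a] == _JAMMED or world.state[b] == _JAMMED:
            continue
        ca, cb = world.cargo[a] >= 0, world.cargo[b] >= 0
        if ca and not cb:
            partners.setdefault(a, []).append(b)
        elif cb and not ca:
            partners.setdefault(b, []).append(a)
    for c in rng.permutation(np.fromiter(partners, dtype=np.int64, count=len(partners))):
        recipients = [r for r in partners[int(c)] if not used[r]]
        if used[c] or not recipients:
            continue
        _attempt(world, np.array([c]), recipients, used, rng)


def _attempt(
    world: WorldState,
    carriers: np.ndarray,
    empties: list[int],
    used: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """One p_transfer draw per carrier; uniform recipient choice on success."""
    for c in rng.permutation(carriers) if carriers.size > 1 else carriers:
        if not empties:
            break
        if rng.random() < world.params.p_transfer:
            r = empties.pop(int(rng.integers(len(empties))))
            world.cargo[r] = world.cargo[c] + 1
            world.cargo[c] = -1
            world.dirn[c] *= -1
            world.dirn[r] *= -1
            used[c] = used[r] = True
            world.n_transfers += 1


def jam_phase(world: WorldState, rng: np.random.Generator, groups=None) -> None:
    """Freeze disjoint zero-sum groups of four co-located agents.

    At each site, among non-jammed agents, groups of exactly four with
    direction sum zero (two facing each way) form greedily; every grouped agent
    enters JAMMED(jam_duration) and each group logs one event.  Agents released
    from a freeze this very step have not yet re-met anyone and are exempt
    until they have moved (otherwise a released quartet would re-jam in place
    forever).
    """
    t = world.clock + 1
    dur = world.params.jam_duration
    if groups is None:
        groups = _colocated_groups(world.pos, min_size=4)
    for site, members in groups:
        if members.size < 4:
            continue
        free = members[world.state[members] != _JAMMED]
        if world._just_released is not None:
            free = free[~world._just_released[free]]
        if free.size < 4:
            continue
        plus = free[world.dirn[free] > 0]
        minus = free[world.dirn[free] < 0]
        n_groups = min(plus.size, minus.size) // 2
        if n_groups == 0:
            continue
        chosen = np.concatenate(
            (
                rng.permutation(plus)[: 2 * n_groups],
                rng.permutation(minus)[: 2 * n_groups],
            )
        )
        world.state[chosen] = AgentState.JAMMED
        world.timer[chosen] = dur
        for _ in range(n_groups):
            world.jam_log.record(t, site, 4)


def step(world: WorldState, rng: np.random.Generator, T: int | None = None) -> WorldState:
    """Advance the world by one time step (in place; returns the world).

    Phase order: timer decrement -> movement (with endpoint and pause events)
    -> transfers -> jams.  The clock increments at the end; events recorded in
    this step carry time ``clock + 1``.
    """
    if T is not None and world.clock >= T:
        raise ValueError(f"cannot step past T={T}")
    move_phase(world, rng)
    groups = _colocated_groups(world.pos)
    transfer_phase(world, rng, groups)
    jam_phase(world, rng, groups)
    world.clock += 1
    return world


def run(
    world: WorldState,
    rng: np.random.Generator,
    T: int,
    trajectory: list | None = None,
) -> WorldState:
    """Run ``T`` steps; optionally append per-step (t, pos, dirn, state, cargo)
    snapshots to ``trajectory`` for space-time plots."""
    for _ in range(T):
        step(world, rng)
        if trajectory is not None:
            trajectory.append(
                (
                    world.clock,
                    world.pos.copy(),
                    world.dirn.copy(),
                    world.state.copy(),
                    world.cargo.copy(),
                )
            )
    return world
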