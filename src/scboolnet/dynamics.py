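"""Synchronous Boolean dynamics: trajectories, attractors, exhaustive oracle.

All genes update simultaneously from the previous state.  A trajectory from
any initial state of a finite deterministic system must eventually revisit a
state; the states between the first visit and the revisit form the attractor
(singleton fixed point or longer cycle).  Trajectory simulation is the
production path — one run per cell, seeded with that cell's binarized
expression — while :func:`enumerate_attractors_bruteforce` walks the whole
2^n state space and serves as the small-n oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .boolean_network import BooleanNetwork, NetworkState

__all__ = [
    "Trajectory",
    "Attractor",
    "SimulationResult",
    "synchronous_step",
    "simulate_to_attractor",
    "enumerate_attractors_bruteforce",
    "BRUTEFORCE_SIZE_GUARD",
]

BRUTEFORCE_SIZE_GUARD = 22
DEFAULT_MAX_STEPS = 10_000


@dataclass(frozen=True)
class Attractor:
    """Terminal cycle in canonical rotation (lexicographically smallest state first)."""

    cycle: tuple[NetworkState, ...]
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind",
                           "singleton" if len(self.cycle) == 1 else "cyclic")

    @property
    def period(self) -> int:
        return len(self.cycle)

    @classmethod
    def from_cycle(cls, states: list[NetworkState] | tuple[NetworkState, ...]) -> "Attractor":
        states = tuple(states)
        k = min(range(len(states)), key=lambda i: states[i].bits)
        return cls(states[k:] + states[:k])

    def gene_fraction_on(self, gene_index: int) -> float:
        """Fraction of cycle states in which the gene is 1."""
        return sum(s[gene_index] for s in self.cycle) / self.period

    def packed(self) -> str:
        return "|".join(s.packed() for s in self.cycle)

    def __repr__(self) -> str:
        return f"Attractor(period={self.period}, kind={self.kind})"


@dataclass
class Trajectory:
    """Visited states from the initial state up to and including the first revisit."""

    states: list[NetworkState]
    first_repeat_index: int | None

    @property
    def steps_taken(self) -> int:
        return len(self.states) - 1

    @property
    def steps_to_cycle(self) -> int | None:
        return self.first_repeat_index


@dataclass
class SimulationResult:
    """Trajectory plus its attractor; ``attractor is None`` marks a no-result run."""

    trajectory: Trajectory
    attractor: Attractor | None

    @property
    def reached(self) -> bool:
        return self.attractor is not None


def synchronous_step(net: BooleanNetwork, state: NetworkState) -> NetworkState:
    """One synchronous update: every gene reads only the old state."""
    if len(state) != net.n:
        raise ValueError(f"state length {len(state)} != network size {net.n}")
    return NetworkState(net.step_bits(state.bits))


def simulate_to_attractor(net: BooleanNetwork, initial: NetworkState,
                          max_steps: int = DEFAULT_MAX_STEPS) -> SimulationResult:
    """Iterate the synchronous map until a state repeats; extract the cycle.

    Returns a no-result marker (``attractor=None``) if ``max_steps`` updates
    pass without a revisit; with ``max_steps >= 2**net.n`` that cannot
    happen.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if len(initial) != net.n:
        raise ValueError(f"state length {len(initial)} != network size {net.n}")
    seen: dict[tuple, int] = {initial.bits: 0}
    states = [initial]
    bits = initial.bits
    for step in range(1, max_steps + 1):
        bits = net.step_bits(bits)
        state = NetworkState(bits)
        states.append(state)
        if bits in seen:
            entry = seen[bits]
            cycle = states[entry:step]
            traj = Trajectory(states=states, first_repeat_index=entry)
            return SimulationResult(traj, Attractor.from_cycle(cycle))
        seen[bits] = step
    return SimulationResult(Trajectory(states=states, first_repeat_index=None), None)


def enumerate_attractors_bruteforce(net: BooleanNetwork) -> list[tuple[Attractor, int]]:
    """Exact attractor set with basin sizes by walking all 2^n states.

    Basins partition the state space, so basin sizes sum to 2^n.  Guarded to
    n <= 22; use trajectory simulation beyond that.
    """
    n = net.n
    if n > BRUTEFORCE_SIZE_GUARD:
        raise ValueError(
            f"network size {n} exceeds the brute-force guard "
            f"({BRUTEFORCE_SIZE_GUARD}); use simulate_to_attractor")
    # successor map over integer-coded states
    succ: list[int] = []
    for code in range(1 << n):
        bits = tuple((code >> (n - 1 - i)) & 1 for i in range(n))
        new = net.step_bits(bits)
        succ.append(sum(b << (n - 1 - i) for i, b in enumerate(new)))

    attractor_of: list[int | None] = [None] * (1 << n)
    attractors: list[Attractor] = []
    basins: list[int] = []
    for start in range(1 << n):
        if attractor_of[start] is not None:
            continue
        path = []
        pos: dict[int, int] = {}
        code = start
        while attractor_of[code] is None and code not in pos:
            pos[code] = len(path)
            path.append(code)
            code = succ[code]
        if attractor_of[code] is not None:
            aid = attractor_of[code]
        else:
            cycle_codes = path[pos[code]:]
            cycle = [NetworkState(((c >> (n - 1 - i)) & 1) for i in range(n))
                     for c in cycle_codes]
            attractors.append(Attractor.from_cycle(cycle))
            basins.append(0)
            aid = len(attractors) - 1
        for c in path:
            attractor_of[c] = aid
            basins[aid] += 1
    return list(zip(attractors, basins))
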