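"""Seven-phase gait vocabulary and the walking-cycle ordering.

A gait cycle is conventionally divided into stance and swing; here the
walking cycle is resolved into six phases traversed in a fixed cyclic
order — heel strike, foot flat, midstance, heel off, toe-off, swing —
plus a seventh, quiet standing, which sits outside the cycle.
"""

from __future__ import annotations

from enum import Enum


class Phase(Enum):
    """One of the seven gait phases.

    The integer value fixes the enumeration order used for matrix rows,
    report tables and deterministic tie-breaking.
    """

    STAND = 0
    HEEL_STRIKE = 1
    FOOT_FLAT = 2
    MIDSTANCE = 3
    HEEL_OFF = 4
    TOE_OFF = 5
    SWING = 6

    @property
    def short(self) -> str:
        """Two-letter abbreviation (ST, HS, FF, MS, HO, TO, SW)."""
        return _SHORT[self]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


_SHORT = {
    Phase.STAND: "ST",
    Phase.HEEL_STRIKE: "HS",
    Phase.FOOT_FLAT: "FF",
    Phase.MIDSTANCE: "MS",
    Phase.HEEL_OFF: "HO",
    Phase.TOE_OFF: "TO",
    Phase.SWING: "SW",
}

#: All seven phases in enumeration order.
ALL_PHASES: tuple[Phase, ...] = tuple(Phase)

#: The six walking phases in the order they are traversed within a cycle.
WALKING_CYCLE: tuple[Phase, ...] = (
    Phase.HEEL_STRIKE,
    Phase.FOOT_FLAT,
    Phase.MIDSTANCE,
    Phase.HEEL_OFF,
    Phase.TOE_OFF,
    Phase.SWING,
)

#: The walking phases as a set (everything except STAND).
WALKING_PHASES: frozenset[Phase] = frozenset(WALKING_CYCLE)

#: Junction phases: short transitional postures between the primary ones.
JUNCTION_PHASES: frozenset[Phase] = frozenset({Phase.FOOT_FLAT, Phase.HEEL_OFF})

N_PHASES = 7
N_SENSORS = 5

#: Sensor names, anterior (under the toes) to posterior (under the heel).
SENSOR_NAMES: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")


def cycle_successor(phase: Phase) -> Phase:
    """Return the phase that follows ``phase`` in the walking cycle.

    The cycle is cyclic: the successor of SWING wraps to HEEL_STRIKE.
    STAND is outside the cycle and has no successor.

    Raises
    ------
    ValueError
        If ``phase`` is STAND.
    """
    if phase is Phase.STAND:
        raise ValueError("STAND is outside the walking cycle and has no successor")
    i = WALKING_CYCLE.index(phase)
    return WALKING_CYCLE[(i + 1) % len(WALKING_CYCLE)]
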