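"""Design of the resource-allocation game.

Every trial opposes a fixed *default* allocation — 100 points for the
decision-maker, 50 for an anonymous recipient (1 point = 0.10 EUR) — to an
*alternative* allocation drawn from the integer lattice near the circle of
radius 50 centred at (50, 50).  The polar angle of an alternative relative to
the circle centre is the social-value-orientation (SVO) angle it expresses:
positive angles give the recipient more than 50 points (prosocial), negative
angles less (antisocial).  A small number of *selfish* alternatives pay the
decision-maker more than 100 points while leaving the recipient at 50; these
probe response bias rather than social attitude.

The module generates the full 406-allocation set from the published selection
rules, partitions it into the four angle-balanced subsets used across
experimental phases, and reads/writes the shared allocation CSV dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Role",
    "Phase",
    "Allocation",
    "TrialSet",
    "DEFAULT_ALLOCATION",
    "allocation_angle",
    "generate_allocation_set",
    "partition_subsets",
    "make_selfish_trials",
    "make_manipulation_set",
    "write_allocations_csv",
    "read_allocations_csv",
]

CENTRE = (50.0, 50.0)
RADIUS = 50.0
BAND_TOLERANCE = 1.0
ANGLE_LIMIT_DEG = 112.5
EXPECTED_SET_SIZE = 406
SUBSET_SIZES = (102, 102, 101, 101)


class Role(str, Enum):
    """What an allocation is doing in the design."""

    default = "default"
    prosocial_alt = "prosocial_alt"
    antisocial_alt = "antisocial_alt"
    selfish_alt = "selfish_alt"


class Phase(str, Enum):
    before = "before"
    manipulation = "manipulation"
    after = "after"


class DegenerateAllocationError(ValueError):
    """Raised for the circle centre (50, 50), whose angle is undefined."""


class PartitionMismatchError(ValueError):
    """Raised when partitioning is asked of anything but the full 406 set."""


@dataclass(frozen=True)
class Allocation:
    """An integer point pair (self, other) with its design role."""

    pi_self: int
    pi_other: int
    role: Role

    def __post_init__(self) -> None:
        if self.role is Role.default and (self.pi_self, self.pi_other) != (100, 50):
            raise ValueError("the default allocation is (100, 50)")
        if self.role is Role.prosocial_alt and self.pi_other <= 50:
            raise ValueError("prosocial alternatives give the other more than 50")
        if self.role is Role.antisocial_alt and self.pi_other >= 50:
            raise ValueError("antisocial alternatives give the other less than 50")
        if self.role is Role.selfish_alt and not (self.pi_self > 100 and self.pi_other == 50):
            raise ValueError("selfish alternatives pay self > 100 with other at 50")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.pi_self, self.pi_other)


DEFAULT_ALLOCATION = Allocation(100, 50, Role.default)


@dataclass(frozen=True)
class TrialSet:
    """An ordered list of allocations presented in one phase."""

    allocations: tuple[Allocation, ...]
    phase: Phase
    subset_id: int

    def __post_init__(self) -> None:
        pairs = [a.pair for a in self.allocations]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (pi_self, pi_other) pair within a trial set")

    def __len__(self) -> int:
        return len(self.allocations)


def _role_for(pi_other: int) -> Role:
    return Role.prosocial_alt if pi_other > 50 else Role.antisocial_alt


def allocation_angle(a: Allocation | tuple[int, int]) -> float:
    """Polar angle of an allocation in degrees, self axis at 0.

    Measured at the circle centre (50, 50), in (-180, 180].  The default
    (100, 50) sits at 0 deg; pure generosity (50, 100) at +90 deg.
    """
    x, y = (a.pi_self, a.pi_other) if isinstance(a, Allocation) else a
    if (x, y) == (50, 50):
        raise DegenerateAllocationError("angle undefined at the circle centre (50, 50)")
    ang = math.degrees(math.atan2(y - 50.0, x - 50.0))
    # atan2 returns (-180, 180]; normalise -180 to +180 for the contract
    return 180.0 if ang == -180.0 else ang


def generate_allocation_set(
    radius: float = RADIUS,
    tolerance: float = BAND_TOLERANCE,
    angle_limit: float = ANGLE_LIMIT_DEG,
) -> list[Allocation]:
    """All circle-band alternative allocations under the selection rules.

    Integer pairs are kept when, in order: their distance from (50, 50) lies
    in [radius - tolerance, radius + tolerance]; their polar angle lies in
    [-angle_limit, +angle_limit]; they do not pay the self more than the
    default (pi_self <= 100); they do not pay the other exactly the default's
    50; and the other's payoff lies in [0, 100].  With the default parameters
    this yields the published 406 alternatives.  Deterministic.
    """
    if not (radius > tolerance > 0):
        raise ValueError("requires radius > tolerance > 0")
    lo, hi = radius - tolerance, radius + tolerance
    span = int(math.ceil(hi)) + 1
    out: list[Allocation] = []
    for x in range(50 - span, 50 + span + 1):
        for y in range(50 - span, 50 + span + 1):
            d = math.hypot(x - 50, y - 50)
            if not (lo <= d <= hi):
                continue
            if abs(allocation_angle((x, y))) > angle_limit:
                continue
            if x > 100:
                continue
            if y == 50:
                continue
            if not (0 <= y <= 100):
                continue
            out.append(Allocation(x, y, _role_for(y)))
    return out


def partition_subsets(allocations: Sequence[Allocation]) -> list[TrialSet]:
    """Split the 406-allocation set into four angle-balanced subsets.

    Allocations are sorted by angle and dealt round-robin into four subsets,
    which therefore sample the arc evenly; the two left-over allocations of
    the 4 x 101 deal go to subsets 1 and 2, giving sizes 102/102/101/101.
    """
    if len(allocations) != EXPECTED_SET_SIZE:
        raise PartitionMismatchError(
            f"expected the full {EXPECTED_SET_SIZE}-allocation set, got {len(allocations)}"
        )
    ordered = sorted(allocations, key=allocation_angle)
    buckets: list[list[Allocation]] = [[], [], [], []]
    for i, a in enumerate(ordered):
        buckets[i % 4].append(a)
    # round-robin over 406 = 4*101 + 2 already leaves the two extras in
    # buckets 0 and 1; assert rather than re-trim
    sizes = tuple(len(b) for b in buckets)
    assert sizes == SUBSET_SIZES, sizes
    return [
        TrialSet(tuple(b), Phase.before, subset_id=i + 1)
        for i, b in enumerate(buckets)
    ]


def make_selfish_trials(n: int = 9, seed: int | np.random.Generator = 0) -> list[Allocation]:
    """Synthetic stand-ins for the 9 self-advantageous allocations.

    The originals (deposited with the study materials) pay the self more than
    100 points with the other fixed at 50; only that much is specified here,
    so pi_self is drawn uniformly without replacement from [101, 110].
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n > 10:
        raise ValueError("only 10 integer values available in (100, 110]")
    rng = np.random.default_rng(seed)
    vals = rng.choice(np.arange(101, 111), size=n, replace=False)
    return [Allocation(int(v), 50, Role.selfish_alt) for v in vals]


def make_manipulation_set(
    source: TrialSet, n: int = 63, seed: int | np.random.Generator = 0
) -> TrialSet:
    """Angle-stratified sample of ``n`` alternatives for the prediction phase.

    The held-out subset is sorted by angle and divided into ``n`` contiguous
    strata; one allocation is drawn per stratum, so the sample spans the arc.
    """
    if n > len(source):
        raise ValueError("cannot sample more trials than the source subset holds")
    rng = np.random.default_rng(seed)
    ordered = sorted(source.allocations, key=allocation_angle)
    edges = np.linspace(0, len(ordered), n + 1)
    picks = []
    for i in range(n):
        lo, hi = int(edges[i]), max(int(edges[i]), int(edges[i + 1]) - 1)
        picks.append(ordered[int(rng.integers(lo, hi + 1))])
    return TrialSet(tuple(picks), Phase.manipulation, subset_id=source.subset_id)


# ---------------------------------------------------------------------------
# CSV dialect: header pi_self,pi_other,role,subset_id

def write_allocations_csv(path, trial_sets: Iterable[TrialSet]) -> None:
    rows = [
        {"pi_self": a.pi_self, "pi_other": a.pi_other, "role": a.role.value,
         "subset_id": ts.subset_id}
        for ts in trial_sets
        for a in ts.allocations
    ]
    pd.DataFrame(rows, columns=["pi_self", "pi_other", "role", "subset_id"]).to_csv(
        path, index=False
    )


def read_allocations_csv(path, phase: Phase = Phase.before) -> list[TrialSet]:
    df = pd.read_csv(path)
    sets = []
    for sid, grp in df.groupby("subset_id", sort=True):
        allocs = tuple(
            Allocation(int(r.pi_self), int(r.pi_other), Role(r.role))
            for r in grp.itertuples()
        )
        sets.append(TrialSet(allocs, phase, subset_id=int(sid)))
    return sets
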