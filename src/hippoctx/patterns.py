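"""Synthetic object/context worlds and corrupted test batteries.

The model's training world is a set of sparse binary patterns: each object or
context is a flattened 8x8 binary matrix with exactly ``n_active`` (default 16)
of its 64 units on.  Objects are grouped under contexts (default 120 objects,
40 contexts, 3 objects per context) and every object is associated with exactly
one context.

Test inputs are produced by four corruption operators:

``additive``
    extra units switched on (active count grows),
``nonadditive``
    paired swaps -- for every zero turned on, an original one is turned off
    (active count preserved),
``partial``
    only a fraction of the original ones is retained (the level is a
    *completeness* fraction: 1.0 is the intact pattern),
``mixed``
    half the budget applied additively, half non-additively.

Noise levels are fractions of the pattern's original active count by default
(``basis='active_units'``); ``basis='total_units'`` is available for
sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Role",
    "BinaryPattern",
    "AssociationSet",
    "CorruptionMode",
    "CorruptionSpec",
    "TargetBundle",
    "Trial",
    "BATTERY_NAMES",
    "generate_pattern",
    "build_association_set",
    "make_targets",
    "corrupt",
    "build_test_battery",
]

DEFAULT_N_UNITS = 64
DEFAULT_N_ACTIVE = 16


class Role(str, Enum):
    OBJECT = "object"
    CONTEXT = "context"


@dataclass(frozen=True)
class BinaryPattern:
    """A fixed-length binary activity vector with an id and a role."""

    values: np.ndarray
    role: Role
    id: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("pattern values must be a 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pattern values must be 0/1")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n_units(self) -> int:
        return self.values.size

    @property
    def n_active(self) -> int:
        return int(self.values.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryPattern):
            return NotImplemented
        return (
            self.id == other.id
            and self.role == other.role
            and np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.id, self.role, self.values.tobytes()))


@dataclass(frozen=True)
class AssociationSet:
    """The generated world: objects, contexts and the object->context map."""

    objects: tuple[BinaryPattern, ...]
    contexts: tuple[BinaryPattern, ...]
    objects_per_context: int
    context_of: Mapping[int, int]

    def __post_init__(self) -> None:
        if len(self.objects) != self.objects_per_context * len(self.contexts):
            raise ValueError(
                "|objects| must equal objects_per_context * |contexts|"
            )
        counts: dict[int, int] = {}
        ctx_ids = {c.id for c in self.contexts}
        for obj in self.objects:
            cid = self.context_of.get(obj.id)
            if cid not in ctx_ids:
                raise ValueError(f"object {obj.id} maps to unknown context {cid}")
            counts[cid] = counts.get(cid, 0) + 1
        if any(n != self.objects_per_context for n in counts.values()):
            raise ValueError("every context must own exactly objects_per_context objects")

    def object_by_id(self, oid: int) -> BinaryPattern:
        for o in self.objects:
            if o.id == oid:
                return o
        raise KeyError(f"unknown object id {oid}")

    def context_by_id(self, cid: int) -> BinaryPattern:
        for c in self.contexts:
            if c.id == cid:
                return c
        raise KeyError(f"unknown context id {cid}")

    def objects_of_context(self, cid: int) -> tuple[BinaryPattern, ...]:
        """Objects owned by a context, in ascending id (canonical slot) order."""
        members = sorted(
            (o for o in self.objects if self.context_of[o.id] == cid),
            key=lambda o: o.id,
        )
        if not members:
            raise KeyError(f"unknown context id {cid}")
        return tuple(members)


class CorruptionMode(str, Enum):
    ADDITIVE = "additive"
    NONADDITIVE = "nonadditive"
    PARTIAL = "partial"
    MIXED = "mixed"


@dataclass(frozen=True)
class CorruptionSpec:
    mode: CorruptionMode
    level: float
    basis: str = "active_units"  # or "total_units"

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError("level must be in [0, 1]")
        if self.basis not in ("active_units", "total_units"):
            raise ValueError(f"unknown basis {self.basis!r}")

    def n_change(self, pattern: BinaryPattern) -> int:
        base = pattern.n_active if self.basis == "active_units" else pattern.n_units
        return _round_half_away(self.level * base)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TargetBundle:
    """Ground-truth patterns for the four output streams of one trial.

    O and OBCG are keyed to the object (and the context it was *trained* with);
    C and CBOG are keyed to the *presented* context.  CBOG concatenates the
    presented context's objects in ascending object-id order.
    """

    O: BinaryPattern
    OBCG: BinaryPattern
    C: BinaryPattern
    CBOG: np.ndarray
    cbog_slot_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.CBOG, dtype=np.uint8).copy()
        arr.flags.writeable = False
        object.__setattr__(self, "CBOG", arr)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "O": self.O.values,
            "OBCG": self.OBCG.values,
            "C": self.C.values,
            "CBOG": self.CBOG,
        }


@dataclass(frozen=True)
class Trial:
    """One presentation: LEC/MEC inputs (either may be absent) plus targets."""

    lec_input: BinaryPattern | None
    mec_input: BinaryPattern | None
    targets: TargetBundle
    tags: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lec_input is None and self.mec_input is None:
            raise ValueError("at least one of lec_input/mec_input must be present")


def generate_pattern(
    n_units: int,
    n_active: int,
    rng: np.random.Generator,
    *,
    role: Role = Role.OBJECT,
    id: int = 0,
) -> BinaryPattern:
    """Uniformly random binary pattern with exactly ``n_active`` ones."""
    if not 0 <= n_active <= n_units:
        raise ValueError(f"n_active={n_active} must be in [0, n_units={n_units}]")
    values = np.zeros(n_units, dtype=np.uint8)
    on = rng.choice(n_units, size=n_active, replace=False)
    values[on] = 1
    return BinaryPattern(values=values, role=role, id=id)


def build_association_set(
    n_contexts: int = 40,
    objects_per_context: int = 3,
    n_units: int = DEFAULT_N_UNITS,
    n_active: int = DEFAULT_N_ACTIVE,
    rng: np.random.Generator | None = None,
) -> AssociationSet:
    """Generate the training world: distinct patterns, one context per object."""
    if n_contexts <= 0 or objects_per_context <= 0 or n_units <= 0 or n_active < 0:
        raise ValueError("all counts must be positive")
    n_objects = n_contexts * objects_per_context
    n_total = n_objects + n_contexts
    if math.comb(n_units, n_active) < n_total:
        raise ValueError(
            f"cannot draw {n_total} distinct {n_active}-of-{n_units} patterns"
        )
    if rng is None:
        rng = np.random.default_rng()

    seen: set[bytes] = set()

    def draw(role: Role, pid: int) -> BinaryPattern:
        while True:
            p = generate_pattern(n_units, n_active, rng, role=role, id=pid)
            key = p.values.tobytes()
            if key not in seen:
                seen.add(key)
                return p

    contexts = tuple(draw(Role.CONTEXT, cid) for cid in range(n_contexts))
    objects = tuple(draw(Role.OBJECT, oid) for oid in range(n_objects))
    context_of = {oid: oid % n_contexts for oid in range(n_objects)}
    return AssociationSet(
        objects=objects,
        contexts=contexts,
        objects_per_context=objects_per_context,
        context_of=context_of,
    )


def make_targets(object_id: int, context_id: int, assoc: AssociationSet) -> TargetBundle:
    """Ground truth for a trial presenting ``object_id`` with ``context_id``.

    OBCG is the context the object was associated with during training (which
    differs from ``context_id`` on mismatch trials); C and CBOG follow the
    presented context.
    """
    obj = assoc.object_by_id(object_id)
    trained_ctx = assoc.context_by_id(assoc.context_of[object_id])
    presented_ctx = assoc.context_by_id(context_id)
    slots = assoc.objects_of_context(context_id)
    cbog = np.concatenate([o.values for o in slots])
    return TargetBundle(
        O=obj,
        OBCG=trained_ctx,
        C=presented_ctx,
        CBOG=cbog,
        cbog_slot_ids=tuple(o.id for o in slots),
    )


def corrupt(
    p: BinaryPattern,
    spec: CorruptionSpec,
    rng: np.random.Generator,
) -> BinaryPattern:
    """Apply one corruption operator; see the module docstring for contracts."""
    values = np.array(p.values, dtype=np.uint8)
    ones = np.flatnonzero(values == 1)
    zeros = np.flatnonzero(values == 0)

    if spec.mode is CorruptionMode.PARTIAL:
        # level is completeness: retain round(level * basis) of the ones
        n_keep = spec.n_change(p)
        if n_keep > ones.size:
            n_keep = ones.size
        keep = rng.choice(ones, size=n_keep, replace=False) if n_keep else np.array([], dtype=int)
        values[:] = 0
        values[keep] = 1
        return replace(p, values=values)

    n_change = spec.n_change(p)
    if n_change == 0:
        return replace(p, values=values)
    if spec.mode is not CorruptionMode.ADDITIVE and ones.size == 0:
        raise ValueError("pattern must have at least one active unit")

    if spec.mode is CorruptionMode.ADDITIVE:
        n_add, n_swap = n_change, 0
    elif spec.mode is CorruptionMode.NONADDITIVE:
        n_add, n_swap = 0, n_change
    else:  # MIXED: odd remainder goes to the additive half
        n_swap = n_change // 2
        n_add = n_change - n_swap

    if n_add + n_swap > zeros.size:
        raise ValueError(
            f"cannot turn on {n_add + n_swap} units: only {zeros.size} zeros available"
        )
    if n_swap > ones.size:
        raise ValueError(
            f"cannot turn off {n_swap} units: only {ones.size} ones available"
        )

    turn_on = rng.choice(zeros, size=n_add + n_swap, replace=False)
    turn_off = rng.choice(ones, size=n_swap, replace=False) if n_swap else np.array([], dtype=int)
    values[turn_on] = 1
    values[turn_off] = 0
    return replace(p, values=values)


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    if n < 2:
        raise ValueError("a derangement needs at least 2 elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


BATTERY_NAMES = (
    "cbog_context_only",
    "partial_context",
    "partial_object",
    "additive_object",
    "additive_context",
    "nonadditive_object",
    "nonadditive_context",
    "mismatch",
    "sample_O_C",
    "sample_OBCG",
    "sample_CBOG",
)

# The calibration ("sample") tasks: mixed 15% noise / 40% complete for O and C,
# mismatch plus degraded-context-only tests for OBCG, and mismatch plus
# degraded-object-only tests for CBOG.
SAMPLE_NOISE_LEVEL = 0.15
SAMPLE_PARTIAL_LEVEL = 0.40
SAMPLE_SINGLE_NOISE_LEVEL = 0.30


def _matched_pairs(assoc: AssociationSet) -> list[tuple[int, int]]:
    return [(o.id, assoc.context_of[o.id]) for o in assoc.objects]


def _trial(
    assoc: AssociationSet,
    oid: int,
    cid: int,
    lec: BinaryPattern | None,
    mec: BinaryPattern | None,
    tags: dict,
) -> Trial:
    return Trial(lec_input=lec, mec_input=mec, targets=make_targets(oid, cid, assoc), tags=tags)


def _zero_pattern(template: BinaryPattern) -> BinaryPattern:
    return replace(template, values=np.zeros(template.n_units, dtype=np.uint8))


def build_test_battery(
    assoc: AssociationSet,
    battery_name: str,
    levels: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    basis: str = "active_units",
) -> list[Trial]:
    """Build the named corrupted/mismatched test battery.

    One trial is produced per (object-context association, level).  The
    degraded input is corrupted at the given level and the other input is
    presented clean.  ``cbog_context_only`` clamps the LEC input to all zeros
    (an absent cue); ``mismatch`` re-pairs every object with a deranged
    context so that no object sees its trained context.
    """
    if battery_name not in BATTERY_NAMES:
        raise ValueError(f"unknown battery {battery_name!r}")
    if rng is None:
        rng = np.random.default_rng()
    pairs = _matched_pairs(assoc)
    trials: list[Trial] = []

    def spec(mode: CorruptionMode, level: float) -> CorruptionSpec:
        return CorruptionSpec(mode=mode, level=level, basis=basis)

    if battery_name == "cbog_context_only":
        for oid, cid in pairs:
            ctx = assoc.context_by_id(cid)
            lec = _zero_pattern(assoc.object_by_id(oid))
            trials.append(_trial(assoc, oid, cid, lec, ctx, {"battery": battery_name}))
        return trials

    if battery_name == "mismatch":
        perm = _random_derangement(len(assoc.contexts), rng)
        for oid, cid in pairs:
            new_cid = assoc.contexts[perm[cid]].id
            trials.append(
                _trial(
                    assoc,
                    oid,
                    new_cid,
                    assoc.object_by_id(oid),
                    assoc.context_by_id(new_cid),
                    {"battery": battery_name, "mismatch": True},
                )
            )
        return trials

    if battery_name in ("sample_O_C", "sample_OBCG", "sample_CBOG"):
        return _build_sample_battery(assoc, battery_name, rng, basis)

    mode, side = {
        "partial_context": (CorruptionMode.PARTIAL, "context"),
        "partial_object": (CorruptionMode.PARTIAL, "object"),
        "additive_object": (CorruptionMode.ADDITIVE, "object"),
        "additive_context": (CorruptionMode.ADDITIVE, "context"),
        "nonadditive_object": (CorruptionMode.NONADDITIVE, "object"),
        "nonadditive_context": (CorruptionMode.NONADDITIVE, "context"),
    }[battery_name]
    if levels is None:
        raise ValueError(f"battery {battery_name!r} requires corruption levels")

    for level in levels:
        for oid, cid in pairs:
            obj = assoc.object_by_id(oid)
            ctx = assoc.context_by_id(cid)
            if side == "object":
                obj = corrupt(obj, spec(mode, level), rng)
            else:
                ctx = corrupt(ctx, spec(mode, level), rng)
            trials.append(
                _trial(assoc, oid, cid, obj, ctx, {"battery": battery_name, "level": level})
            )
    return trials


def _build_sample_battery(
    assoc: AssociationSet,
    battery_name: str,
    rng: np.random.Generator,
    basis: str,
) -> list[Trial]:
    pairs = _matched_pairs(assoc)
    trials: list[Trial] = []
    mixed15 = CorruptionSpec(CorruptionMode.MIXED, SAMPLE_NOISE_LEVEL, basis)
    partial40 = CorruptionSpec(CorruptionMode.PARTIAL, SAMPLE_PARTIAL_LEVEL, basis)
    mixed30 = CorruptionSpec(CorruptionMode.MIXED, SAMPLE_SINGLE_NOISE_LEVEL, basis)

    if battery_name == "sample_O_C":
        for oid, cid in pairs:
            obj = corrupt(assoc.object_by_id(oid), mixed15, rng)
            ctx = corrupt(assoc.context_by_id(cid), mixed15, rng)
            trials.append(_trial(assoc, oid, cid, obj, ctx, {"battery": battery_name, "subtest": "noise"}))
        for oid, cid in pairs:
            obj = corrupt(assoc.object_by_id(oid), partial40, rng)
            ctx = corrupt(assoc.context_by_id(cid), partial40, rng)
            trials.append(_trial(assoc, oid, cid, obj, ctx, {"battery": battery_name, "subtest": "partial"}))
        return trials

    degrade_context = battery_name == "sample_OBCG"
    trials.extend(
        Trial(
            lec_input=t.lec_input,
            mec_input=t.mec_input,
            targets=t.targets,
            tags={"battery": battery_name, "subtest": "mismatch"},
        )
        for t in build_test_battery(assoc, "mismatch", rng=rng, basis=basis)
    )
    for subtest, cspec in (("noise", mixed30), ("partial", partial40)):
        for oid, cid in pairs:
            obj = assoc.object_by_id(oid)
            ctx = assoc.context_by_id(cid)
            if degrade_context:
                ctx = corrupt(ctx, cspec, rng)
            else:
                obj = corrupt(obj, cspec, rng)
            trials.append(_trial(assoc, oid, cid, obj, ctx, {"battery": battery_name, "subtest": subtest}))
    return trials
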