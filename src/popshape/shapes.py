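"""Deterministic classification of bucket vectors into eleven shapes.

The five-bucket pyramid reduction yields a sequence of four steps, each
-1 / 0 / +1 for a bucket becoming smaller, staying equal, or becoming
larger bottom-up.  Most of the 81 possible step patterns map straight to
one of eleven shapes — pyramid, bell, plunger and their inverses,
lower/middle/upper diamond, column, hourglass — but some patterns are
ambiguous and need an extra comparison of two non-consecutive buckets:
the canonical example is (-1,-1,-1,+1), a pyramid when the top bucket
stays below the third bucket and an hourglass when it recovers.

The complete mapping ships as a reviewable CSV data asset
(``data/decision_table.csv``) rather than hard-coded logic; rows pinned
directly by the published shape descriptions are marked ``anchored``,
rows forced by mirror anti-symmetry are marked ``mirror``, and the
remainder — derived from a level-path rule consistent with all anchored
rows — are marked ``reconstructed`` so they can be replaced wholesale if
the literal published mapping becomes available.

The mapping is mirror anti-symmetric by construction: classifying a
bucket vector upside down yields the mirrored shape (pyramid <->
inverted pyramid, lower <-> upper diamond, ...), with column,
middle diamond and hourglass their own mirrors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .pyramid import LT, BucketVector, compare_buckets, step_sequence
from .studbook_io import SpeciesConfig

__all__ = [
    "SHAPES",
    "NOT_ASCRIBED",
    "DecisionRule",
    "decision_table",
    "build_decision_table",
    "classify",
    "mirror_shape",
]

PYRAMID = "pyramid"
INVERTED_PYRAMID = "inverted_pyramid"
BELL = "bell"
INVERTED_BELL = "inverted_bell"
PLUNGER = "plunger"
INVERTED_PLUNGER = "inverted_plunger"
LOWER_DIAMOND = "lower_diamond"
MIDDLE_DIAMOND = "middle_diamond"
UPPER_DIAMOND = "upper_diamond"
COLUMN = "column"
HOURGLASS = "hourglass"
NOT_ASCRIBED = "not_ascribed"

SHAPES = (
    PYRAMID, INVERTED_PYRAMID, BELL, INVERTED_BELL, PLUNGER,
    INVERTED_PLUNGER, LOWER_DIAMOND, MIDDLE_DIAMOND, UPPER_DIAMOND,
    COLUMN, HOURGLASS,
)

_MIRROR = {
    PYRAMID: INVERTED_PYRAMID,
    INVERTED_PYRAMID: PYRAMID,
    BELL: INVERTED_BELL,
    INVERTED_BELL: BELL,
    PLUNGER: INVERTED_PLUNGER,
    INVERTED_PLUNGER: PLUNGER,
    LOWER_DIAMOND: UPPER_DIAMOND,
    UPPER_DIAMOND: LOWER_DIAMOND,
    MIDDLE_DIAMOND: MIDDLE_DIAMOND,
    COLUMN: COLUMN,
    HOURGLASS: HOURGLASS,
    NOT_ASCRIBED: NOT_ASCRIBED,
}


def mirror_shape(shape: str) -> str:
    """The shape of the upside-down pyramid; self for symmetric shapes."""
    try:
        return _MIRROR[shape]
    except KeyError:
        raise ValueError(f"unknown shape {shape!r}") from None


@dataclass(frozen=True)
class DecisionRule:
    """Outcome for one step pattern, optionally guarded.

    When ``guard`` is set, the rule compares bucket ``guard[0]`` against
    bucket ``guard[1]`` (1-based, bottom-up) under the SEM-overlap test:
    the outcome is ``shape_if_true`` unless the first is strictly smaller
    (LT), in which case it is ``shape_if_false``.
    """

    pattern: tuple[int, int, int, int]
    shape_if_true: str
    shape_if_false: str
    guard: Optional[tuple[int, int]] = None
    provenance: str = "reconstructed"

    @property
    def unconditional(self) -> bool:
        return self.guard is None or self.shape_if_true == self.shape_if_false


def _mirror_pattern(p: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(-s for s in reversed(p))


def _levels(p: tuple[int, ...]) -> list[int]:
    out = [0]
    for s in p:
        out.append(out[-1] + s)
    return out


def _diamond_for(max_positions: list[int]) -> str:
    # A maximum plateau that reaches the middle bucket reads as a middle
    # diamond; otherwise the plateau's side decides.  Either convention
    # is mirror-consistent; this one avoids calling a broad central
    # plateau an extreme diamond.
    center = sum(max_positions) / len(max_positions)
    if 3 in max_positions or center == 3:
        return MIDDLE_DIAMOND
    if center < 3:
        return LOWER_DIAMOND
    return UPPER_DIAMOND


# Patterns whose outcome is pinned directly by the published shape
# descriptions and the worked ambiguous example.
_ANCHORED = {
    (-1, -1, -1, -1),     # default expectation: broad base, narrow top
    (1, 1, 1, 1),         # inverted pyramid
    (0, 0, 0, 0),         # column
    (0, -1, -1, -1),      # no juvenile mortality: bell
    (-1, 0, 0, -1),       # columnar adults subsumed under pyramid
    (-1, -1, -1, 1),      # the worked pyramid-vs-hourglass guard case
    (-1, -1, -1, 0),      # flat adult-senior top, normal reproduction:
    (-1, -1, 0, 0),       # plunger family
    (-1, 0, -1, 0),
    (-1, 0, 0, 0),
}


def _derive_rule(p: tuple[int, int, int, int]) -> DecisionRule:
    """Level-path rule producing one decision per pattern.

    Monotone patterns resolve by their first and last step (flat top ->
    plunger family, strict first and last decline -> pyramid, flat base
    with a final decline -> bell, mirrored for rises); a single rise
    followed by decline is a diamond positioned at the level maximum; a
    single decline followed by recovery is an hourglass guarded on
    whether the top recovers past the bucket preceding the interior
    minimum; patterns with several direction changes resolve by the
    position of their level extremes.
    """
    provenance = "anchored" if p in _ANCHORED else "reconstructed"

    def rule(shape, guard=None, if_false=None):
        return DecisionRule(
            pattern=p,
            shape_if_true=shape,
            shape_if_false=if_false if if_false is not None else shape,
            guard=guard,
            provenance=provenance,
        )

    if all(s == 0 for s in p):
        return rule(COLUMN)

    if all(s <= 0 for s in p):
        if p[3] == 0:
            return rule(PLUNGER)
        if p[0] == -1:
            return rule(PYRAMID)
        return rule(BELL)

    if all(s >= 0 for s in p):
        if p[0] == 0:
            return rule(INVERTED_PLUNGER)
        if p[3] == 1:
            return rule(INVERTED_PYRAMID)
        return rule(INVERTED_BELL)

    levels = _levels(p)
    signs = [s for s in p if s != 0]
    changes = sum(1 for a, b in zip(signs, signs[1:]) if a != b)

    if changes == 1 and signs[0] == 1:
        # single rise then decline: the broadest part names the diamond
        top = max(levels)
        return rule(_diamond_for([i for i, l in enumerate(levels, 1) if l == top]))

    if changes == 1 and signs[0] == -1:
        # decline then recovery: hourglass candidate
        q = _mirror_pattern(p)
        if q == p:
            return rule(HOURGLASS)
        if p <= q:
            bottom = min(levels)
            ref = next(i for i, l in enumerate(levels, 1) if l == bottom) - 1
            if levels[0] > levels[4]:
                fallback = PYRAMID
            elif levels[0] < levels[4]:
                fallback = INVERTED_PYRAMID
            else:
                fallback = HOURGLASS
            if fallback == HOURGLASS:
                return rule(HOURGLASS)
            return rule(HOURGLASS, guard=(5, ref), if_false=fallback)
        # non-canonical orientation: forced by mirror anti-symmetry
        base = _derive_rule(q)
        guard = None
        if base.guard is not None:
            guard = (6 - base.guard[0], 6 - base.guard[1])
        return DecisionRule(
            pattern=p,
            shape_if_true=mirror_shape(base.shape_if_true),
            shape_if_false=mirror_shape(base.shape_if_false),
            guard=guard,
            provenance="mirror",
        )

    # several direction changes: resolve by the level extremes
    top, bottom = max(levels), min(levels)
    max_pos = [i for i, l in enumerate(levels, 1) if l == top]
    min_pos = [i for i, l in enumerate(levels, 1) if l == bottom]
    if 1 not in max_pos and 5 not in max_pos:
        return rule(_diamond_for(max_pos))
    if 1 not in min_pos and 5 not in min_pos:
        return rule(HOURGLASS)
    if levels[0] > levels[4]:
        return rule(PYRAMID)
    if levels[0] < levels[4]:
        return rule(INVERTED_PYRAMID)
    raise AssertionError(f"unclassifiable pattern {p}")  # pragma: no cover


def build_decision_table() -> list[DecisionRule]:
    """Derive the full 81-row table from the level-path rule."""
    steps = (-1, 0, 1)
    rules = [
        _derive_rule((s1, s2, s3, s4))
        for s1 in steps for s2 in steps for s3 in steps for s4 in steps
    ]
    _check_table(rules)
    return rules


def _check_table(rules: list[DecisionRule]) -> None:
    """Startup self-check: totality, determinism, mirror anti-symmetry."""
    index = {r.pattern: r for r in rules}
    if len(index) != 81 or len(rules) != 81:
        raise AssertionError("decision table must cover all 81 patterns once")
    for r in rules:
        for shape in (r.shape_if_true, r.shape_if_false):
            if shape not in SHAPES:
                raise AssertionError(f"unknown shape {shape!r} in table")
        m = index[_mirror_pattern(r.pattern)]
        if m.shape_if_true != mirror_shape(r.shape_if_true) or (
            m.shape_if_false != mirror_shape(r.shape_if_false)
        ):
            raise AssertionError(
                f"mirror anti-symmetry violated at {r.pattern}"
            )
        if (r.guard is None) != (m.guard is None):
            raise AssertionError(f"guard mismatch under mirror at {r.pattern}")
        if r.guard is not None and m.guard != (6 - r.guard[0], 6 - r.guard[1]):
            raise AssertionError(f"guard indices not mirrored at {r.pattern}")


_TABLE: Optional[dict[tuple[int, int, int, int], DecisionRule]] = None


def _table_resource():
    return importlib.resources.files("popshape").joinpath(
        "data/decision_table.csv"
    )


def decision_table() -> list[DecisionRule]:
    """Load (and cache) the shipped decision table, self-checked."""
    global _TABLE
    if _TABLE is None:
        with importlib.resources.as_file(_table_resource()) as path:
            frame = pd.read_csv(path, keep_default_na=False)
        rules = []
        for row in frame.itertuples(index=False):
            pattern = (int(row.step1), int(row.step2),
                       int(row.step3), int(row.step4))
            guard = None
            if row.guard:
                a, b = row.guard.split("~")
                guard = (int(a), int(b))
            rules.append(DecisionRule(
                pattern=pattern,
                shape_if_true=row.shape_if_true,
                shape_if_false=row.shape_if_false,
                guard=guard,
                provenance=row.provenance,
            ))
        _check_table(rules)
        _TABLE = {r.pattern: r for r in rules}
    return list(_TABLE.values())


def write_decision_table(path) -> None:
    """Regenerate the CSV data asset from the level-path rule."""
    rows = []
    for r in build_decision_table():
        rows.append({
            "step1": r.pattern[0],
            "step2": r.pattern[1],
            "step3": r.pattern[2],
            "step4": r.pattern[3],
            "guard": f"{r.guard[0]}~{r.guard[1]}" if r.guard else "",
            "shape_if_true": r.shape_if_true,
            "shape_if_false": r.shape_if_false,
            "provenance": r.provenance,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def classify(v: BucketVector, config: Optional[SpeciesConfig] = None) -> str:
    """Classify one bucket vector into one of the eleven shapes.

    Vectors of populations at or below the ascription threshold return
    ``not_ascribed`` so yearly series keep their grid.  Guarded patterns
    compare the named non-consecutive buckets with the same SEM-overlap
    test used for the step sequence.
    """
    config = config or SpeciesConfig()
    if not v.ascribable:
        return NOT_ASCRIBED
    decision_table()
    rule = _TABLE[step_sequence(v, config.sem_factor)]
    if rule.unconditional:
        return rule.shape_if_true
    a, b = rule.guard
    cmp = compare_buckets(v.buckets[a - 1], v.buckets[b - 1], config.sem_factor)
    return rule.shape_if_false if cmp == LT else rule.shape_if_true
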