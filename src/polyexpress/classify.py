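"""Classification of three-taxon band units into differential expression states.

A *unit* is one band position scored in the A-genome parent (``a``), the
somatic hybrid (``h``) and the E-genome parent (``e``) with ordinal
intensity levels ``0..L`` (0 = absent).  Relative to the two parents the
hybrid can sit in one of 12 differential states, conventionally labelled
with Roman numerals:

* additivity (mid-parent): I (a > e) and XII (a < e);
* E-expression-level dominance: II (hybrid matches the E parent, expressed)
  and XI (hybrid matches the E parent, silent);
* A-expression-level dominance: IV (expressed) and IX (silent);
* transgressive down (below both parents): III, VII, X;
* transgressive up (above both parents): V, VI, VIII.

Units whose three levels are all equal are "no change" (mid-parent) and are
excluded from percentage denominators downstream.
"""

from __future__ import annotations

import enum
from typing import Iterable, Sequence, Tuple

Levels = Tuple[int, int, int]


class Category(enum.Enum):
    """The 12 differential expression states plus the non-differential one."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"
    XI = "XI"
    XII = "XII"
    NO_CHANGE = "NO_CHANGE"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: The 12 differential categories in canonical order (NO_CHANGE excluded).
DIFFERENTIAL_CATEGORIES: Tuple[Category, ...] = tuple(
    c for c in Category if c is not Category.NO_CHANGE
)


class CategoryGroup(enum.Enum):
    ADDITIVITY = "additivity"
    A_DOMINANCE = "A_dominance"
    E_DOMINANCE = "E_dominance"
    TRANSGRESSIVE_UP = "transgressive_up"
    TRANSGRESSIVE_DOWN = "transgressive_down"
    NO_CHANGE = "no_change"


class DominanceDirection(enum.Enum):
    EXPRESSED = "expressed"
    SILENT = "silent"
    NA = "na"


_GROUPS = {
    Category.I: CategoryGroup.ADDITIVITY,
    Category.XII: CategoryGroup.ADDITIVITY,
    Category.IV: CategoryGroup.A_DOMINANCE,
    Category.IX: CategoryGroup.A_DOMINANCE,
    Category.II: CategoryGroup.E_DOMINANCE,
    Category.XI: CategoryGroup.E_DOMINANCE,
    Category.V: CategoryGroup.TRANSGRESSIVE_UP,
    Category.VI: CategoryGroup.TRANSGRESSIVE_UP,
    Category.VIII: CategoryGroup.TRANSGRESSIVE_UP,
    Category.III: CategoryGroup.TRANSGRESSIVE_DOWN,
    Category.VII: CategoryGroup.TRANSGRESSIVE_DOWN,
    Category.X: CategoryGroup.TRANSGRESSIVE_DOWN,
    Category.NO_CHANGE: CategoryGroup.NO_CHANGE,
}

_DIRECTIONS = {
    Category.IV: DominanceDirection.EXPRESSED,
    Category.II: DominanceDirection.EXPRESSED,
    Category.IX: DominanceDirection.SILENT,
    Category.XI: DominanceDirection.SILENT,
}


def group_of(category: Category) -> CategoryGroup:
    """Roll a category up to its expression-pattern group."""
    return _GROUPS[category]


def dominance_direction(category: Category) -> DominanceDirection:
    """Expressed vs silent split of the dominance categories (NA otherwise)."""
    return _DIRECTIONS.get(category, DominanceDirection.NA)


def _validate_levels(levels: Sequence[int], max_level: int | None) -> Levels:
    if len(levels) != 3:
        raise ValueError(f"expected 3 levels (a, h, e), got {len(levels)}")
    out = []
    for name, x in zip("ahe", levels):
        xi = int(x)
        if xi != x:
            raise ValueError(f"level {name}={x!r} is not an integer")
        if xi < 0 or (max_level is not None and xi > max_level):
            hi = max_level if max_level is not None else "inf"
            raise ValueError(f"level {name}={xi} outside [0, {hi}]")
        out.append(xi)
    return tuple(out)  # type: ignore[return-value]


def classify_unit(
    levels: Sequence[int],
    delta: int = 0,
    max_level: int | None = None,
) -> Category:
    """Assign a (a, h, e) level triple to its differential expression state.

    Two levels are treated as equal when they differ by at most ``delta``
    (default 0: levels are already coarse ordinals).  Dominance (hybrid equal
    to one parent) takes precedence over strict intermediacy when ``delta``
    makes both readings possible, and the A side is tested before the E side.

    Parameters
    ----------
    levels
        ``(a, h, e)``: the A parent, the hybrid and the E parent.
    delta
        Equality tolerance on the ordinal intensity scale; must be
        non-negative and smaller than the scale maximum when one is given.
    max_level
        Optional intensity-scale maximum used to validate inputs.

    Returns
    -------
    Category
        Exactly one of I..XII or NO_CHANGE (total partition of level space).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if max_level is not None and delta >= max_level:
        raise ValueError("delta must be smaller than the intensity maximum")
    a, h, e = _validate_levels(levels, max_level)

    def eq(x: int, y: int) -> bool:
        return abs(x - y) <= delta

    if eq(a, e):
        # parents indistinguishable: hybrid either matches the mid-parent
        # value or is transgressive
        if h > max(a, e) + delta:
            return Category.VIII
        if h < min(a, e) - delta:
            return Category.VII
        return Category.NO_CHANGE
    if a > e:
        if eq(h, a):
            return Category.IV
        if eq(h, e):
            return Category.XI
        if h > a:
            return Category.V
        if h < e:
            return Category.III
        return Category.I
    # a < e
    if eq(h, e):
        return Category.II
    if eq(h, a):
        return Category.IX
    if h > e:
        return Category.VI
    if h < a:
        return Category.X
    return Category.XII


def is_novel(levels: Sequence[int]) -> bool:
    """Novel (acquired) expression: band in the hybrid, in neither parent."""
    a, h, e = _validate_levels(levels, None)
    return a == 0 and e == 0 and h > 0


def is_silenced(levels: Sequence[int]) -> bool:
    """Silencing: band in both parents, none in the hybrid."""
    a, h, e = _validate_levels(levels, None)
    return a > 0 and e > 0 and h == 0


def classify_units(
    units: Iterable[Sequence[int]],
    delta: int = 0,
    max_level: int | None = None,
) -> list[Category]:
    """Classify an iterable of (a, h, e) triples."""
    return [classify_unit(u, delta=delta, max_level=max_level) for u in units]


def category_levels(
    category: Category, max_level: int, delta: int = 0
) -> list[Levels]:
    """All (a, h, e) triples on a 0..max_level scale mapping to ``category``.

    Enumerates the full level cube, so it is exact by construction; used by
    the simulator to draw truth triples consistent with a target category.
    """
    if max_level < 2:
        raise ValueError("max_level must be >= 2 to represent all states")
    rng = range(max_level + 1)
    return [
        (a, h, e)
        for a in rng
        for h in rng
        for e in rng
        if classify_unit((a, h, e), delta=delta, max_level=max_level) is category
    ]
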