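"""Summary statistics over classified units.

Turns per-unit categories into the tables a three-taxon AFLP profiling
study reports: per-category tallies and percentages, group roll-ups
(additivity / A- and E-expression-level dominance / transgressive up and
down), subgenome contribution totals, novel-expression and silencing sums
per taxon, and functional-class percentage tables.

All percentages are over the differential units only (no-change units are
mid-parent and excluded from denominators) and are rounded half-up to one
decimal, the convention the source tables use; roll-ups computed by summing
rounded components can therefore differ from the same roll-up computed on
raw counts by one unit in the last decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from polyexpress.classify import (
    Category,
    CategoryGroup,
    DIFFERENTIAL_CATEGORIES,
    dominance_direction,
    DominanceDirection,
    group_of,
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategoryTally:
    """Counts of units per category, with percentage accessors."""

    counts: dict[Category, int]
    n_no_change: int = 0

    def __post_init__(self) -> None:
        for c in DIFFERENTIAL_CATEGORIES:
            self.counts.setdefault(c, 0)
        if any(v < 0 for v in self.counts.values()) or self.n_no_change < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_differential(self) -> int:
        return sum(self.counts[c] for c in DIFFERENTIAL_CATEGORIES)

    def percentage(self, category: Category) -> float:
        """Category percentage of differential units, half-up to 1 decimal."""
        n = self.n_differential
        if n == 0:
            raise ZeroDivisionError("no differential units tallied")
        return round_half_up(100.0 * self.counts[category] / n)

    def group_count(self, group: CategoryGroup) -> int:
        if group is CategoryGroup.NO_CHANGE:
            return self.n_no_change
        return sum(
            self.counts[c] for c in DIFFERENTIAL_CATEGORIES if group_of(c) is group
        )

    def group_percentage(self, group: CategoryGroup) -> float:
        """Group percentage from the summed group count (not summed decimals)."""
        n = self.n_differential
        if n == 0:
            raise ZeroDivisionError("no differential units tallied")
        return round_half_up(100.0 * self.group_count(group) / n)

    def category_percentages(self) -> dict[Category, float]:
        return {c: self.percentage(c) for c in DIFFERENTIAL_CATEGORIES}


def tally(categories: Iterable[Category]) -> CategoryTally:
    """Count categories; NO_CHANGE is tracked separately from the 12 states."""
    counts = {c: 0 for c in DIFFERENTIAL_CATEGORIES}
    n_no_change = 0
    for cat in categories:
        if cat is Category.NO_CHANGE:
            n_no_change += 1
        else:
            counts[cat] += 1
    return CategoryTally(counts=counts, n_no_change=n_no_change)


#: Subgenome attribution of the two additivity categories: the state with the
#: A parent as the high parent (I) is attributed to the A subgenome, its
#: mirror (XII) to the E subgenome.  Exposed so the attribution can be
#: swapped or re-weighted.
ADDITIVITY_ATTRIBUTION: dict[str, Category] = {"A": Category.I, "E": Category.XII}


@dataclass(frozen=True)
class ContributionReport:
    """Subgenome contributions to hybrid expression, in rounded percentages.

    Fields are sums of per-category rounded percentages (printed-table
    arithmetic), so each roll-up reproduces the arithmetic of the published
    convention rather than re-dividing raw counts.
    """

    additivity_pct_A: float
    additivity_pct_E: float
    dominance_pct_A: float
    dominance_pct_E: float
    dominance_expressed_pct: float
    dominance_silent_pct: float
    up_pct: float
    down_pct: float

    @property
    def additivity_total(self) -> float:
        return round_half_up(self.additivity_pct_A + self.additivity_pct_E)

    @property
    def dominance_total(self) -> float:
        return round_half_up(self.dominance_pct_A + self.dominance_pct_E)

    @property
    def contribution_A(self) -> float:
        return round_half_up(self.additivity_pct_A + self.dominance_pct_A)

    @property
    def contribution_E(self) -> float:
        return round_half_up(self.additivity_pct_E + self.dominance_pct_E)

    @property
    def additivity_dominance_total(self) -> float:
        return round_half_up(self.contribution_A + self.contribution_E)

    @property
    def transgressive_total(self) -> float:
        return round_half_up(self.up_pct + self.down_pct)


def contributions(tally: CategoryTally) -> ContributionReport:
    """Roll a tally up into subgenome contribution percentages."""
    if tally.n_differential == 0:
        raise ZeroDivisionError("no differential units tallied")
    pct = tally.category_percentages()

    def s(cats: Sequence[Category]) -> float:
        return round_half_up(sum(pct[c] for c in cats))

    return ContributionReport(
        additivity_pct_A=pct[ADDITIVITY_ATTRIBUTION["A"]],
        additivity_pct_E=pct[ADDITIVITY_ATTRIBUTION["E"]],
        dominance_pct_A=s([Category.IV, Category.IX]),
        dominance_pct_E=s([Category.II, Category.XI]),
        dominance_expressed_pct=s(
            [c for c in DIFFERENTIAL_CATEGORIES
             if dominance_direction(c) is DominanceDirection.EXPRESSED]
        ),
        dominance_silent_pct=s(
            [c for c in DIFFERENTIAL_CATEGORIES
             if dominance_direction(c) is DominanceDirection.SILENT]
        ),
        up_pct=s([Category.V, Category.VI, Category.VIII]),
        down_pct=s([Category.III, Category.VII, Category.X]),
    )


@dataclass(frozen=True)
class NovelSilencingRow:
    """One taxon row of the novel-expression / silencing summary."""

    taxon: str
    novel_pct: float
    silencing_A_pct: float
    silencing_E_pct: float
    components: dict[str, tuple[float, ...]] = field(hash=False, default_factory=dict)


#: Which categories compose each cell of the per-taxon novel/silencing
#: summary.  In the parents, "novel" is expression the hybrid shares with
#: that parent alone (the expressed-dominance state) and "silencing" the
#: matching silent-dominance state; in the hybrid the novel column sums the
#: transgressive-up states and each silencing column sums the states in
#: which the respective subgenome's copy is off in the hybrid.
DEFAULT_NOVEL_SILENCING_COMPOSITION: dict[tuple[str, str], tuple[Category, ...]] = {
    ("GA", "novel"): (Category.IV,),
    ("GA", "silencing_A"): (Category.IX,),
    ("GA", "silencing_E"): (Category.IV,),
    ("GS", "novel"): (Category.II,),
    ("GS", "silencing_A"): (Category.II,),
    ("GS", "silencing_E"): (Category.XI,),
    ("AS", "novel"): (Category.VIII, Category.V, Category.VI),
    ("AS", "silencing_A"): (Category.IX, Category.II, Category.VII, Category.VIII),
    ("AS", "silencing_E"): (Category.IV, Category.XI, Category.II, Category.VIII),
}


def novel_silencing_report(
    category_pcts: Mapping[Category, float],
    composition: Mapping[tuple[str, str], Sequence[Category]] | None = None,
) -> list[NovelSilencingRow]:
    """Per-taxon novel-expression and silencing sums from category percentages.

    Each cell is the 1-decimal sum of its composed category percentages; the
    composition map is configurable because the per-taxon cell semantics are
    a convention, not a computation on the band matrix.
    """
    comp = dict(composition) if composition is not None else dict(
        DEFAULT_NOVEL_SILENCING_COMPOSITION
    )
    for key, cats in comp.items():
        for c in cats:
            if c not in category_pcts:
                raise KeyError(
                    f"composition cell {key} references category {c} absent "
                    "from category_pcts"
                )

    def cell(taxon: str, col: str) -> tuple[float, tuple[float, ...]]:
        parts = tuple(float(category_pcts[c]) for c in comp[(taxon, col)])
        return round_half_up(sum(parts)), parts

    rows = []
    for taxon in ("GA", "GS", "AS"):
        novel, novel_parts = cell(taxon, "novel")
        sil_a, a_parts = cell(taxon, "silencing_A")
        sil_e, e_parts = cell(taxon, "silencing_E")
        rows.append(
            NovelSilencingRow(
                taxon=taxon,
                novel_pct=novel,
                silencing_A_pct=sil_a,
                silencing_E_pct=sil_e,
                components={
                    "novel": novel_parts,
                    "silencing_A": a_parts,
                    "silencing_E": e_parts,
                },
            )
        )
    return rows


@dataclass(frozen=True)
class FunctionalTable:
    """Counts and 1-decimal percentages of annotated functional classes."""

    class_counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.class_counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total <= 0:
            raise ZeroDivisionError("functional table has no entries")
        return {
            name: round_half_up(100.0 * n / total)
            for name, n in self.class_counts.items()
        }


def functional_percentages(class_counts: Mapping[str, int]) -> FunctionalTable:
    """Percentage per functional class, half-up to one decimal."""
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("class counts must be non-negative")
    return FunctionalTable(class_counts=dict(class_counts))


def report_dict(
    tally_: CategoryTally,
    include_novel_silencing: bool = True,
) -> dict:
    """Machine-readable summary of a tally (JSON-serialisable)."""
    contr = contributions(tally_)
    out = {
        "n_differential": tally_.n_differential,
        "n_no_change": tally_.n_no_change,
        "category_counts": {str(c): tally_.counts[c] for c in DIFFERENTIAL_CATEGORIES},
        "category_percentages": {
            str(c): tally_.percentage(c) for c in DIFFERENTIAL_CATEGORIES
        },
        "group_percentages": {
            g.value: tally_.group_percentage(g)
            for g in CategoryGroup
            if g is not CategoryGroup.NO_CHANGE
        },
        "contributions": {
            "additivity_pct_A": contr.additivity_pct_A,
            "additivity_pct_E": contr.additivity_pct_E,
            "dominance_pct_A": contr.dominance_pct_A,
            "dominance_pct_E": contr.dominance_pct_E,
            "dominance_expressed_pct": contr.dominance_expressed_pct,
            "dominance_silent_pct": contr.dominance_silent_pct,
            "up_pct": contr.up_pct,
            "down_pct": contr.down_pct,
            "contribution_A": contr.contribution_A,
            "contribution_E": contr.contribution_E,
            "additivity_dominance_total": contr.additivity_dominance_total,
            "transgressive_total": contr.transgressive_total,
        },
    }
    if include_novel_silencing:
        rows = novel_silencing_report(tally_.category_percentages())
        out["novel_silencing"] = [
            {
                "taxon": r.taxon,
                "novel_pct": r.novel_pct,
                "silencing_A_pct": r.silencing_A_pct,
                "silencing_E_pct": r.silencing_E_pct,
            }
            for r in rows
        ]
    return out
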