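"""Ground-truthed simulation of three-taxon band matrices and transcripts.

The generator emulates what a duplicate-scored cDNA-AFLP experiment on two
diploid parents and their somatic hybrid delivers to the analyst: a band
matrix of ordinal intensities with a known differential-expression category
behind every band, plus mid-parent ("no change") bands, replicate jitter and
band dropout.  The default study conditions follow the profiling experiment
the package models: 2240 differential units, ~1000 no-change units scored in
duplicate on a 0-3 intensity scale, with the differential units distributed
over the 12 states so that the group totals are additivity 10.7%,
A-dominance 23.8%, E-dominance 21.2%, transgressive up 24.6% and
transgressive down 19.7%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from polyexpress.band_matrix import BandMatrix, TAXA
from polyexpress.classify import (
    Category,
    DIFFERENTIAL_CATEGORIES,
    category_levels,
)

#: Default per-category unit counts out of 2240 differential units.  Within
#: each group the split follows the published per-category percentages where
#: they are arithmetically consistent with the group total; the remainder of
#: the transgressive-up group (after the acquired-expression state VIII) is
#: split between V and VI in the published ratio.
DEFAULT_CATEGORY_COUNTS: dict[Category, int] = {
    Category.I: 115,    # additivity, A parent high           (5.1%)
    Category.XII: 124,  # additivity, E parent high           (5.5%)
    Category.IV: 181,   # A-dominance, expressed              (8.1%)
    Category.IX: 352,   # A-dominance, silent                 (15.7%)
    Category.II: 103,   # E-dominance, expressed              (4.6%)
    Category.XI: 371,   # E-dominance, silent                 (16.6%)
    Category.V: 124,    # transgressive up, A parent high     (5.5%)
    Category.VI: 85,    # transgressive up, E parent high     (3.8%)
    Category.VIII: 343, # acquired expression                 (15.3%)
    Category.III: 193,  # transgressive down, A parent high   (8.6%)
    Category.VII: 105,  # silenced, parents equal             (4.7%)
    Category.X: 144,    # transgressive down, E parent high   (6.4%)
}

DEFAULT_N_UNITS = sum(DEFAULT_CATEGORY_COUNTS.values())  # 2240

DEFAULT_CATEGORY_PROPORTIONS: dict[Category, float] = {
    c: n / DEFAULT_N_UNITS for c, n in DEFAULT_CATEGORY_COUNTS.items()
}


class SimulationConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated profiling experiment.

    Parameters
    ----------
    n_units
        Number of differential units (band positions that differ among the
        three taxa).
    n_no_change
        Number of mid-parent units (all three taxa equal), excluded from
        percentage denominators downstream but present on the gel.
    category_proportions
        Multinomial weights over the 12 differential states; must cover all
        12 and sum to 1.
    intensity_levels
        Intensity-scale maximum L (levels 0..L); L >= 3 is required so that
        additivity, dominance and transgression can coexist.
    dropout_rate
        Per-replicate probability that a positive band is missed (scored 0).
    intensity_jitter_sd
        SD of Gaussian noise added to the true level before re-rounding,
        on the level scale.
    n_replicates
        Gel replicates per taxon.
    allocation
        "multinomial": category counts drawn multinomially (sampling noise
        included); "exact": largest-remainder rounding of the proportions,
        for noise-free reproduction of a target composition.
    seed
        Seed for all randomness in the simulation.
    """

    n_units: int = DEFAULT_N_UNITS
    n_no_change: int = 1000
    category_proportions: dict[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROPORTIONS)
    )
    intensity_levels: int = 3
    dropout_rate: float = 0.02
    intensity_jitter_sd: float = 0.3
    n_replicates: int = 2
    allocation: str = "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 0 or self.n_no_change < 0:
            raise SimulationConfigError("unit counts must be non-negative")
        missing = set(DIFFERENTIAL_CATEGORIES) - set(self.category_proportions)
        if missing:
            raise SimulationConfigError(
                f"category_proportions missing {sorted(str(c) for c in missing)}"
            )
        total = sum(self.category_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SimulationConfigError(
                f"category_proportions sum to {total}, expected 1"
            )
        if any(p < 0 for p in self.category_proportions.values()):
            raise SimulationConfigError("proportions must be non-negative")
        if self.intensity_levels < 3:
            raise SimulationConfigError(
                "intensity_levels must be >= 3 (additivity needs an "
                "intermediate level)"
            )
        if not 0 <= self.dropout_rate < 1:
            raise SimulationConfigError("dropout_rate must be in [0, 1)")
        if self.intensity_jitter_sd < 0:
            raise SimulationConfigError("intensity_jitter_sd must be >= 0")
        if self.n_replicates < 1:
            raise SimulationConfigError("n_replicates must be >= 1")
        if self.allocation not in ("multinomial", "exact"):
            raise SimulationConfigError(
                "allocation must be 'multinomial' or 'exact'"
            )

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """True state of one simulated unit."""

    unit_id: tuple[str, int]
    true_category: Category
    true_levels: tuple[int, int, int]


def _exact_allocation(proportions: Sequence[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n units over the proportions."""
    raw = [p * n for p in proportions]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    by_remainder = sorted(
        range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in by_remainder[:short]:
        counts[i] += 1
    return counts


# Band keys are laid out as pseudo primer combinations of up to 500 bands
# each, with sizes descending from 599 bp (gel order).
_BANDS_PER_COMBINATION = 500
_TOP_SIZE = 599


def _band_key(i: int) -> tuple[str, int]:
    return (
        f"PC{i // _BANDS_PER_COMBINATION + 1:03d}",
        _TOP_SIZE - (i % _BANDS_PER_COMBINATION),
    )


def assign_category_profiles(config: SimulationConfig) -> list[GroundTruth]:
    """Draw the true category and level triple of every simulated unit.

    Differential units are allocated to categories per the configured
    proportions (multinomially or exactly), and each unit's (a, h, e) triple
    is sampled uniformly among the level triples consistent with its
    category on the configured intensity scale.  No-change units get a
    shared positive level in all three taxa.  Reproducible under the seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.intensity_levels
    cats = list(DIFFERENTIAL_CATEGORIES)
    props = [config.category_proportions[c] for c in cats]
    if config.allocation == "multinomial":
        counts = rng.multinomial(config.n_units, props).tolist()
    else:
        counts = _exact_allocation(props, config.n_units)
    triples_by_cat = {c: category_levels(c, L) for c in cats}
    truth: list[GroundTruth] = []
    i = 0
    for cat, k in zip(cats, counts):
        choices = triples_by_cat[cat]
        idx = rng.integers(0, len(choices), size=k)
        for j in idx:
            truth.append(GroundTruth(_band_key(i), cat, choices[int(j)]))
            i += 1
    # no-change units: a visible band at the same level in all three taxa
    levels = rng.integers(1, L + 1, size=config.n_no_change)
    for v in levels:
        truth.append(
            GroundTruth(_band_key(i), Category.NO_CHANGE, (int(v),) * 3)
        )
        i += 1
    return truth


def simulate_band_matrix(
    truth: Sequence[GroundTruth], config: SimulationConfig
) -> BandMatrix:
    """Score the gel: jittered, dropout-afflicted replicate lanes per taxon.

    For each unit, taxon and replicate the observed intensity is
    ``clamp(round(true + N(0, jitter)), 0, L)``; every positive observation
    is then independently zeroed with probability ``dropout_rate``.
    Replicates share the true levels.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.intensity_levels
    n = len(truth)
    true_levels = np.array([t.true_levels for t in truth], dtype=float)  # n x 3
    lanes: dict[str, np.ndarray] = {}
    for ti, taxon in enumerate(TAXA_ORDER):
        for rep in range(1, config.n_replicates + 1):
            x = true_levels[:, ti]
            if config.intensity_jitter_sd > 0:
                x = x + rng.normal(0.0, config.intensity_jitter_sd, size=n)
            obs = np.clip(np.floor(x + 0.5), 0, L).astype(int)
            if config.dropout_rate > 0:
                drop = rng.random(n) < config.dropout_rate
                obs = np.where(drop & (obs > 0), 0, obs)
            lanes[f"{taxon}.{rep}"] = obs
    keys = [t.unit_id for t in truth]
    return BandMatrix.from_lanes(keys, lanes, max_level=L)


#: Taxon order used to map the (a, h, e) truth triple onto lanes.
TAXA_ORDER = TAXA  # ("GA", "AS", "GS") = (A parent, hybrid, E parent)


def generate_transcripts(
    n: int, length_mean: int = 1000, gc: float = 0.5, seed: int = 0
) -> list[SeqRecord]:
    """Random transcript set with i.i.d. bases at a given GC fraction.

    A deliberately minimal null model for exercising the in-silico AFLP
    engine; it carries no codon structure or homology.
    """
    if n < 0:
        raise SimulationConfigError("n must be non-negative")
    if not 0 < gc < 1:
        raise SimulationConfigError("gc must be in (0, 1)")
    if length_mean < 1:
        raise SimulationConfigError("length_mean must be >= 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    records = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), size=length_mean, p=p))
        records.append(
            SeqRecord(Seq(seq), id=f"synthetic_tx_{i + 1:04d}", description="")
        )
    return records


def truth_to_rows(truth: Sequence[GroundTruth]) -> list[dict]:
    """Flatten ground truth into TSV-ready rows."""
    return [
        {
            "primer_combination": t.unit_id[0],
            "size_bp": t.unit_id[1],
            "true_category": str(t.true_category),
            "GA": t.true_levels[0],
            "AS": t.true_levels[1],
            "GS": t.true_levels[2],
        }
        for t in truth
    ]
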