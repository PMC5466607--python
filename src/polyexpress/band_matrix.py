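"""Three-taxon band matrices: TSV I/O and replicate reconciliation.

A band matrix scores every band position (one primer combination x one gel
size) across the lanes of the A-genome parent (GA), the somatic hybrid (AS)
and the E-genome parent (GS), with one or more gel replicates per taxon.
Intensities are small ordinal integers (0 = absent).

TSV dialect: tab-separated, UTF-8, ``#`` comment lines; columns
``primer_combination``, ``size_bp``, then one column per lane named
``TAXON.replicate`` (``GA.1``, ``GA.2``, ``AS.1``, ...).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

TAXA = ("GA", "AS", "GS")

BandKey = tuple[str, int]


class ReconcileRule(enum.Enum):
    """How replicate lanes collapse to one level per taxon.

    ALL_PRESENT scores a taxon 0 unless the band is reproducible (present in
    every replicate), otherwise the rounded replicate mean — the conservative
    convention for silver-stained gels scored in duplicate.  MEAN_ROUND takes
    the rounded mean regardless.
    """

    ALL_PRESENT = "all_present"
    MEAN_ROUND = "mean_round"


@dataclass(frozen=True)
class Unit:
    """One band position reduced to a single (a, h, e) level triple."""

    unit_id: BandKey
    levels: tuple[int, int, int]  # (GA, AS, GS)


class BandMatrixError(ValueError):
    """Malformed band-matrix table."""


def _parse_lane(label: str) -> tuple[str, int]:
    taxon, dot, rep = label.partition(".")
    if taxon not in TAXA or not dot:
        raise BandMatrixError(
            f"unknown lane label {label!r}; expected TAXON.replicate with "
            f"TAXON in {TAXA}"
        )
    try:
        r = int(rep)
    except ValueError:
        raise BandMatrixError(f"non-integer replicate in lane label {label!r}")
    if r < 1:
        raise BandMatrixError(f"replicate index must be >= 1 in {label!r}")
    return taxon, r


class BandMatrix:
    """Band intensities keyed by (primer_combination, size_bp) per lane.

    Thin wrapper over a pandas DataFrame whose index is the band key and
    whose columns are lane labels ``TAXON.replicate``; all lanes are shared
    by all bands (a rectangular gel-score table).
    """

    def __init__(self, data: pd.DataFrame, max_level: int = 3):
        lanes = [_parse_lane(c) for c in data.columns]
        taxa = {t for t, _ in lanes}
        if taxa != set(TAXA):
            missing = set(TAXA) - taxa
            raise BandMatrixError(f"missing taxa in lane set: {sorted(missing)}")
        reps_per_taxon = {t: sorted(r for tt, r in lanes if tt == t) for t in TAXA}
        n_reps = {t: len(v) for t, v in reps_per_taxon.items()}
        if len(set(n_reps.values())) != 1:
            raise BandMatrixError(
                f"unequal replicate counts across taxa: {n_reps}"
            )
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise BandMatrixError(f"duplicate band key {dup}")
        vals = data.to_numpy()
        if vals.size and (
            not pd.api.types.is_integer_dtype(data.dtypes.iloc[0])
            or any(not pd.api.types.is_integer_dtype(d) for d in data.dtypes)
        ):
            raise BandMatrixError("intensities must be integers")
        if vals.size and (vals.min() < 0 or vals.max() > max_level):
            raise BandMatrixError(
                f"intensities outside [0, {max_level}]"
            )
        self._df = data
        self.max_level = max_level
        self.replicates = reps_per_taxon

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def n_replicates(self) -> int:
        return len(self.replicates[TAXA[0]])

    def band_keys(self) -> list[BandKey]:
        return [(str(pc), int(sz)) for pc, sz in self._df.index]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BandMatrix) and self._df.equals(other._df)

    @classmethod
    def from_lanes(
        cls,
        keys: Sequence[BandKey],
        lanes: dict[str, Sequence[int]],
        max_level: int = 3,
    ) -> "BandMatrix":
        index = pd.MultiIndex.from_tuples(keys, names=["primer_combination", "size_bp"])
        df = pd.DataFrame(lanes, index=index, dtype=int)
        return cls(df, max_level=max_level)


def read_band_tsv(path, max_level: int = 3) -> BandMatrix:
    """Read a band-matrix TSV (see module docstring for the dialect).

    Raises BandMatrixError naming the offending row for non-integer
    intensities, duplicate band keys or unknown lane labels.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["primer_combination", "size_bp"]
    if list(df.columns[:2]) != required:
        raise BandMatrixError(
            f"first columns must be {required}, got {list(df.columns[:2])}"
        )
    lane_cols = list(df.columns[2:])
    if not lane_cols:
        raise BandMatrixError("no lane columns found")
    for col in ["size_bp", *lane_cols]:
        for i, v in enumerate(df[col]):
            try:
                int(v)
            except (TypeError, ValueError):
                raise BandMatrixError(
                    f"non-integer value {v!r} in column {col}, row {i + 2}"
                )
        df[col] = df[col].astype(int)
    dup = df.duplicated(subset=required)
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise BandMatrixError(f"duplicate band key at row {row}")
    df = df.set_index(required)
    df.index = pd.MultiIndex.from_tuples(
        [(str(pc), int(sz)) for pc, sz in df.index], names=required
    )
    return BandMatrix(df, max_level=max_level)


def write_band_tsv(matrix: BandMatrix, path) -> None:
    """Write a band matrix in the TSV dialect read by :func:`read_band_tsv`."""
    df = matrix.frame.reset_index()
    df.to_csv(path, sep="\t", index=False)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def reconcile_replicates(
    matrix: BandMatrix,
    rule: ReconcileRule = ReconcileRule.ALL_PRESENT,
) -> list[Unit]:
    """Collapse replicate lanes into one Unit per band position.

    Units are ordered by primer combination (ascending) then band size
    (descending, i.e. top-of-gel first).  On a single-replicate matrix both
    rules are the identity.
    """
    df = matrix.frame
    per_taxon = {}
    for taxon in TAXA:
        cols = [f"{taxon}.{r}" for r in matrix.replicates[taxon]]
        sub = df[cols]
        mean = sub.mean(axis=1)
        rounded = mean.map(_round_half_up)
        if rule is ReconcileRule.ALL_PRESENT:
            present = (sub > 0).all(axis=1)
            rounded = rounded.where(present, 0)
        per_taxon[taxon] = rounded.astype(int)
    order = sorted(
        range(len(df)),
        key=lambda i: (df.index[i][0], -int(df.index[i][1])),
    )
    units = []
    for i in order:
        pc, sz = df.index[i]
        units.append(
            Unit(
                unit_id=(str(pc), int(sz)),
                levels=(
                    int(per_taxon["GA"].iloc[i]),
                    int(per_taxon["AS"].iloc[i]),
                    int(per_taxon["GS"].iloc[i]),
                ),
            )
        )
    return units


def units_to_frame(units: Iterable[Unit]) -> pd.DataFrame:
    """Tabulate units as a DataFrame with GA/AS/GS level columns."""
    rows = [
        {
            "primer_combination": u.unit_id[0],
            "size_bp": u.unit_id[1],
            "GA": u.levels[0],
            "AS": u.levels[1],
            "GS": u.levels[2],
        }
        for u in units
    ]
    return pd.DataFrame(
        rows, columns=["primer_combination", "size_bp", "GA", "AS", "GS"]
    )
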