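"""Relative expression by the comparative-Ct (2^-ddCt) method.

Each target gene's mean Ct is normalised to a reference gene within the
same sample (dCt), then to a calibrator sample (ddCt); relative expression
is 2^-ddCt.  Replicate Ct values are averaged arithmetically before
differencing and no amplification-efficiency correction is applied (the
classic Livak convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


class CtTableError(ValueError):
    """Malformed or incomplete Ct table."""


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in one sample vs the calibrator."""

    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


def read_ct_tsv(path) -> pd.DataFrame:
    """Read a Ct table (columns sample, gene, replicate, ct; '#' comments)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise CtTableError(f"Ct table missing columns {missing}")
    return validate_ct_table(df)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    df = table[CT_COLUMNS].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    if (df["ct"] <= 0).any():
        bad = df.loc[df["ct"] <= 0].iloc[0]
        raise CtTableError(
            f"non-positive Ct {bad['ct']} for sample={bad['sample']!r} "
            f"gene={bad['gene']!r}"
        )
    return df


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    calibrator_sample: str,
) -> list[FoldChange]:
    """Per-sample fold changes of ``gene`` relative to the calibrator sample.

    dCt(sample) = mean Ct(gene) - mean Ct(reference);
    ddCt(sample) = dCt(sample) - dCt(calibrator); fold = 2^-ddCt.
    The calibrator's fold is exactly 1 by construction, and fold ratios
    between samples do not depend on which sample is the calibrator.
    """
    df = validate_ct_table(table)
    mean_ct = df.groupby(["sample", "gene"])["ct"].mean()
    samples = [s for s in df["sample"].unique()]
    for g in (gene, reference_gene):
        if g not in set(df["gene"]):
            raise CtTableError(f"gene {g!r} absent from the Ct table")
    if calibrator_sample not in samples:
        raise CtTableError(f"calibrator sample {calibrator_sample!r} not found")

    def dct(sample: str) -> float:
        try:
            return float(mean_ct[(sample, gene)] - mean_ct[(sample, reference_gene)])
        except KeyError as err:
            raise CtTableError(
                f"sample {sample!r} lacks Ct values for {err.args[0]!r}"
            ) from None

    dct_cal = dct(calibrator_sample)
    out = []
    for sample in samples:
        if (sample, gene) not in mean_ct.index:
            continue
        d = dct(sample)
        dd = d - dct_cal
        out.append(
            FoldChange(
                sample=sample, gene=gene,
                delta_ct=d, delta_delta_ct=dd, fold=2.0 ** (-dd),
            )
        )
    return out


def fold_change_table(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_sample: str,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Fold changes for every target gene (all non-reference genes by default)."""
    df = validate_ct_table(table)
    if genes is None:
        genes = [g for g in df["gene"].unique() if g != reference_gene]
    rows = []
    for g in genes:
        for fc in delta_delta_ct(df, g, reference_gene, calibrator_sample):
            rows.append(
                {
                    "sample": fc.sample,
                    "gene": fc.gene,
                    "delta_ct": fc.delta_ct,
                    "delta_delta_ct": fc.delta_delta_ct,
                    "fold": fc.fold,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "gene", "delta_ct", "delta_delta_ct", "fold"])
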