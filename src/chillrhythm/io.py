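"""Readers and writers for the long-format TSV/CSV tables.

All tables are plain text with a header row; writers prepend provenance
comment lines (tool version and config hash) which readers skip.  Field
separator is inferred from the file extension (``.csv`` -> comma,
anything else -> tab).
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from ._util import config_hash
from .errors import SchemaError, ValidationError

EXPRESSION_COLUMNS = ("gene", "species", "condition", "time_h", "replicate",
                      "fpkm")
LIPID_COLUMNS = ("sample_id", "species", "condition", "time_h", "replicate",
                 "lipid_class", "fatty_acid", "amount")
PAIR_COLUMNS = ("gene_a", "gene_b")

EXPRESSION_KEY = ["gene", "species", "condition", "time_h", "replicate"]
LIPID_KEY = ["sample_id", "lipid_class", "fatty_acid"]


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) "
                          f"{sorted(missing)}")
    return df


def _check_duplicates(df: pd.DataFrame, key: list[str], path) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise ValidationError(f"{path}: duplicated key row(s), e.g. {first}")


def read_expression(path) -> pd.DataFrame:
    """Read a replicate-level FPKM table (gene, species, condition, time_h,
    replicate, fpkm); rejects missing columns, negative FPKM and duplicate
    keys."""
    df = _read(path, EXPRESSION_COLUMNS)
    neg = df.index[df["fpkm"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative FPKM at row {int(neg[0])}")
    _check_duplicates(df, EXPRESSION_KEY, path)
    return df


def read_lipids(path) -> pd.DataFrame:
    """Read a long-format lipid table; rejects negative amounts and
    duplicate (sample, class, fatty acid) rows."""
    df = _read(path, LIPID_COLUMNS)
    neg = df.index[df["amount"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative amount at row {int(neg[0])}")
    _check_duplicates(df, LIPID_KEY, path)
    return df


def read_pairs(path) -> pd.DataFrame:
    """Read the syntenic ortholog pair list (gene_a, gene_b); each gene may
    appear in at most one pair."""
    df = _read(path, PAIR_COLUMNS)
    for col in PAIR_COLUMNS:
        if df[col].duplicated().any():
            gene = df.loc[df[col].duplicated(), col].iloc[0]
            raise ValidationError(f"{path}: gene {gene!r} appears in more "
                                  "than one pair")
    return df


def write_table(df: pd.DataFrame, path, config=None,
                index: bool = False) -> None:
    """Write a table with provenance comment lines in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# chillrhythm {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, sep=_sep(path), index=index)
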