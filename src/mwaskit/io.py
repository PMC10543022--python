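"""Readers and writers for the pipeline's tab-delimited file formats.

Conventions: UTF-8 TSV, ``NA`` as the missing token on write; both empty
fields and ``NA`` are read back as missing.  Summary-statistics headers are
matched case-insensitively with a few common aliases.  All log output goes
to the module logger (stderr by default); files carry results only.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    AbundanceMatrix,
    SUMSTATS_COLUMNS,
    ValidationError,
    validate_annotation,
    validate_phenotypes,
    validate_sumstats,
)

logger = logging.getLogger("mwaskit")

_NA = "NA"
_READ_KW = dict(sep="\t", na_values=[_NA, ""], keep_default_na=False)
_WRITE_KW = dict(sep="\t", na_rep=_NA)

#: accepted aliases for summary-statistics columns (lower-cased)
_SUMSTATS_ALIASES = {
    "variant_id": {"variant_id", "snp", "rsid", "id", "markername"},
    "chr": {"chr", "chrom", "chromosome"},
    "pos": {"pos", "bp", "position", "base_pair_location"},
    "effect_allele": {"effect_allele", "a1", "ea", "allele1"},
    "other_allele": {"other_allele", "a2", "oa", "nea", "allele2"},
    "eaf": {"eaf", "freq", "af", "effect_allele_frequency", "maf"},
    "beta": {"beta", "b", "effect"},
    "se": {"se", "standard_error", "stderr"},
    "pvalue": {"pvalue", "p", "pval", "p_value"},
    "n": {"n", "samplesize", "n_total"},
}


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta" + path.suffix)


def read_abundance_matrix(path, meta_path=None, scale: str = "raw") -> AbundanceMatrix:
    """Read an abundance matrix TSV plus its per-sample metadata TSV.

    The matrix file has sample ids in the first column and metabolite ids in
    the header; the metadata file is keyed by sample id with
    batch/plate/run_day/wave/is_reference columns.  Empty cells and ``NA``
    become missing values.
    """
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    header = pd.read_csv(path, sep="\t", nrows=0)
    cols = list(header.columns[1:])
    seen: set[str] = set()
    for c in cols:
        base = c.split(".")[0] if c.split(".")[-1].isdigit() else c
        if base in seen:
            raise ValidationError(f"duplicated metabolite column {base!r} in {path}")
        seen.add(base)
    values = pd.read_csv(path, index_col=0, **_READ_KW)
    values.index = values.index.astype(str)
    values.index.name = None
    meta = pd.read_csv(meta_path, index_col=0, **_READ_KW)
    meta.index = meta.index.astype(str)
    meta.index.name = None
    if "is_reference" in meta.columns:
        meta["is_reference"] = meta["is_reference"].astype(bool)
    missing_meta = values.index.difference(meta.index)
    if len(missing_meta):
        raise ValidationError(
            f"metadata row missing for sample(s) {missing_meta[:5].tolist()} in {meta_path}"
        )
    return AbundanceMatrix(values, meta.loc[values.index], scale=scale)


def write_abundance_matrix(m: AbundanceMatrix, path, meta_path=None) -> None:
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _meta_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    m.values.to_csv(path, index_label="sample_id", **_WRITE_KW)
    m.sample_meta.to_csv(meta_path, index_label="sample_id", **_WRITE_KW)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    for c in ("ad_ssri", "ad_tca", "ad_snri"):
        if c in df.columns:
            df[c] = df[c].astype(bool)
    for c in ("subject_id", "family_id"):
        if c in df.columns:
            df[c] = df[c].astype(str)
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, **_WRITE_KW)


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, **_READ_KW))


def write_annotation(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, **_WRITE_KW)


def read_sumstats(path) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV with case-insensitive headers.

    Rows with non-positive standard errors are dropped with a logged count.
    A missing mandatory column raises :class:`ValidationError` listing all
    missing names.
    """
    df = pd.read_csv(path, **_READ_KW)
    rename: dict[str, str] = {}
    lower_used: set[str] = set()
    for col in df.columns:
        lc = str(col).strip().lower()
        for canonical, aliases in _SUMSTATS_ALIASES.items():
            if lc in aliases and canonical not in lower_used:
                rename[col] = canonical
                lower_used.add(canonical)
                break
    df = df.rename(columns=rename)
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing mandatory column(s) {missing}")
    df = df[list(SUMSTATS_COLUMNS)].copy()
    df["variant_id"] = df["variant_id"].astype(str)
    df["chr"] = df["chr"].astype(str)
    for c in ("eaf", "beta", "se", "pvalue"):
        df[c] = pd.to_numeric(df[c])
    bad = ~(df["se"] > 0)
    if bad.any():
        logger.warning("%s: dropped %d row(s) with se <= 0", path, int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return validate_sumstats(df)


def write_sumstats(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, **_WRITE_KW)


def read_association_table(path) -> pd.DataFrame:
    return pd.read_csv(path, **_READ_KW)


def write_association_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, **_WRITE_KW)


def read_ld_map(path) -> dict[frozenset, float]:
    """Read a pairwise LD table (variant_a, variant_b, r2) into a lookup."""
    df = pd.read_csv(path, **_READ_KW)
    return {
        frozenset((str(a), str(b))): float(r)
        for a, b, r in zip(df["variant_a"], df["variant_b"], df["r2"])
    }


def write_ld_map(ld: dict, path) -> None:
    rows = [{"variant_a": sorted(k)[0], "variant_b": sorted(k)[1], "r2": v} for k, v in ld.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"]).to_csv(
        path, index=False, **_WRITE_KW
    )


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Generic TSV writer with the package's NA conventions."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, **_WRITE_KW)


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col, **_READ_KW)
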