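"""Core in-memory containers for the pipeline.

The pipeline moves four kinds of tabular data around: an abundance matrix
with per-sample technical metadata, a phenotype/covariate table, a pathway
annotation table, and GWAS summary statistics.  All of them are pandas
DataFrames with a documented column contract; the abundance matrix gets a
small dataclass wrapper because its values and metadata must stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

WAVES = ("baseline", "follow-up-6y", "follow-up-9y")
MDD_LEVELS = ("control", "remitted", "current")
SMOKING_LEVELS = ("never", "ex", "current")
SCALES = ("raw", "normalized", "log2")

#: required columns of the per-sample technical metadata table
SAMPLE_META_COLUMNS = ("batch", "plate", "run_day", "wave", "is_reference")

#: required columns of the phenotype table
PHENOTYPE_COLUMNS = (
    "subject_id",
    "family_id",
    "wave",
    "mdd_status",
    "ids_total",
    "sex",
    "age",
    "education",
    "physical_activity",
    "smoking",
    "alcohol",
    "n_chronic_diseases",
    "bmi",
    "shipment",
    "ad_ssri",
    "ad_tca",
    "ad_snri",
)

#: required columns of a GWAS summary-statistics table
SUMSTATS_COLUMNS = (
    "variant_id",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

#: columns of a per-metabolite association result table
ASSOCIATION_COLUMNS = (
    "metabolite_id",
    "contrast",
    "model",
    "beta",
    "se",
    "pvalue",
    "qvalue",
    "n_used",
)


class ValidationError(ValueError):
    """Raised when a table violates its column/value contract."""


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundances with per-sample technical metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with metabolite ids as columns.
        Missing measurements are NaN (the missingness mask is ``values.isna()``).
    sample_meta
        DataFrame indexed by sample id with columns ``batch``, ``plate``,
        ``run_day``, ``wave`` and boolean ``is_reference``, one row per sample
        of ``values`` in the same order.
    scale
        One of ``raw`` (non-negative abundances), ``normalized``
        (median-scaled, still non-negative) or ``log2``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated metabolite ids: {dups}")
        missing_meta = [c for c in SAMPLE_META_COLUMNS if c not in self.sample_meta.columns]
        if missing_meta:
            raise ValidationError(f"sample_meta lacks columns: {missing_meta}")
        if not self.values.index.equals(self.sample_meta.index):
            extra = self.values.index.difference(self.sample_meta.index).tolist()
            raise ValidationError(
                f"sample_meta rows do not match value rows (no metadata for {extra[:5]} ...)"
            )
        for col in ("batch", "plate", "run_day", "wave"):
            if self.sample_meta[col].isna().any():
                bad = self.sample_meta.index[self.sample_meta[col].isna()][0]
                raise ValidationError(f"sample {bad!r} has no {col} label")
        if self.scale in ("raw", "normalized"):
            vals = self.values.to_numpy(dtype=float)
            neg = np.asarray((vals < 0) & ~np.isnan(vals)).nonzero()
            if neg[0].size:
                i, j = neg[0][0], neg[1][0]
                raise ValidationError(
                    f"negative {self.scale}-scale abundance at sample "
                    f"{self.values.index[i]!r}, metabolite {self.values.columns[j]!r}"
                )

    # -- convenience ------------------------------------------------------
    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask, True where a value is missing."""
        return self.values.isna()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def is_reference(self) -> pd.Series:
        return self.sample_meta["is_reference"].astype(bool)

    def experimental(self) -> "AbundanceMatrix":
        """Submatrix of experimental (non-reference) samples."""
        keep = ~self.is_reference()
        return self.subset_samples(self.values.index[keep])

    def references(self) -> "AbundanceMatrix":
        keep = self.is_reference()
        return self.subset_samples(self.values.index[keep])

    def subset_samples(self, ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.loc[ids], self.sample_meta.loc[ids], self.scale)

    def subset_metabolites(self, ids) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values[list(ids)], self.sample_meta, self.scale)

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values, self.sample_meta.loc[values.index], scale or self.scale)

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.values.copy(), self.sample_meta.copy(), self.scale)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check the phenotype-table contract and return the table unchanged."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks columns: {missing}")
    bad_status = set(df["mdd_status"].dropna().unique()) - set(MDD_LEVELS)
    if bad_status:
        raise ValidationError(f"unknown mdd_status levels: {sorted(bad_status)}")
    bad_smoke = set(df["smoking"].dropna().unique()) - set(SMOKING_LEVELS)
    if bad_smoke:
        raise ValidationError(f"unknown smoking levels: {sorted(bad_smoke)}")
    dup = df.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        pair = df.loc[dup, ["subject_id", "wave"]].iloc[0].tolist()
        raise ValidationError(f"duplicate phenotype record for subject/wave {pair}")
    base = df[df["wave"] == "baseline"]
    if base["family_id"].isna().any():
        sid = base.loc[base["family_id"].isna(), "subject_id"].iloc[0]
        raise ValidationError(f"baseline record without family_id (subject {sid!r})")
    return df


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    """Check the pathway-annotation contract (sub pathway implies super pathway)."""
    for col in ("metabolite_id", "super_pathway", "sub_pathway"):
        if col not in df.columns:
            raise ValidationError(f"annotation table lacks column {col!r}")
    bad = df["sub_pathway"].notna() & df["super_pathway"].isna()
    if bad.any():
        mid = df.loc[bad, "metabolite_id"].iloc[0]
        raise ValidationError(f"metabolite {mid!r} has a sub_pathway but no super_pathway")
    return df


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"summary statistics lack columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValidationError("summary statistics contain se <= 0")
    if ((df["eaf"] < 0) | (df["eaf"] > 1)).any():
        raise ValidationError("eaf outside [0, 1]")
    return df


@dataclass
class QcStep:
    """Record of one QC stage: counts before/after plus exclusions with reasons."""

    name: str
    n_samples_before: int
    n_samples_after: int
    n_metabolites_before: int
    n_metabolites_after: int
    excluded: dict[str, str] = field(default_factory=dict)
    info: dict = field(default_factory=dict)


@dataclass
class QcReport:
    """Accumulated per-step QC records plus per-metabolite diagnostics."""

    steps: list[QcStep] = field(default_factory=list)
    technical_cv: pd.Series | None = None
    wave_missingness_p: pd.Series | None = None
    masked_plates: list[tuple[str, str]] = field(default_factory=list)

    def add(self, step: QcStep) -> None:
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": s.name,
                "n_samples_before": s.n_samples_before,
                "n_samples_after": s.n_samples_after,
                "n_metabolites_before": s.n_metabolites_before,
                "n_metabolites_after": s.n_metabolites_after,
                "n_excluded": len(s.excluded),
            }
            for s in self.steps
        ]
        return pd.DataFrame(rows)

    def exclusions(self) -> pd.DataFrame:
        rows = [
            {"step": s.name, "identifier": k, "reason": v}
            for s in self.steps
            for k, v in s.excluded.items()
        ]
        return pd.DataFrame(rows, columns=["step", "identifier", "reason"])


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``assoc_effects`` and ``ad_effects`` are per-metabolite signed effect
    sizes in within-metabolite log2-SD units (non-zero only for truly
    affected metabolites); ``liability`` is the latent depression liability
    per subject; technical parameters are the multiplicative factors and
    per-metabolite technical CVs the generator used.
    """

    assoc_effects: pd.Series
    ad_effects: pd.Series
    liability: pd.Series
    family_liability_corr: float
    technical_cv: pd.Series
    runday_factors: pd.Series
    batch_factors: pd.Series
    log2_sd: pd.Series


@dataclass
class MrTruth:
    """Ground truth of simulated GWAS summary statistics."""

    theta: pd.Series  # per-metabolite causal effect on the outcome
    pleiotropy: pd.Series  # per-SNP direct effect on the outcome
    true_beta_exposure: pd.Series  # per-SNP true exposure effect


__all__ = [
    "AbundanceMatrix",
    "QcStep",
    "QcReport",
    "CohortTruth",
    "MrTruth",
    "ValidationError",
    "validate_phenotypes",
    "validate_annotation",
    "validate_sumstats",
    "WAVES",
    "MDD_LEVELS",
    "SMOKING_LEVELS",
    "PHENOTYPE_COLUMNS",
    "SUMSTATS_COLUMNS",
    "ASSOCIATION_COLUMNS",
    "SAMPLE_META_COLUMNS",
    "replace",
]
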