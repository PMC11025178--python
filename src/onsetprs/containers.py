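"""Core in-memory containers shared across the pipeline stages.

The containers are thin, validated wrappers around numpy arrays and pandas
DataFrames: a :class:`GenotypeMatrix` (samples x variants effect-allele
dosages), a :class:`SurvivalCohort` (entry/exit ages on the age timescale,
event indicator, covariates), a :class:`PRSModel` (ordered variant weights
with provenance), and the tabular schema for per-variant association
summaries ("sumstats").

Dosages are stored as float with NaN marking missing calls; observed values
are 0, 1 or 2 copies of the effect allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ValidationError

#: Column order for variant association summary tables.
SUMSTATS_COLUMNS = [
    "variant_id", "chr", "pos", "ea", "oa",
    "eaf", "beta", "se", "p", "n", "converged",
]

#: Required columns of a survival cohort table.
COHORT_COLUMNS = ["sample_id", "entry_age", "exit_age", "event", "fh"]

VARIANT_COLUMNS = ["variant_id", "chr", "pos", "ea", "oa"]


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with variant metadata.

    Parameters
    ----------
    dosages : ndarray, shape (n_samples, n_variants)
        Float array with values in {0, 1, 2} and NaN for missing calls.
    variants : DataFrame
        One row per variant with columns ``variant_id, chr, pos, ea, oa``.
    samples : list of str
        Ordered sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = list(self.samples)
        self.validate()

    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ValidationError(
                f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise ValidationError(
                f"{len(self.variants)} variant rows for {m} dosage columns")
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants]
        if missing_cols:
            raise ValidationError(f"variant table lacks columns {missing_cols}")
        if self.variants["variant_id"].duplicated().any():
            dups = self.variants.loc[
                self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValidationError(f"duplicate variant ids: {list(dups[:5])}")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must be in {0,1,2} or NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, variant_id: str) -> int:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in matrix")
        return int(idx[0])

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def eaf(self) -> np.ndarray:
        """Effect-allele frequency per variant over non-missing calls.

        NaN for variants with no observed calls.
        """
        obs = ~np.isnan(self.dosages)
        count = obs.sum(axis=0).astype(float)
        total = np.where(obs, self.dosages, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(count > 0, total / (2.0 * count), np.nan)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset by boolean mask or integer positions (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.dosages[:, keep],
            self.variants.iloc[keep].reset_index(drop=True),
            self.samples,
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.dosages[keep, :],
            self.variants,
            [self.samples[i] for i in keep],
        )


@dataclass
class SurvivalCohort:
    """Per-sample follow-up table on the age timescale.

    ``exit_age`` is the age at event (diagnosis) when ``event == 1`` and the
    censoring age otherwise; ``entry_age`` is the age at enrolment (left
    truncation). ``fh`` is binary family history (NaN allowed). Any further
    numeric columns named in ``covariates`` are adjustment covariates.
    """

    table: pd.DataFrame
    covariates: list[str] = field(default_factory=list)
    label: str = "General"

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.table]
        if missing:
            raise ValidationError(f"cohort table lacks columns {missing}")
        missing_cov = [c for c in self.covariates if c not in self.table]
        if missing_cov:
            raise ValidationError(f"covariate columns absent: {missing_cov}")
        if len(self.table) == 0:
            return
        if not (self.table["exit_age"] > self.table["entry_age"]).all():
            bad = (self.table["exit_age"] <= self.table["entry_age"]).sum()
            raise ValidationError(f"{bad} rows with exit_age <= entry_age")
        ev = self.table["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event must be 0/1")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    def subset(self, mask: np.ndarray, label: str | None = None) -> "SurvivalCohort":
        return SurvivalCohort(
            self.table.loc[np.asarray(mask)].reset_index(drop=True),
            covariates=list(self.covariates),
            label=self.label if label is None else label,
        )


@dataclass
class PRSModel:
    """Ordered list of (variant, effect allele, weight) defining a score.

    ``entries`` columns: ``variant_id, chr, pos, effect_allele, other_allele,
    weight, provenance`` where provenance is one of ``reported``, ``gwas``,
    ``merged-replaced``. Weights are log odds or log hazard ratios.
    """

    entries: pd.DataFrame
    name: str = "PRS"

    REQUIRED = ["variant_id", "effect_allele", "weight"]

    def __post_init__(self):
        self.entries = self.entries.reset_index(drop=True)
        missing = [c for c in self.REQUIRED if c not in self.entries]
        if missing:
            raise ValidationError(f"PRS model lacks columns {missing}")
        if "provenance" not in self.entries:
            self.entries["provenance"] = "gwas"
        if self.entries["variant_id"].duplicated().any():
            raise ValidationError("duplicate variant ids in PRS model")
        w = self.entries["weight"].to_numpy(dtype=float)
        if not np.isfinite(w).all():
            raise ValidationError("non-finite PRS weights")

    def __len__(self) -> int:
        return len(self.entries)


def empty_sumstats() -> pd.DataFrame:
    return pd.DataFrame(columns=SUMSTATS_COLUMNS)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check a sumstats table against the shared schema and return it."""
    if len(df) == 0 and len(df.columns) == 0:
        raise EmptyInputError("empty summary-statistics table")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"sumstats table lacks columns {missing}")
    ok = df["converged"].astype(bool)
    se = df.loc[ok, "se"].to_numpy(dtype=float)
    if (se <= 0).any():
        raise ValidationError("non-positive SE among converged rows")
    p = df.loc[ok, "p"].to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p-values outside (0, 1]")
    return df
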