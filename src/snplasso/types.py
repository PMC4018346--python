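"""Core data containers shared across the pipeline.

Two first-class objects travel between stages: :class:`GenotypeMatrix`
(samples x SNPs minor-allele dosages with a missingness mask encoded as
NaN) and :class:`CohortTable` (per-sample phenotype and covariates).
Category enumerations are fixed here so that every module validates
against the same vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AGE_GROUPS: tuple[str, ...] = ("<55", "55-64", "65-69", "70-74", "75+")
GENDERS: tuple[str, ...] = ("male", "female")
REGIONS: tuple[str, ...] = ("barcelona", "valles", "elche", "tenerife", "asturias")
SMOKING_LEVELS: tuple[str, ...] = ("never", "occasional", "former", "current")
SMOKING_WITH_MISSING: tuple[str, ...] = SMOKING_LEVELS + ("missing",)
SUBPHENOTYPES: tuple[str, ...] = ("control", "lowNMIT", "highNMIT", "MIT", "unknown")
P53_CLASSES: tuple[str, ...] = ("low", "high", "unknown")
STATUSES: tuple[str, ...] = ("control", "case")

#: Columns of a serialized CohortTable, in order.
COHORT_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "status",
    "subphenotype",
    "p53_class",
    "age_group",
    "gender",
    "region",
    "smoking",
)


class ValidationError(ValueError):
    """Raised when a container violates its declared invariants."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix.

    Parameters
    ----------
    sample_ids, snp_ids:
        Unique row / column identifiers.
    dosage:
        Float array of shape ``(n_samples, n_snps)`` with values in
        ``{0, 1, 2}``; missing genotypes are ``NaN``.
    gene_of:
        Map from SNP id to gene label.
    allele_labels:
        Map from SNP id to ``(major, minor)`` allele letters.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    gene_of: dict[str, str] = field(default_factory=dict)
    allele_labels: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n, p = self.dosage.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != p:
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if len(set(self.snp_ids)) != p:
            raise ValidationError("duplicate SNP ids")
        observed = self.dosage[~np.isnan(self.dosage)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValidationError(f"dosage values outside {{0,1,2,NaN}}: {bad[:5]}")

    # -- convenience ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.dosage).any())

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_ids.index(snp_id)]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            list(self.snp_ids),
            self.dosage.copy(),
            dict(self.gene_of),
            dict(self.allele_labels),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
            and self.gene_of == other.gene_of
            and self.allele_labels == other.allele_labels
        )


class CohortTable:
    """Per-sample phenotype and covariate table.

    Wraps a :class:`pandas.DataFrame` with the fixed column set
    :data:`COHORT_COLUMNS` and validates the category vocabulary:
    controls carry ``subphenotype == "control"`` and
    ``p53_class == "unknown"``.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing_cols = set(COHORT_COLUMNS) - set(df.columns)
        if missing_cols:
            raise ValidationError(f"cohort table missing columns {sorted(missing_cols)}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids in cohort table")
        checks = {
            "status": STATUSES,
            "subphenotype": SUBPHENOTYPES,
            "p53_class": P53_CLASSES,
            "age_group": AGE_GROUPS,
            "gender": GENDERS,
            "region": REGIONS,
            "smoking": SMOKING_WITH_MISSING,
        }
        for col, allowed in checks.items():
            bad = set(df[col].astype(str)) - set(allowed)
            if bad:
                raise ValidationError(f"column {col!r} has unknown tokens {sorted(bad)}")
        controls = df[df["status"] == "control"]
        if (controls["subphenotype"] != "control").any():
            raise ValidationError("controls must have subphenotype 'control'")
        if (controls["p53_class"] != "unknown").any():
            raise ValidationError("controls must have p53_class 'unknown'")
        cases = df[df["status"] == "case"]
        if (cases["subphenotype"] == "control").any():
            raise ValidationError("cases may not have subphenotype 'control'")

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].astype(str).tolist()

    @property
    def status(self) -> np.ndarray:
        """Binary outcome vector: 1 = case, 0 = control."""
        return (self.frame["status"].to_numpy() == "case").astype(float)

    @property
    def n_cases(self) -> int:
        return int((self.frame["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.frame["status"] == "control").sum())

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.frame.equals(other.frame)

    def subset(self, mask: np.ndarray) -> "CohortTable":
        return CohortTable(self.frame.loc[np.asarray(mask, dtype=bool)])


def covariate_design(
    cohort: CohortTable, drop_missing_smoking: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build the adjustment design matrix (without intercept).

    Dummy-codes age group, gender, region and smoking with the first
    level of each as reference. Samples with smoking == "missing" are
    dropped (complete-case analysis).

    Returns
    -------
    X : (n_kept, k) float array of dummy columns
    keep : boolean mask over the original rows
    names : column names
    """
    df = cohort.frame
    keep = np.ones(len(df), dtype=bool)
    if drop_missing_smoking:
        keep &= (df["smoking"] != "missing").to_numpy()
    sub = df.loc[keep]
    cols: list[np.ndarray] = []
    names: list[str] = []
    spec: Sequence[tuple[str, tuple[str, ...]]] = (
        ("age_group", AGE_GROUPS),
        ("gender", GENDERS),
        ("region", REGIONS),
        ("smoking", SMOKING_LEVELS),
    )
    for col, levels in spec:
        values = sub[col].astype(str).to_numpy()
        for level in levels[1:]:
            dummy = (values == level).astype(float)
            if dummy.min() == dummy.max():  # constant: no information
                continue
            cols.append(dummy)
            names.append(f"{col}[{level}]")
    X = np.column_stack(cols) if cols else np.empty((len(sub), 0))
    return X, keep, names


def category_probs(counts: Mapping[str, float]) -> dict[str, float]:
    """Normalize a counts mapping into probabilities."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValidationError("counts must sum to a positive total")
    return {k: v / total for k, v in counts.items()}
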