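"""Cohort file IO, genotype encodings, and SNP screening.

Covers the pre-modelling plumbing: reading/writing the dosage matrix in
a PLINK-``.raw``-style text dialect or plain CSV, minor-allele
frequency and Hardy-Weinberg screening in controls, mode-of-inheritance
design encodings, frequency-based imputation of missing genotypes, and
derivation of case subphenotype labels (stage/grade classes and the
median-split immunostaining histoscore).
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import COHORT_COLUMNS, CohortTable, GenotypeMatrix, ValidationError

__all__ = [
    "ParseError",
    "HweResult",
    "Histoscore",
    "read_genotypes",
    "write_genotypes",
    "read_cohort",
    "write_cohort",
    "genotype_counts",
    "minor_allele_freq",
    "round_half_up",
    "hwe_test",
    "encode_moi",
    "impute_missing",
    "histoscore",
    "classify_p53",
    "assign_subphenotype",
    "control_genotype_counts",
    "screen_snps",
]

MOI_MODES = ("additive", "dominant", "recessive", "codominant")

#: Report-only flag threshold for Hardy-Weinberg departures in controls.
HWE_FLAG_P = 1e-4

_MISSING_TOKENS = {"NA", "", "NaN", "nan"}


class ParseError(ValidationError):
    """Malformed genotype/cohort file; message names line and column."""


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------


def write_genotypes(path: str | Path, matrix: GenotypeMatrix, dialect: str = "plink_raw") -> None:
    """Write a dosage matrix as text.

    ``plink_raw``: tab-delimited, header ``FID IID <snp>_<minor> ...``,
    missing cells written as ``NA``. ``csv``: comma-delimited with a
    single ``sample_id`` key column. Both round-trip bit-exactly through
    :func:`read_genotypes`.
    """
    path = Path(path)
    if dialect == "plink_raw":
        sep = "\t"
        header = ["FID", "IID"] + [
            f"{s}_{matrix.allele_labels.get(s, ('A', 'B'))[1]}" for s in matrix.snp_ids
        ]
        key_cols = 2
    elif dialect == "csv":
        sep = ","
        header = ["sample_id"] + list(matrix.snp_ids)
        key_cols = 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            row = [sid] * key_cols
            for v in matrix.dosage[i]:
                row.append("NA" if np.isnan(v) else str(int(v)))
            fh.write(sep.join(row) + "\n")


def read_genotypes(
    path: str | Path,
    dialect: str = "plink_raw",
    gene_of: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Parse a genotype file written in one of the two text dialects.

    Unknown tokens raise :class:`ParseError` naming the offending line
    and column (1-based, as editors count them).
    """
    path = Path(path)
    if dialect == "plink_raw":
        sep, key_cols = "\t", 2
    elif dialect == "csv":
        sep, key_cols = ",", 1
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split(sep)
    if dialect == "plink_raw":
        if header[:2] != ["FID", "IID"]:
            raise ParseError(f"{path}: line 1: expected header to start 'FID{sep}IID'")
    elif header[:1] != ["sample_id"]:
        raise ParseError(f"{path}: line 1: expected header to start 'sample_id'")
    snp_ids: list[str] = []
    allele_labels: dict[str, tuple[str, str]] = {}
    for col in header[key_cols:]:
        if dialect == "plink_raw":
            snp, _, minor = col.rpartition("_")
            if not snp or not minor:
                raise ParseError(f"{path}: line 1: bad SNP column token {col!r}")
            snp_ids.append(snp)
            allele_labels[snp] = ("A" if minor != "A" else "B", minor)
        else:
            snp_ids.append(col)
    if len(set(snp_ids)) != len(snp_ids):
        raise ParseError(f"{path}: line 1: duplicated SNP ids")
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != len(header):
            raise ParseError(
                f"{path}: line {lineno}: {len(parts)} fields, expected {len(header)}"
            )
        sample_ids.append(parts[key_cols - 1])
        row: list[float] = []
        for colno, tok in enumerate(parts[key_cols:], start=key_cols + 1):
            tok = tok.strip()
            if tok in _MISSING_TOKENS:
                row.append(np.nan)
            elif tok in ("0", "1", "2"):
                row.append(float(tok))
            else:
                raise ParseError(
                    f"{path}: line {lineno}, column {colno}: bad dosage token {tok!r}"
                )
        rows.append(row)
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicated sample ids")
    dosage = np.array(rows, dtype=float).reshape(len(rows), len(snp_ids))
    return GenotypeMatrix(
        sample_ids, snp_ids, dosage, gene_of=dict(gene_of or {}), allele_labels=allele_labels
    )


def write_cohort(path: str | Path, cohort: CohortTable) -> None:
    cohort.frame.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return CohortTable(df)


# ---------------------------------------------------------------------------
# Allele frequency and Hardy-Weinberg screening
# ---------------------------------------------------------------------------


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """Observed (n_AA, n_Aa, n_aa) genotype counts, ignoring missing."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def minor_allele_freq(counts: Sequence[float]) -> float:
    """Minor-allele frequency from (n_AA, n_Aa, n_aa) genotype counts."""
    n_aa, n_het, n_min = (float(c) for c in counts)
    if min(n_aa, n_het, n_min) < 0:
        raise ValidationError("genotype counts must be nonnegative")
    total = n_aa + n_het + n_min
    if total == 0:
        raise ValidationError("all genotype counts are zero")
    return (n_het + 2.0 * n_min) / (2.0 * total)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (reporting convention)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class HweResult:
    snp_id: str
    chi2: float
    df: int
    p_value: float
    control_counts: tuple[int, int, int]
    flagged: bool  # p <= HWE_FLAG_P (report-only)


def hwe_test(counts: Sequence[int], snp_id: str = "") -> HweResult:
    """Pearson chi-squared test of Hardy-Weinberg proportions (1 df).

    Expected counts are computed at the sample allele frequency. A
    monomorphic SNP yields chi2 = 0, p = 1 with a warning rather than an
    error.
    """
    n_aa, n_het, n_min = (int(c) for c in counts)
    n = n_aa + n_het + n_min
    if n < 1:
        raise ValidationError("need at least one genotyped sample")
    q = (n_het + 2 * n_min) / (2 * n)
    if q == 0.0 or q == 1.0:
        warnings.warn(f"SNP {snp_id or '<unnamed>'} is monomorphic; HWE p set to 1")
        return HweResult(snp_id, 0.0, 1, 1.0, (n_aa, n_het, n_min), False)
    p = 1.0 - q
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa, n_het, n_min], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, chi2, 1, p_value, (n_aa, n_het, n_min), p_value <= HWE_FLAG_P)


def control_genotype_counts(matrix: GenotypeMatrix, cohort: CohortTable) -> dict[str, tuple[int, int, int]]:
    """Per-SNP control genotype counts (missing dropped)."""
    is_control = cohort.status == 0.0
    return {
        snp: genotype_counts(matrix.dosage[is_control, j])
        for j, snp in enumerate(matrix.snp_ids)
    }


def screen_snps(matrix: GenotypeMatrix, cohort: CohortTable) -> pd.DataFrame:
    """Report-only QC table: control MAF, HWE in controls, call rate.

    Nothing is excluded; the ``hwe_flag`` column marks departures at
    p <= 1e-4 for the analyst.
    """
    counts = control_genotype_counts(matrix, cohort)
    rows = []
    for j, snp in enumerate(matrix.snp_ids):
        c = counts[snp]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hwe = hwe_test(c, snp)
        call_rate = 1.0 - float(np.isnan(matrix.dosage[:, j]).mean())
        rows.append(
            {
                "snp_id": snp,
                "gene": matrix.gene_of.get(snp, ""),
                "control_maf": minor_allele_freq(c) if sum(c) else np.nan,
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p_value,
                "hwe_flag": hwe.flagged,
                "call_rate": call_rate,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mode-of-inheritance encodings
# ---------------------------------------------------------------------------


def encode_moi(dosage_column: np.ndarray, moi: str) -> np.ndarray:
    """Design column(s) for one SNP under a mode of inheritance.

    additive -> (0,1,2); dominant -> carrier indicator; recessive ->
    rare-homozygote indicator; codominant -> two indicator columns
    (heterozygote, rare homozygote). Output shape is ``(n, 1)`` or
    ``(n, 2)``. Missing dosages must be imputed first.
    """
    g = np.asarray(dosage_column, dtype=float)
    if np.isnan(g).any():
        raise ValidationError("missing dosages present; impute before encoding")
    if not np.isin(g, (0.0, 1.0, 2.0)).all():
        raise ValidationError("dosages must be in {0,1,2}")
    if moi == "additive":
        return g[:, None].copy()
    if moi == "dominant":
        return (g >= 1.0).astype(float)[:, None]
    if moi == "recessive":
        return (g == 2.0).astype(float)[:, None]
    if moi == "codominant":
        return np.column_stack([(g == 1.0).astype(float), (g == 2.0).astype(float)])
    raise ValueError(f"unknown mode of inheritance {moi!r}")


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_missing(matrix: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Fill missing dosages by sampling the SNP's observed genotype mix.

    Each missing cell is drawn independently from the empirical
    {0,1,2} distribution of that SNP over all genotyped samples (cases
    and controls pooled). Deterministic given ``seed``. A stand-in for
    model-based imputation, adequate for low-LD tagSNP panels.
    """
    out = matrix.copy()
    fully_missing = [
        snp
        for j, snp in enumerate(out.snp_ids)
        if np.isnan(out.dosage[:, j]).all()
    ]
    if fully_missing:
        raise ValidationError(f"SNPs with 100% missingness: {fully_missing}")
    rng = np.random.default_rng(seed)
    for j in range(out.n_snps):
        col = out.dosage[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        counts = np.array(genotype_counts(col), dtype=float)
        probs = counts / counts.sum()
        col[miss] = rng.choice(3, size=int(miss.sum()), p=probs).astype(float)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Histoscore and subphenotype labels
# ---------------------------------------------------------------------------

#: Staining intensity grades of the immunostaining score.
INTENSITY_LEVELS = (0, 1, 2, 3)


@dataclass
class Histoscore:
    """Intensity-percentage summary: score = sum_i p_i * i, range 0-300."""

    percentages: tuple[float, float, float, float]
    score: float


def histoscore(percentages: Sequence[float]) -> Histoscore:
    p = tuple(float(v) for v in percentages)
    if len(p) != len(INTENSITY_LEVELS):
        raise ValidationError(f"need {len(INTENSITY_LEVELS)} intensity percentages")
    if any(v < 0 for v in p):
        raise ValidationError("percentages must be nonnegative")
    if abs(sum(p) - 100.0) > 1e-6:
        raise ValidationError(f"percentages sum to {sum(p)}, expected 100")
    score = float(sum(v * i for v, i in zip(p, INTENSITY_LEVELS)))
    return Histoscore(p, score)


def classify_p53(scores: Iterable[Histoscore | float]) -> list[str]:
    """Median split of case histoscores into 'low' (ties low) / 'high'."""
    values = [s.score if isinstance(s, Histoscore) else float(s) for s in scores]
    if not values:
        raise ValidationError("no histoscores to classify")
    median = float(np.median(values))
    return ["low" if v <= median else "high" for v in values]


_STAGES = ("Ta", "T1", "Tis", "T2", "T3", "T4")
_GRADES = ("G1", "G2", "G3", "unknown")

# (stage, grade) -> subphenotype; combinations not listed are "unknown".
_SUBPHENOTYPE_MAP: dict[tuple[str, str], str] = {
    ("Ta", "G1"): "lowNMIT",
    ("Ta", "G2"): "lowNMIT",
    ("Ta", "G3"): "highNMIT",
    ("T1", "G2"): "highNMIT",
    ("T1", "G3"): "highNMIT",
}
_SUBPHENOTYPE_MAP.update({("Tis", g): "highNMIT" for g in _GRADES})
_SUBPHENOTYPE_MAP.update({(s, g): "MIT" for s in ("T2", "T3", "T4") for g in _GRADES})


def assign_subphenotype(stage: str, grade: str) -> str:
    """Map tumor stage/grade to the invasiveness-risk subphenotype.

    Low-risk non-muscle-invasive: TaG1, TaG2. High-risk
    non-muscle-invasive: TaG3, T1G2, T1G3 and Tis (any grade).
    Muscle-invasive: T2-T4 (any grade). Anything else is "unknown".
    """
    if stage not in _STAGES:
        raise ValidationError(f"unrecognized stage {stage!r}")
    if grade not in _GRADES:
        raise ValidationError(f"unrecognized grade {grade!r}")
    return _SUBPHENOTYPE_MAP.get((stage, grade), "unknown")
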