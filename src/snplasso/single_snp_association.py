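"""Classical per-SNP inference.

Covariate-adjusted logistic likelihood-ratio tests under four modes of
inheritance, best-mode selection, polytomous subtype-heterogeneity
tests, SNP x SNP and SNP x smoking interaction scans, min-p permutation
correction for multiple testing, and the per-allele study power
calculation. All models adjust for age group, gender, region and
smoking status (complete-case on smoking).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import intercept_only_loglik, logistic_fit, multinomial_fit
from .data_prep import MOI_MODES, encode_moi, genotype_counts
from .synthetic_cohort import case_genotype_probs, hwe_probs
from .types import CohortTable, GenotypeMatrix, ValidationError, covariate_design

__all__ = [
    "AssociationResult",
    "HeterogeneityResult",
    "PermutationCorrection",
    "fit_snp_logistic",
    "fit_all_moi",
    "best_moi",
    "polytomous_heterogeneity",
    "interaction_scan",
    "minp_permutation",
    "power_per_allele",
    "power_per_allele_sim",
    "association_table",
]

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class AssociationResult:
    snp_id: str
    moi: str
    beta: float
    or_point: float
    ci95: tuple[float, float]
    lrt_stat: float
    lrt_df: int
    p_value: float
    p_trend: float
    #: second coefficient (rare homozygote) under the codominant model
    beta_aa: float = float("nan")
    ci95_aa: tuple[float, float] = (float("nan"), float("nan"))
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(
            f in self.flags
            for f in ("constant_genotype", "nonconverged", "separation")
        )


@dataclass
class HeterogeneityResult:
    snp_id: str
    subtypes: tuple[str, ...]
    per_subtype_betas: dict[str, float]
    het_lrt_stat: float
    het_df: int
    het_p: float
    flags: list[str] = field(default_factory=list)


@dataclass
class PermutationCorrection:
    n_perm: int
    family: str
    observed_p: dict[str, float]
    corrected_p: dict[str, float]
    seed: int


def _flagged_result(snp_id: str, moi: str, flags: list[str]) -> AssociationResult:
    nan = float("nan")
    return AssociationResult(
        snp_id, moi, nan, nan, (nan, nan), nan, 1 + (moi == "codominant"), nan, nan,
        flags=flags,
    )


def _prepare(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Outcome, covariate block and complete-case mask."""
    X_cov, keep, _ = covariate_design(cohort)
    y = cohort.status[keep]
    return y, X_cov, keep


def fit_snp_logistic(
    genotype_column: np.ndarray,
    cohort: CohortTable,
    moi: str,
    snp_id: str = "",
    compute_trend: bool = True,
) -> AssociationResult:
    """Adjusted logistic fit of one SNP under one mode of inheritance.

    Likelihood-ratio test against the covariate-only null; Wald 95% CI
    on the genotype coefficient. Degenerate inputs (constant genotype,
    separation, non-convergence) come back flagged, never raised.
    """
    if moi not in MOI_MODES:
        raise ValueError(f"unknown mode of inheritance {moi!r}")
    g = np.asarray(genotype_column, dtype=float)
    if np.isnan(g).any():
        raise ValidationError("missing genotypes present; impute first")
    y, X_cov, keep = _prepare(cohort)
    g = g[keep]
    flags: list[str] = []
    if np.unique(g).size < 2:
        return _flagged_result(snp_id, moi, ["constant_genotype"])
    used_moi = moi
    if moi == "codominant":
        n0, n1, n2 = genotype_counts(g)
        if n1 == 0 or n2 == 0:
            warnings.warn(
                f"SNP {snp_id or '<unnamed>'}: empty codominant class, "
                "collapsing to dominant coding"
            )
            flags.append("collapsed_codominant")
            used_moi = "dominant"
    G = encode_moi(g, used_moi)
    ones = np.ones((len(y), 1))
    X_null = np.hstack([ones, X_cov])
    X_full = np.hstack([ones, X_cov, G])
    null_fit = logistic_fit(X_null, y)
    full_fit = logistic_fit(X_full, y)
    flags += [f for f in full_fit.flags if f not in flags]
    k = G.shape[1]
    lrt = max(0.0, 2.0 * (full_fit.loglik - null_fit.loglik))
    p_value = float(stats.chi2.sf(lrt, df=k))
    def _exp(v: float) -> float:
        return float(np.exp(np.clip(v, -700.0, 700.0)))

    beta = float(full_fit.beta[-k])
    se = float(np.sqrt(max(full_fit.cov[-k, -k], 0.0)))
    ci = (_exp(beta - Z975 * se), _exp(beta + Z975 * se))
    beta_aa, ci_aa = float("nan"), (float("nan"), float("nan"))
    if k == 2:
        beta_aa = float(full_fit.beta[-1])
        se_aa = float(np.sqrt(max(full_fit.cov[-1, -1], 0.0)))
        ci_aa = (_exp(beta_aa - Z975 * se_aa), _exp(beta_aa + Z975 * se_aa))
    if compute_trend and moi != "additive":
        p_trend = fit_snp_logistic(
            genotype_column, cohort, "additive", snp_id, compute_trend=False
        ).p_value
    else:
        p_trend = p_value if moi == "additive" else float("nan")
    return AssociationResult(
        snp_id=snp_id,
        moi=moi,
        beta=beta,
        or_point=_exp(beta),
        ci95=ci,
        lrt_stat=lrt,
        lrt_df=k,
        p_value=p_value,
        p_trend=p_trend,
        beta_aa=beta_aa,
        ci95_aa=ci_aa,
        flags=flags,
    )


def fit_all_moi(
    genotype_column: np.ndarray, cohort: CohortTable, snp_id: str = ""
) -> dict[str, AssociationResult]:
    return {
        moi: fit_snp_logistic(genotype_column, cohort, moi, snp_id)
        for moi in MOI_MODES
    }


def best_moi(results: dict[str, AssociationResult]) -> tuple[str, float]:
    """Mode of inheritance with the lowest p-value.

    Ties (and the all-flagged case) resolve in the fixed order
    additive > dominant > recessive > codominant. Flagged fits are
    excluded from the minimum.
    """
    best: tuple[str, float] | None = None
    for moi in ("additive", "dominant", "recessive", "codominant"):
        r = results.get(moi)
        if r is None or not r.ok or not np.isfinite(r.p_value):
            continue
        if best is None or r.p_value < best[1]:
            best = (moi, r.p_value)
    if best is None:
        return ("additive", float("nan"))
    return best


# ---------------------------------------------------------------------------
# Polytomous subtype heterogeneity
# ---------------------------------------------------------------------------


def polytomous_heterogeneity(
    genotype_column: np.ndarray,
    cohort: CohortTable,
    snp_id: str = "",
    case_classes: str = "subphenotype",
) -> HeterogeneityResult:
    """Subtype-heterogeneity likelihood-ratio test (additive coding).

    Fits a multinomial logit of {control, subtype_1, ...} on covariates
    plus genotype, once with a free genotype coefficient per subtype and
    once with a single shared coefficient; the heterogeneity statistic
    is twice the log-likelihood difference with df = (#subtypes - 1).
    ``case_classes`` may be "subphenotype" (stage/grade classes) or
    "p53_class". Cases with an unknown class and empty subtypes are
    dropped with a warning.
    """
    g = np.asarray(genotype_column, dtype=float)
    if np.isnan(g).any():
        raise ValidationError("missing genotypes present; impute first")
    y_bin, X_cov, keep = _prepare(cohort)
    g = g[keep]
    labels = cohort.frame.loc[keep, case_classes].astype(str).to_numpy()
    status = cohort.frame.loc[keep, "status"].to_numpy()
    flags: list[str] = []
    order = (
        ("lowNMIT", "highNMIT", "MIT")
        if case_classes == "subphenotype"
        else ("low", "high")
    )
    present = [s for s in order if ((labels == s) & (status == "case")).sum() > 0]
    dropped = [s for s in order if s not in present]
    if dropped:
        warnings.warn(f"SNP {snp_id or '<unnamed>'}: empty subtypes dropped: {dropped}")
        flags.append("dropped_subtypes")
    if len(present) < 2:
        raise ValidationError("need at least two non-empty case subtypes")
    known = (status == "control") | np.isin(labels, present)
    if (~known).any():
        flags.append("dropped_unknown_class")
    g, X_cov, labels, status = g[known], X_cov[known], labels[known], status[known]
    codes = np.zeros(len(labels), dtype=int)
    for k, s in enumerate(present, start=1):
        codes[(labels == s) & (status == "case")] = k
    X = np.hstack([np.ones((len(codes), 1)), X_cov, g[:, None]])
    j_geno = X.shape[1] - 1
    free = multinomial_fit(X, codes)
    tied = multinomial_fit(X, codes, tied_cols=(j_geno,))
    if not (free.converged and tied.converged):
        flags.append("nonconverged")
    het_lrt = max(0.0, 2.0 * (free.loglik - tied.loglik))
    het_df = len(present) - 1
    het_p = float(stats.chi2.sf(het_lrt, df=het_df))
    betas = {s: float(free.coef[j_geno, k]) for k, s in enumerate(present)}
    return HeterogeneityResult(
        snp_id=snp_id,
        subtypes=tuple(present),
        per_subtype_betas=betas,
        het_lrt_stat=het_lrt,
        het_df=het_df,
        het_p=het_p,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Interaction scans
# ---------------------------------------------------------------------------


def interaction_scan(
    matrix: GenotypeMatrix, cohort: CohortTable, kind: str = "snp_snp"
) -> pd.DataFrame:
    """LRT scan of multiplicative per-allele interaction terms (1 df).

    ``snp_snp``: every unordered SNP pair, product of the two additive
    dosages added to the adjusted two-SNP model. ``snp_smoking``: each
    SNP crossed with ever-smoking (never vs ever). Non-converging fits
    are flagged and excluded from summaries.
    """
    if matrix.has_missing():
        raise ValidationError("missing genotypes present; impute first")
    y, X_cov, keep = _prepare(cohort)
    D = matrix.dosage[keep]
    ones = np.ones((len(y), 1))
    rows: list[dict] = []
    if kind == "snp_snp":
        for a in range(matrix.n_snps):
            ga = D[:, a : a + 1]
            for b in range(a + 1, matrix.n_snps):
                gb = D[:, b : b + 1]
                X_base = np.hstack([ones, X_cov, ga, gb])
                X_int = np.hstack([X_base, ga * gb])
                rows.append(
                    _interaction_row(
                        X_base, X_int, y,
                        {"snp_a": matrix.snp_ids[a], "snp_b": matrix.snp_ids[b]},
                    )
                )
    elif kind == "snp_smoking":
        ever = (
            cohort.frame.loc[keep, "smoking"]
            .astype(str)
            .isin(["occasional", "former", "current"])
            .to_numpy()
            .astype(float)[:, None]
        )
        for a in range(matrix.n_snps):
            ga = D[:, a : a + 1]
            # smoking main effects are already in the covariate block
            X_base = np.hstack([ones, X_cov, ga])
            X_int = np.hstack([X_base, ga * ever])
            rows.append(
                _interaction_row(X_base, X_int, y, {"snp_a": matrix.snp_ids[a]})
            )
    else:
        raise ValueError(f"unknown interaction kind {kind!r}")
    return pd.DataFrame(rows)


def _interaction_row(X_base, X_int, y, ids: dict) -> dict:
    base = logistic_fit(X_base, y)
    full = logistic_fit(X_int, y)
    lrt = max(0.0, 2.0 * (full.loglik - base.loglik))
    ok = base.converged and full.converged and "separation" not in full.flags
    return {
        **ids,
        "beta_int": float(full.beta[-1]),
        "lrt_stat": lrt,
        "p_value": float(stats.chi2.sf(lrt, df=1)) if ok else float("nan"),
        "converged": ok,
    }


# ---------------------------------------------------------------------------
# Min-p permutation correction
# ---------------------------------------------------------------------------


def _trend_pvalues(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Covariate-free score (trend) test p-values, vectorized over SNPs."""
    n = len(y)
    n1 = y.sum()
    n0 = n - n1
    col_mean = D.mean(axis=0)
    U = D.T @ y - n1 * col_mean
    ssd = ((D - col_mean) ** 2).sum(axis=0)
    V = n1 * n0 / (n * (n - 1.0)) * ssd
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U * U / V, 0.0)
    return stats.chi2.sf(chi2, df=1)


def _lrt_family_pvalues(
    D: np.ndarray, y: np.ndarray, X_cov: np.ndarray, mois: tuple[str, ...]
) -> np.ndarray:
    ones = np.ones((len(y), 1))
    X_null = np.hstack([ones, X_cov])
    null_ll = logistic_fit(X_null, y).loglik
    out = np.empty(D.shape[1])
    for j in range(D.shape[1]):
        best = 1.0
        g = D[:, j]
        if np.unique(g).size < 2:
            out[j] = 1.0
            continue
        for moi in mois:
            used = moi
            if moi == "codominant":
                _, n1, n2 = genotype_counts(g)
                if n1 == 0 or n2 == 0:
                    used = "dominant"
            G = encode_moi(g, used)
            fit = logistic_fit(np.hstack([X_null, G]), y)
            lrt = max(0.0, 2.0 * (fit.loglik - null_ll))
            best = min(best, float(stats.chi2.sf(lrt, df=G.shape[1])))
        out[j] = best
    return out


_FAMILIES = ("trend", "lrt_additive", "lrt_best_moi")


def minp_permutation(
    matrix: GenotypeMatrix,
    cohort: CohortTable,
    family: str = "lrt_additive",
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationCorrection:
    """Family-wise min-p permutation correction.

    The genotype block is permuted against the (outcome + covariate)
    block, preserving outcome-covariate and SNP-SNP dependence while
    breaking genotype-outcome association. For each SNP,
    ``corrected_p = (1 + #{perm: min_family p_perm <= p_obs}) / (n_perm + 1)``.

    Families: "trend" (covariate-free score test, vectorized),
    "lrt_additive" (adjusted additive LRT), "lrt_best_moi" (min over
    the four modes of inheritance, adjusted).
    """
    if n_perm < 100:
        raise ValidationError("n_perm < 100 gives an unstable permutation tail")
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {_FAMILIES}")
    if matrix.has_missing():
        raise ValidationError("missing genotypes present; impute first")
    y, X_cov, keep = _prepare(cohort)
    D = matrix.dosage[keep]
    rng = np.random.default_rng(seed)

    def pvals(Dperm: np.ndarray) -> np.ndarray:
        if family == "trend":
            return _trend_pvalues(Dperm, y)
        mois = ("additive",) if family == "lrt_additive" else MOI_MODES
        return _lrt_family_pvalues(Dperm, y, X_cov, mois)

    observed = pvals(D)
    if family == "trend":
        # one matmul per batch of permutations
        perm_min = np.empty(n_perm)
        n = len(y)
        n1, n0 = y.sum(), len(y) - y.sum()
        col_mean = D.mean(axis=0)
        ssd = ((D - col_mean) ** 2).sum(axis=0)
        V = n1 * n0 / (n * (n - 1.0)) * ssd
        for start in range(0, n_perm, 256):
            b = min(256, n_perm - start)
            Y = np.empty((n, b))
            for k in range(b):
                Y[:, k] = y[rng.permutation(n)]
            U = D.T @ Y - n1 * col_mean[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                chi2 = np.where(V[:, None] > 0, U * U / V[:, None], 0.0)
            perm_min[start : start + b] = stats.chi2.sf(chi2.max(axis=0), df=1)
    else:
        perm_min = np.empty(n_perm)
        for k in range(n_perm):
            Dperm = D[rng.permutation(len(y))]
            perm_min[k] = pvals(Dperm).min()
    corrected = (1.0 + (perm_min[None, :] <= observed[:, None]).sum(axis=1)) / (
        n_perm + 1.0
    )
    return PermutationCorrection(
        n_perm=n_perm,
        family=family,
        observed_p=dict(zip(matrix.snp_ids, observed.tolist())),
        corrected_p=dict(zip(matrix.snp_ids, corrected.tolist())),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------


def power_per_allele(
    n_cases: int, n_controls: int, maf: float, or_per_allele: float, alpha: float = 0.05
) -> float:
    """Analytic power of the two-sided 1-df per-allele test.

    Normal approximation on the log allele odds ratio with
    allele-count variance; case allele frequency follows from the
    exponentially tilted genotype distribution, so it is exactly the
    frequency the additive logistic model implies.
    """
    if not 0.0 < maf <= 0.5:
        raise ValidationError("maf must be in (0, 0.5]")
    if or_per_allele <= 0 or not 0.0 < alpha < 1.0:
        raise ValidationError("need or > 0 and alpha in (0,1)")
    q0 = maf
    probs_case = case_genotype_probs(maf, float(np.log(or_per_allele)))
    q1 = float(probs_case[1] / 2 + probs_case[2])
    log_or_allele = float(
        np.log(q1 / (1 - q1)) - np.log(q0 / (1 - q0))
    )
    var = (
        1.0 / (2 * n_cases * q1)
        + 1.0 / (2 * n_cases * (1 - q1))
        + 1.0 / (2 * n_controls * q0)
        + 1.0 / (2 * n_controls * (1 - q0))
    )
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    delta = abs(log_or_allele) / np.sqrt(var)
    return float(stats.norm.cdf(delta - z_alpha) + stats.norm.cdf(-delta - z_alpha))


def power_per_allele_sim(
    n_cases: int,
    n_controls: int,
    maf: float,
    or_per_allele: float,
    alpha: float = 0.05,
    n_rep: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical power of the covariate-free additive LRT by simulation.

    Each replicate draws genotype counts from the tilted case / HWE
    control distributions and fits the additive logistic model on the
    weighted 6-row sufficient representation.
    """
    rng = np.random.default_rng(seed)
    p_ctrl = hwe_probs(maf)
    p_case = case_genotype_probs(maf, float(np.log(or_per_allele)))
    X = np.array(
        [[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]
    )
    y = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    hits = 0
    for _ in range(n_rep):
        w = np.concatenate(
            [rng.multinomial(n_cases, p_case), rng.multinomial(n_controls, p_ctrl)]
        ).astype(float)
        fit = logistic_fit(X, y, sample_weight=w)
        ll0 = intercept_only_loglik(y, sample_weight=w)
        lrt = max(0.0, 2.0 * (fit.loglik - ll0))
        if stats.chi2.sf(lrt, df=1) <= alpha:
            hits += 1
    return hits / n_rep


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def association_table(matrix: GenotypeMatrix, cohort: CohortTable) -> pd.DataFrame:
    """Per-SNP summary table mirroring the classical report layout.

    Genotype counts by arm, best-mode OR with Wald 95% CI and LRT
    p-value, additive trend p, and a reproducibility placeholder filled
    in by the multi-SNP stage.
    """
    if matrix.has_missing():
        raise ValidationError("missing genotypes present; impute first")
    is_case = cohort.status == 1.0
    rows = []
    for j, snp in enumerate(matrix.snp_ids):
        g = matrix.dosage[:, j]
        results = fit_all_moi(g, cohort, snp)
        moi, p = best_moi(results)
        r = results[moi]
        case_counts = genotype_counts(g[is_case])
        ctrl_counts = genotype_counts(g[~is_case])
        rows.append(
            {
                "snp_id": snp,
                "gene": matrix.gene_of.get(snp, ""),
                "case_AA": case_counts[0],
                "case_Aa": case_counts[1],
                "case_aa": case_counts[2],
                "ctrl_AA": ctrl_counts[0],
                "ctrl_Aa": ctrl_counts[1],
                "ctrl_aa": ctrl_counts[2],
                "moi": moi,
                "or": r.or_point,
                "ci_lo": r.ci95[0],
                "ci_hi": r.ci95[1],
                "p_value": p,
                "p_trend": results["additive"].p_value,
                "reproducibility_pct": np.nan,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
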