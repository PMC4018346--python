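"""Case-control cohort simulator.

Generates genotype matrices and covariate tables with the structure the
downstream analyses assume: control genotypes in Hardy-Weinberg
proportions at a specified minor-allele frequency, case genotypes drawn
by exponential tilting of the control distribution
(``P_case(g) proportional to P_ctrl(g) * exp(beta * g)``), which is
exactly consistent with a prospective additive logistic model under
case-control sampling. Covariates are tilted the same way, so their
configured log-odds are recovered by logistic regression on the
simulated data.

SNPs are simulated independently (low-LD tagSNP panel assumption);
missingness is applied completely at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import panels
from .data_prep import classify_p53, histoscore
from .types import (
    AGE_GROUPS,
    GENDERS,
    REGIONS,
    SMOKING_LEVELS,
    CohortTable,
    GenotypeMatrix,
    ValidationError,
)

__all__ = [
    "SnpSpec",
    "CovariateModel",
    "P53Model",
    "SimConfig",
    "default_sim_config",
    "simulate_genotypes",
    "simulate_cohort",
]

_PROB_TOL = 1e-12

_COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": AGE_GROUPS,
    "gender": GENDERS,
    "region": REGIONS,
    "smoking": SMOKING_LEVELS,
}


@dataclass(frozen=True)
class SnpSpec:
    snp_id: str
    gene: str
    control_maf: float
    log_or: float = 0.0  # per-allele log odds ratio


@dataclass
class CovariateModel:
    """Control-population category probabilities and disease log-odds.

    ``control_probs[cov][level]`` is the level's probability among
    controls; ``log_odds[cov][level]`` its per-level log odds of disease
    relative to the covariate's first level. Case probabilities follow
    by exponential tilting.
    """

    control_probs: dict[str, dict[str, float]]
    log_odds: dict[str, dict[str, float]]
    smoking_missing_rate: tuple[float, float] = (0.0, 0.0)  # (cases, controls)

    def case_probs(self, cov: str) -> dict[str, float]:
        probs = self.control_probs[cov]
        lors = self.log_odds.get(cov, {})
        weights = {k: p * np.exp(lors.get(k, 0.0)) for k, p in probs.items()}
        total = sum(weights.values())
        return {k: w / total for k, w in weights.items()}

    def validate(self) -> None:
        for cov, levels in _COVARIATE_LEVELS.items():
            if cov not in self.control_probs:
                raise ValidationError(f"covariate model missing {cov!r}")
            probs = self.control_probs[cov]
            if set(probs) != set(levels):
                raise ValidationError(
                    f"{cov}: expected levels {levels}, got {sorted(probs)}"
                )
            vals = np.array(list(probs.values()))
            if (vals < 0).any() or (vals > 1).any():
                raise ValidationError(f"{cov}: probabilities outside [0,1]")
            if abs(vals.sum() - 1.0) > _PROB_TOL:
                raise ValidationError(f"{cov}: probabilities sum to {vals.sum()}")


@dataclass
class P53Model:
    """Dirichlet model over the four intensity percentages (x100)."""

    alpha: tuple[float, float, float, float] = (3.0, 2.0, 1.5, 1.0)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return 100.0 * rng.dirichlet(self.alpha, size=n)


@dataclass
class SimConfig:
    n_cases: int
    n_controls: int
    snp_specs: list[SnpSpec]
    covariate_model: CovariateModel
    subphenotype_probs: tuple[float, float, float] = (0.625, 0.175, 0.2)
    p53_model: P53Model = field(default_factory=P53Model)
    missing_rate: float = 0.0
    seed: int = 0
    #: Prospective-sampling intercept (baseline log-odds of disease) and
    #: rejection-sampling draw cap; only used with mode="prospective".
    base_log_odds: float = -1.0
    max_prospective_draws: int = 2_000_000

    def validate(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValidationError("sample counts must be nonnegative")
        ids = [s.snp_id for s in self.snp_specs]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate SNP ids in snp_specs")
        for s in self.snp_specs:
            if not 0.0 < s.control_maf <= 0.5:
                raise ValidationError(
                    f"{s.snp_id}: control_maf {s.control_maf} outside (0, 0.5]"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError(f"missing_rate {self.missing_rate} outside [0, 1)")
        probs = np.asarray(self.subphenotype_probs, dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ValidationError("subphenotype_probs must be a probability vector")
        self.covariate_model.validate()


def default_covariate_model() -> CovariateModel:
    """Covariate model matching the reference cohort margins."""
    control_probs: dict[str, dict[str, float]] = {}
    log_odds: dict[str, dict[str, float]] = {}
    for cov, counts in panels.DEMOGRAPHICS.items():
        ctrl_tot = sum(c for _, c in counts.values())
        case_tot = sum(c for c, _ in counts.values())
        control_probs[cov] = {k: ctrl / ctrl_tot for k, (_, ctrl) in counts.items()}
        levels = list(counts)
        ref_case, ref_ctrl = counts[levels[0]]
        log_odds[cov] = {
            k: float(np.log((case / case_tot) / (ctrl / ctrl_tot))
                     - np.log((ref_case / case_tot) / (ref_ctrl / ctrl_tot)))
            for k, (case, ctrl) in counts.items()
        }
    case_miss = panels.SMOKING_MISSING[0] / panels.N_CASES
    ctrl_miss = panels.SMOKING_MISSING[1] / panels.N_CONTROLS
    return CovariateModel(control_probs, log_odds, (case_miss, ctrl_miss))


def default_sim_config(
    n_cases: int = panels.N_CASES,
    n_controls: int = panels.N_CONTROLS,
    n_snps: int = panels.N_PANEL_SNPS,
    seed: int = 0,
    missing_rate: float = 0.0,
    log_or_of: dict[str, float] | None = None,
) -> SimConfig:
    """Default configuration: reference SNP panel, reference margins.

    ``log_or_of`` injects per-allele effects for named SNPs; every other
    SNP is null.
    """
    effects = log_or_of or {}
    panel_ids = {p.snp_id for p in panels.default_panel(n_snps)}
    unknown = set(effects) - panel_ids
    if unknown:
        raise ValidationError(
            f"log_or_of names SNPs outside the {n_snps}-SNP panel: {sorted(unknown)}"
        )
    specs = [
        SnpSpec(p.snp_id, p.gene, p.control_maf, effects.get(p.snp_id, 0.0))
        for p in panels.default_panel(n_snps)
    ]
    return SimConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        snp_specs=specs,
        covariate_model=default_covariate_model(),
        missing_rate=missing_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (P0, P1, P2) at MAF q."""
    q = float(maf)
    p = 1.0 - q
    return np.array([p * p, 2.0 * p * q, q * q])


def case_genotype_probs(maf: float, log_or: float) -> np.ndarray:
    """Exponentially tilted case genotype distribution."""
    w = hwe_probs(maf) * np.exp(log_or * np.arange(3))
    return w / w.sum()


def _draw_genotypes(
    rng: np.random.Generator, probs: np.ndarray, n: int
) -> np.ndarray:
    u = rng.random(n)
    return np.searchsorted(np.cumsum(probs)[:-1], u, side="right").astype(float)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate the dosage matrix (cases first, then controls).

    Controls follow Hardy-Weinberg proportions at each SNP's
    ``control_maf``; cases follow the tilted distribution so the
    per-allele odds ratio equals ``exp(log_or)`` exactly under the
    additive logistic model. Missingness is MCAR at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x67]))
    n_cases, n_controls = config.n_cases, config.n_controls
    n = n_cases + n_controls
    p = len(config.snp_specs)
    dosage = np.empty((n, p))
    for j, spec in enumerate(config.snp_specs):
        dosage[:n_cases, j] = _draw_genotypes(
            rng, case_genotype_probs(spec.control_maf, spec.log_or), n_cases
        )
        dosage[n_cases:, j] = _draw_genotypes(rng, hwe_probs(spec.control_maf), n_controls)
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    sample_ids = [f"case{i + 1:05d}" for i in range(n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(n_controls)
    ]
    return GenotypeMatrix(
        sample_ids,
        [s.snp_id for s in config.snp_specs],
        dosage,
        gene_of={s.snp_id: s.gene for s in config.snp_specs},
        allele_labels={s.snp_id: ("G", "A") for s in config.snp_specs},
    )


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def _draw_categories(
    rng: np.random.Generator, probs: dict[str, float], levels: Sequence[str], n: int
) -> np.ndarray:
    pvec = np.array([probs[level] for level in levels])
    idx = _draw_genotypes(rng, pvec / pvec.sum(), n).astype(int)
    return np.array(levels, dtype=object)[idx]


def simulate_cohort(
    config: SimConfig, mode: str = "retrospective"
) -> tuple[GenotypeMatrix, CohortTable]:
    """Simulate genotypes plus the phenotype/covariate table.

    ``retrospective`` (default) draws exactly ``n_cases`` cases and
    ``n_controls`` controls using exponential tilting per covariate and
    per SNP. ``prospective`` draws population samples, assigns disease
    from the joint logistic model with intercept ``base_log_odds``, and
    keeps drawing until both quotas fill (raises if
    ``max_prospective_draws`` is exceeded).
    """
    if mode == "retrospective":
        matrix = simulate_genotypes(config)
    elif mode == "prospective":
        matrix = _simulate_genotypes_prospective(config)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    n_cases, n_controls = config.n_cases, config.n_controls
    model = config.covariate_model
    columns: dict[str, np.ndarray] = {}
    for cov, levels in _COVARIATE_LEVELS.items():
        case_vals = _draw_categories(rng, model.case_probs(cov), levels, n_cases)
        ctrl_vals = _draw_categories(rng, model.control_probs[cov], levels, n_controls)
        columns[cov] = np.concatenate([case_vals, ctrl_vals])
    # smoking non-response, applied after the level draw (MCAR within arm)
    miss_case, miss_ctrl = model.smoking_missing_rate
    smoking = columns["smoking"]
    miss_mask = np.concatenate(
        [rng.random(n_cases) < miss_case, rng.random(n_controls) < miss_ctrl]
    )
    smoking[miss_mask] = "missing"

    sub_levels = ("lowNMIT", "highNMIT", "MIT")
    sub_idx = _draw_genotypes(
        rng, np.asarray(config.subphenotype_probs, dtype=float), n_cases
    ).astype(int)
    subphenotype = np.concatenate(
        [np.array(sub_levels, dtype=object)[sub_idx], np.repeat("control", n_controls)]
    )
    if n_cases:
        pct = config.p53_model.draw(rng, n_cases)
        pct = pct / pct.sum(axis=1, keepdims=True) * 100.0
        scores = [histoscore(tuple(row)) for row in pct]
        p53 = np.concatenate(
            [np.array(classify_p53(scores), dtype=object), np.repeat("unknown", n_controls)]
        )
    else:
        p53 = np.repeat("unknown", n_controls)

    frame = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "status": ["case"] * n_cases + ["control"] * n_controls,
            "subphenotype": subphenotype,
            "p53_class": p53,
            "age_group": columns["age_group"],
            "gender": columns["gender"],
            "region": columns["region"],
            "smoking": smoking,
        }
    )
    return matrix, CohortTable(frame)


def _simulate_genotypes_prospective(config: SimConfig) -> GenotypeMatrix:
    """Rejection sampler: population draws classified by the logistic model."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E]))
    specs = config.snp_specs
    probs = np.stack([hwe_probs(s.control_maf) for s in specs])  # population ~ control
    betas = np.array([s.log_or for s in specs])
    need_case, need_ctrl = config.n_cases, config.n_controls
    cases: list[np.ndarray] = []
    ctrls: list[np.ndarray] = []
    drawn = 0
    batch = max(1024, need_case + need_ctrl)
    while need_case > 0 or need_ctrl > 0:
        if drawn >= config.max_prospective_draws:
            raise RuntimeError(
                f"prospective sampler exceeded {config.max_prospective_draws} draws "
                f"(still need {need_case} cases, {need_ctrl} controls)"
            )
        drawn += batch
        u = rng.random((batch, len(specs)))
        cum = np.cumsum(probs, axis=1)
        g = (u[:, :, None] > cum[None, :, :2]).sum(axis=2).astype(float)
        eta = config.base_log_odds + g @ betas
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        g_case, g_ctrl = g[is_case], g[~is_case]
        if need_case > 0 and len(g_case):
            take = g_case[:need_case]
            cases.append(take)
            need_case -= len(take)
        if need_ctrl > 0 and len(g_ctrl):
            take = g_ctrl[:need_ctrl]
            ctrls.append(take)
            need_ctrl -= len(take)
    dosage = np.concatenate(
        [np.concatenate(cases) if cases else np.empty((0, len(specs)))]
        + [np.concatenate(ctrls) if ctrls else np.empty((0, len(specs)))]
    )
    if config.missing_rate > 0:
        dosage[rng.random(dosage.shape) < config.missing_rate] = np.nan
    sample_ids = [f"case{i + 1:05d}" for i in range(config.n_cases)] + [
        f"ctrl{i + 1:05d}" for i in range(config.n_controls)
    ]
    return GenotypeMatrix(
        sample_ids,
        [s.snp_id for s in specs],
        dosage,
        gene_of={s.snp_id: s.gene for s in specs},
        allele_labels={s.snp_id: ("G", "A") for s in specs},
    )
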