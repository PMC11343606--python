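"""Synthetic two-arm cohorts with a planted expression signature.

Generates negative-binomial count matrices in which a chosen subset of
genes is upregulated by a known fold in one arm, plus covariate tables and
score-linked survival times, so every downstream stage can be tested by
parameter recovery without any external dataset.

All randomness flows from a single integer seed; each stage draws from its
own deterministic sub-stream, so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_counts",
    "generate_bimodal_vector",
    "generate_survival",
    "simulate_cohort",
]

CONTROL_ARM = "control"
CASE_ARM = "case"

# Stage keys for deterministic sub-streams of the one global seed.
_STREAMS = {"lengths": 1, "means": 2, "counts": 3, "covariates": 4, "survival": 5}

#: Baseline exponential event rate at the cohort-average score.
BASE_HAZARD = 0.1

#: Spread (log-normal sigma) of per-gene baseline means around `baseline_mean`.
GENE_MEAN_SIGMA = 0.25


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _STREAMS[stage])))


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 300
    n_signature_genes: int = 29
    samples_per_group: int = 10
    baseline_mean: float = 100.0
    dispersion: float = 10.0
    signature_fold: float = 4.0
    gene_length_range: tuple[int, int] = (500, 5000)
    survival_link: float = 0.0
    censor_rate: float = 0.2
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be positive, got {self.n_genes}")
        if self.n_signature_genes < 1:
            raise ConfigurationError(
                f"n_signature_genes must be positive, got {self.n_signature_genes}"
            )
        if self.n_signature_genes > self.n_genes:
            raise ConfigurationError(
                "n_signature_genes exceeds n_genes "
                f"({self.n_signature_genes} > {self.n_genes})"
            )
        if self.samples_per_group < 2:
            raise ConfigurationError(
                f"samples_per_group must be >= 2, got {self.samples_per_group}"
            )
        if self.baseline_mean <= 0:
            raise ConfigurationError(
                f"baseline_mean must be positive, got {self.baseline_mean}"
            )
        if self.dispersion <= 0:
            raise ConfigurationError(
                f"dispersion must be positive, got {self.dispersion}"
            )
        if self.signature_fold < 1:
            raise ConfigurationError(
                f"signature_fold must be >= 1, got {self.signature_fold}"
            )
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                f"gene_length_range must be positive and ordered, got {(lo, hi)}"
            )
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigurationError(
                f"censor_rate must be in [0, 1], got {self.censor_rate}"
            )
        return self


@dataclass(frozen=True)
class PlantedTruth:
    signature_genes: tuple[str, ...]
    fold: float


@dataclass(frozen=True)
class SyntheticCohort:
    counts: pd.DataFrame
    gene_lengths: pd.Series
    metadata: pd.DataFrame
    truth: PlantedTruth
    config: SyntheticConfig = field(repr=False)


def _sample_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str]]:
    m = cfg.samples_per_group
    width = max(2, len(str(m)))
    ctrl = [f"ctrl_{i:0{width}d}" for i in range(1, m + 1)]
    case = [f"case_{i:0{width}d}" for i in range(1, m + 1)]
    return ctrl, case


def generate_counts(config: SyntheticConfig) -> SyntheticCohort:
    """Two-arm negative-binomial counts with planted upregulated genes.

    Every gene shares its distribution across arms except the planted
    signature genes, whose mean is multiplied by ``signature_fold`` in the
    case arm only.
    """
    cfg = config.validate()
    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]

    lengths = pd.Series(
        _rng(cfg.seed, "lengths").integers(
            cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, cfg.n_genes
        ),
        index=genes,
        name="length",
    )

    means_rng = _rng(cfg.seed, "means")
    base_means = cfg.baseline_mean * means_rng.lognormal(
        0.0, GENE_MEAN_SIGMA, cfg.n_genes
    )
    planted_idx = np.sort(
        means_rng.choice(cfg.n_genes, cfg.n_signature_genes, replace=False)
    )
    planted = tuple(genes[i] for i in planted_idx)

    ctrl_ids, case_ids = _sample_ids(cfg)
    samples = ctrl_ids + case_ids
    mu = np.tile(base_means[:, None], (1, len(samples))).astype(float)
    mu[planted_idx, len(ctrl_ids):] *= cfg.signature_fold

    size = cfg.dispersion
    p = size / (size + mu)
    counts = _rng(cfg.seed, "counts").negative_binomial(size, p)

    cov_rng = _rng(cfg.seed, "covariates")
    metadata = pd.DataFrame(
        {
            "group": [CONTROL_ARM] * len(ctrl_ids) + [CASE_ARM] * len(case_ids),
            "age": np.round(cov_rng.normal(62.0, 8.0, len(samples)), 1),
            "stage": cov_rng.integers(1, 5, len(samples)),
            "location": cov_rng.choice(["left", "right"], len(samples)),
        },
        index=pd.Index(samples, name="sample_id"),
    )

    return SyntheticCohort(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=lengths,
        metadata=metadata,
        truth=PlantedTruth(signature_genes=planted, fold=cfg.signature_fold),
        config=cfg,
    )


def generate_bimodal_vector(
    n_low: int,
    n_high: int,
    mu_low: float,
    mu_high: float,
    sigma: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-component Gaussian mixture fixture for step fitting.

    Returns ``(values, is_high)`` where ``is_high`` records true component
    membership for threshold-recovery tests. Values are in generation
    order: the low block first, then the high block.
    """
    if n_low < 1 or n_high < 1:
        raise ConfigurationError(
            f"n_low and n_high must be >= 1, got {(n_low, n_high)}"
        )
    if not mu_low < mu_high:
        raise ConfigurationError(
            f"mu_low must be < mu_high, got {(mu_low, mu_high)}"
        )
    if sigma <= 0:
        raise ConfigurationError(f"sigma must be positive, got {sigma}")
    rng = np.random.default_rng(seed)
    values = np.concatenate(
        [rng.normal(mu_low, sigma, n_low), rng.normal(mu_high, sigma, n_high)]
    )
    is_high = np.concatenate([np.zeros(n_low, bool), np.ones(n_high, bool)])
    return values, is_high


def generate_survival(scores, config: SyntheticConfig) -> pd.DataFrame:
    """Exponential survival with hazard tied to the standardized score.

    hazard_i = BASE_HAZARD * exp(survival_link * z_i). A negative link
    therefore gives high-score samples longer expected survival. Censoring
    is independent: each sample is censored with probability
    ``censor_rate``, at a uniform fraction of its event time.
    """
    cfg = config.validate()
    s = pd.Series(np.asarray(scores, dtype=float))
    if isinstance(scores, pd.Series):
        s.index = scores.index
    if not np.all(np.isfinite(s)):
        raise InputError("scores must be finite")
    sd = s.std(ddof=0)
    z = (s - s.mean()) / sd if sd > 0 else s * 0.0
    hazard = BASE_HAZARD * np.exp(cfg.survival_link * z.to_numpy())
    rng = _rng(cfg.seed, "survival")
    times = rng.exponential(1.0 / hazard)
    event = rng.random(len(s)) >= cfg.censor_rate
    times = np.where(event, times, times * rng.random(len(s)))
    times = np.maximum(times, np.finfo(float).tiny)  # strictly positive
    return pd.DataFrame({"time": times, "event": event}, index=s.index)


def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Full cohort: counts, covariates, and score-linked survival.

    The survival-driving score is the composite signature score of the
    planted genes computed through the real pipeline (TPM, log transform,
    step thresholds, 3-sigma normalization).
    """
    from . import diffexpr, signature, stepminer

    cohort = generate_counts(config)
    logexpr = diffexpr.log_transform(
        diffexpr.tpm(cohort.counts, cohort.gene_lengths)
    )
    fits = stepminer.fit_matrix(logexpr.loc[list(cohort.truth.signature_genes)])
    norm = signature.normalize_expression(
        logexpr.loc[list(cohort.truth.signature_genes)], fits
    )
    scores = signature.composite_score(norm, cohort.truth.signature_genes).scores
    surv = generate_survival(scores, config)
    metadata = cohort.metadata.join(surv)
    return replace(cohort, metadata=metadata)
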