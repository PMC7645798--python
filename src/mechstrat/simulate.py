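"""Synthetic genotype cohorts with planted mechanism-structured cluster signal.

The generator emulates the statistical shape of a joint AD/PD discovery cohort
(486 AD + 358 PD patients, 148 SNPs in 15 mechanism groups) and a 561-patient
validation cohort. Each patient belongs to one of ``k_true`` latent clusters;
SNPs in mechanisms burdened by that cluster (a binary cluster × mechanism
*signature*) have their minor-allele frequency shifted upward by
``effect_delta``, so clusters differ in mechanism-level risk-allele load.
Dosages are Hardy–Weinberg binomial draws (no LD). Confounders (age, sex,
study) are drawn independently of cluster by default; clinical outcomes can
depend on cluster, confounders, and — longitudinally — on cluster-specific
progression slopes with a per-patient random intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import DEFAULT_GROUP_SIZES
from .io import GenotypeMatrix

__all__ = [
    "OutcomeSpec",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_validation_cohort",
    "generate_longitudinal",
    "cyclic_signature",
    "default_config",
]


class ConfigurationError(ValueError):
    """Raised when a synthetic-cohort configuration is internally inconsistent."""


def cyclic_signature(k: int, n_mechanisms: int) -> np.ndarray:
    """Binary cluster × mechanism matrix: cluster c burdens mechanisms c, c+k, c+2k…

    Every cluster is a mixture of several mechanisms and every mechanism is
    burdened by exactly one cluster.
    """
    sig = np.zeros((k, n_mechanisms), dtype=int)
    for m in range(n_mechanisms):
        sig[m % k, m] = 1
    return sig


@dataclass
class OutcomeSpec:
    """Generative law of one clinical outcome.

    ``cluster_means`` are baseline means per cluster (outcome units);
    ``slopes`` the per-visit change per cluster; ``sd`` the residual noise SD;
    ``random_intercept_sd`` the between-patient SD shared across visits;
    ``age_coef``/``sex_coef`` linear confounder effects on standardized age
    and on female sex.
    """

    cluster_means: tuple[float, ...]
    sd: float = 1.0
    slopes: tuple[float, ...] | None = None
    random_intercept_sd: float = 0.3
    age_coef: float = 0.2
    sex_coef: float = 0.1


@dataclass
class SyntheticConfig:
    """All constants of the synthetic study design.

    Defaults reproduce the emulated design: 486 + 358 discovery patients,
    561 validation patients, 148 SNPs over 15 mechanism groups, 4 planted
    clusters with a cyclic mechanism signature and a +0.2 MAF shift on
    burdened-mechanism SNPs.
    """

    n_patients_ad: int = 486
    n_patients_pd: int = 358
    n_validation: int = 561
    k_true: int = 4
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    maf_range: tuple[float, float] = (0.05, 0.35)
    signature: np.ndarray | None = None  # k_true x n_mechanisms binary; None -> cyclic
    effect_delta: float = 0.2
    cluster_proportions: tuple[float, ...] | None = None  # None -> uniform
    age_mean: float = 70.0
    age_sd: float = 8.0
    p_female: float = 0.45
    outcomes: dict[str, OutcomeSpec] = field(default_factory=dict)
    n_visits: int = 3
    missing_fraction: float = 0.0
    snp_ids: tuple[str, ...] | None = None  # None -> snp001.. matching group_sizes
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if any(g < 1 for g in self.group_sizes):
            raise ConfigurationError("all group_sizes must be >= 1")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple([1.0 / self.k_true] * self.k_true)
        self.cluster_proportions = tuple(float(p) for p in self.cluster_proportions)
        if len(self.cluster_proportions) != self.k_true:
            raise ConfigurationError("cluster_proportions length must equal k_true")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-8 or min(self.cluster_proportions) < 0:
            raise ConfigurationError("cluster_proportions must be a simplex vector")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.effect_delta < 0 or hi + self.effect_delta >= 1.0:
            raise ConfigurationError(
                "effect_delta must be >= 0 and keep all shifted frequencies below 1"
            )
        if self.signature is None:
            self.signature = cyclic_signature(self.k_true, self.n_mechanisms)
        self.signature = np.asarray(self.signature, dtype=int)
        if self.signature.shape != (self.k_true, self.n_mechanisms):
            raise ConfigurationError(
                f"signature must be {self.k_true} x {self.n_mechanisms}, "
                f"got {self.signature.shape}"
            )
        if self.snp_ids is None:
            self.snp_ids = tuple(f"snp{i + 1:03d}" for i in range(self.n_snps))
        self.snp_ids = tuple(self.snp_ids)
        if len(self.snp_ids) != self.n_snps:
            raise ConfigurationError("snp_ids length must equal sum(group_sizes)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        if not self.outcomes:
            self.outcomes = _default_outcomes(self.k_true)
        for name, spec in self.outcomes.items():
            if len(spec.cluster_means) != self.k_true:
                raise ConfigurationError(f"outcome {name!r}: cluster_means length != k_true")
            if spec.slopes is not None and len(spec.slopes) != self.k_true:
                raise ConfigurationError(f"outcome {name!r}: slopes length != k_true")

    @property
    def n_mechanisms(self) -> int:
        return len(self.group_sizes)

    @property
    def n_snps(self) -> int:
        return sum(self.group_sizes)

    @property
    def n_discovery(self) -> int:
        return self.n_patients_ad + self.n_patients_pd

    @property
    def mechanism_of_snp(self) -> np.ndarray:
        """Mechanism index (0-based) of every SNP column, per group_sizes blocks."""
        return np.repeat(np.arange(self.n_mechanisms), self.group_sizes)


def _default_outcomes(k: int) -> dict[str, OutcomeSpec]:
    # One outcome with a baseline shift in the last cluster, one with a
    # graded slope profile; means recycle if k != 4.
    def cyc(vals: Sequence[float]) -> tuple[float, ...]:
        return tuple(vals[i % len(vals)] for i in range(k))

    return {
        "cognition": OutcomeSpec(
            cluster_means=cyc([0.0, 0.0, 0.0, 1.0]),
            sd=1.0,
            slopes=cyc([0.0, 0.0, 0.5, 0.0]),
            random_intercept_sd=0.3,
        ),
        "motor": OutcomeSpec(
            cluster_means=cyc([0.0, 0.3, 0.6, 0.9]),
            sd=1.0,
            slopes=cyc([0.1, 0.1, 0.1, 0.1]),
            random_intercept_sd=0.3,
        ),
    }


def default_config(**overrides) -> SyntheticConfig:
    """The documented default study design; keyword overrides applied on top."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


@dataclass
class SyntheticCohort:
    """A generated cohort: genotypes, planted truth, confounders, outcomes."""

    genotypes: GenotypeMatrix
    true_labels: pd.Series  # planted cluster index per patient, 0-based
    covariates: pd.DataFrame  # age, sex, study
    outcomes: pd.DataFrame  # baseline outcome values per patient
    config: SyntheticConfig

    def __post_init__(self) -> None:
        n = self.genotypes.n_patients
        for tab in (self.true_labels, self.covariates, self.outcomes):
            if len(tab) != n:
                raise ValueError("row counts disagree across cohort tables")

    @property
    def n_patients(self) -> int:
        return self.genotypes.n_patients


def _baseline_mafs(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.n_snps)


def _draw_cohort(
    config: SyntheticConfig,
    n: int,
    mafs: np.ndarray,
    rng: np.random.Generator,
    prefix: str,
    studies: np.ndarray,
    diseases: np.ndarray,
) -> SyntheticCohort:
    k = config.k_true
    labels = rng.choice(k, size=n, p=config.cluster_proportions)
    mech_of = config.mechanism_of_snp
    # per-patient allele frequency: baseline + delta where the patient's
    # cluster signature burdens the SNP's mechanism
    shift = config.signature[labels][:, mech_of] * config.effect_delta  # (n, n_snps)
    freq = np.clip(mafs[None, :] + shift, 1e-9, 1 - 1e-9)
    dosages = rng.binomial(2, freq).astype(float)
    if config.missing_fraction > 0:
        mask = rng.random(dosages.shape) < config.missing_fraction
        dosages[mask] = np.nan

    patient_ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    geno = GenotypeMatrix(
        dosages=pd.DataFrame(dosages, index=patient_ids, columns=list(config.snp_ids)),
        cohort=pd.Series(studies, index=patient_ids, name="study"),
        disease=pd.Series(diseases, index=patient_ids, name="disease"),
    )
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = rng.random(n) < config.p_female  # True = female
    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(sex, "F", "M"),
            "study": studies,
        },
        index=patient_ids,
    )
    age_z = (age - config.age_mean) / config.age_sd
    outcome_cols = {}
    for name, spec in config.outcomes.items():
        mu = np.asarray(spec.cluster_means)[labels]
        outcome_cols[name] = (
            mu
            + spec.age_coef * age_z
            + spec.sex_coef * sex.astype(float)
            + rng.normal(0.0, spec.sd, size=n)
        )
    outcomes = pd.DataFrame(outcome_cols, index=patient_ids)
    return SyntheticCohort(
        genotypes=geno,
        true_labels=pd.Series(labels, index=patient_ids, name="true_cluster"),
        covariates=covariates,
        outcomes=outcomes,
        config=config,
    )


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate the discovery cohort (AD + PD patients, one genotype matrix).

    Cluster membership is drawn from ``cluster_proportions``; each dosage is
    Binomial(2, f) with f the SNP's baseline MAF plus ``effect_delta`` when
    the patient's cluster burdens the SNP's mechanism. Confounders are drawn
    independently of cluster. Fully reproducible from ``config.seed``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng([config.seed, 0])
    mafs = _baseline_mafs(config, np.random.default_rng([config.seed, 99]))
    n_ad, n_pd = config.n_patients_ad, config.n_patients_pd
    studies = np.array(["ADNI"] * n_ad + ["PPMI"] * n_pd)
    diseases = np.array(["AD"] * n_ad + ["PD"] * n_pd)
    return _draw_cohort(config, n_ad + n_pd, mafs, rng, "D", studies, diseases)


def generate_validation_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Generate the validation cohort from the identical generative law.

    Uses the same baseline MAFs and signature as :func:`generate_cohort` for
    the same config, but an independent random stream, emulating an external
    study of ``n_validation`` patients (default 561).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng([config.seed, 1])
    mafs = _baseline_mafs(config, np.random.default_rng([config.seed, 99]))
    n = config.n_validation
    # validation merges several external studies; a single label suffices here
    studies = np.array(["VALID"] * n)
    half = n // 2
    diseases = np.array(["AD"] * half + ["PD"] * (n - half))
    return _draw_cohort(config, n, mafs, rng, "V", studies, diseases)


def generate_longitudinal(
    cohort: SyntheticCohort, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Per-visit outcome table with cluster-specific slopes.

    For each outcome with a ``slopes`` entry, visit t (t = 0 … n_visits-1)
    yields ``baseline + slope[cluster]*t + b_i + noise`` where ``b_i`` is a
    per-patient normal random intercept. Returns a long table with columns
    ``patient_id``, ``visit`` and one column per outcome; planted slopes are
    stored in ``DataFrame.attrs["true_slopes"]``.
    """
    config = config or cohort.config
    if config.n_visits < 2:
        raise ConfigurationError("n_visits must be >= 2 for longitudinal outcomes")
    rng = np.random.default_rng([config.seed, 2])
    labels = cohort.true_labels.to_numpy()
    n = len(labels)
    visits = np.arange(config.n_visits)
    rows_pid = np.repeat(cohort.true_labels.index.to_numpy(), config.n_visits)
    rows_visit = np.tile(visits, n)
    table = pd.DataFrame({"patient_id": rows_pid, "visit": rows_visit})
    true_slopes: dict[str, tuple[float, ...]] = {}
    for name, spec in config.outcomes.items():
        if spec.slopes is None:
            continue
        slopes = np.asarray(spec.slopes)[labels]  # (n,)
        baseline = cohort.outcomes[name].to_numpy()
        b = rng.normal(0.0, spec.random_intercept_sd, size=n)
        noise = rng.normal(0.0, spec.sd, size=(n, config.n_visits))
        if spec.sd == 0:
            noise[:] = 0.0
        values = (
            baseline[:, None] + slopes[:, None] * visits[None, :] + b[:, None] + noise
        )
        table[name] = values.reshape(-1)
        true_slopes[name] = tuple(spec.slopes)
    table.attrs["true_slopes"] = true_slopes
    return table
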