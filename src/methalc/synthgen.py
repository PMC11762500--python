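"""Seeded synthetic DNAm cohorts with a known sparse CpG effect architecture.

The generator emulates the statistical structure a blood-methylation analysis
of alcohol consumption relies on, at desk scale:

* a samples x CpGs beta-value matrix with bimodal methylation states, batch
  shifts and cell-composition-like latent factors;
* a weekly alcohol-units phenotype whose log(units + 1) transform carries a
  planted sparse linear architecture on standardized M-values (logit of beta),
  in three effect-size tiers, plus age/sex/smoking covariate effects;
* a reporting mechanism in which the methylome tracks *habitual* intake while
  the questionnaire records *last-week* intake, which for a subset of
  "more"/"less" reporters deviates multiplicatively from habit.

Everything is driven by one integer seed fanned out into named substreams, so
cohorts are bit-reproducible (generator algorithm version in
``GENERATOR_VERSION``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

GENERATOR_VERSION = 1

#: variance tolerance when checking that planted per-CpG contributions fit
#: inside the total methylome variance target
_VAR_TOL = 1e-9

FLAG_STATES = ("normal", "more", "less", "unknown")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random substream of a single global seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class EffectArchitecture:
    """Sparse three-tier CpG effect architecture.

    ``var_fraction_*`` is the fraction of the (covariate-free) phenotypic
    variance a single causal CpG of that tier explains; the tiers default to
    the 0.01% / 0.1% / 1% scale the mixture-prior EWAS model assumes.  When
    the planted contributions sum to ``total_methylome_variance`` the per-CpG
    fractions are realized exactly (up to sampling noise); a smaller sum
    rescales them proportionally.
    """

    n_cpgs_small: int = 1000
    n_cpgs_medium: int = 300
    n_cpgs_large: int = 10
    var_fraction_small: float = 0.0001
    var_fraction_medium: float = 0.001
    var_fraction_large: float = 0.01
    total_methylome_variance: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_cpgs_small", "n_cpgs_medium", "n_cpgs_large"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in (
            "var_fraction_small",
            "var_fraction_medium",
            "var_fraction_large",
            "total_methylome_variance",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.planted_sum > self.total_methylome_variance + _VAR_TOL:
            raise ValueError(
                "sum of planted per-CpG variance contributions "
                f"({self.planted_sum:.4g}) exceeds total_methylome_variance "
                f"({self.total_methylome_variance:.4g})"
            )

    @property
    def n_causal(self) -> int:
        return self.n_cpgs_small + self.n_cpgs_medium + self.n_cpgs_large

    @property
    def planted_sum(self) -> float:
        return (
            self.n_cpgs_small * self.var_fraction_small
            + self.n_cpgs_medium * self.var_fraction_medium
            + self.n_cpgs_large * self.var_fraction_large
        )

    @classmethod
    def null(cls) -> "EffectArchitecture":
        return cls(n_cpgs_small=0, n_cpgs_medium=0, n_cpgs_large=0)


@dataclass(frozen=True)
class ReportingModel:
    """Last-week versus habitual intake reporting states.

    Default state probabilities follow the cohort accounting the pipeline is
    built around (62.8% normal week, 22.5% more, 9.7% less, remainder
    unknown).  Deviant reporters' last-week units are a multiplicative
    perturbation of habitual units with spread ``deviation_sd`` and a floor at
    zero; "more" reporters deviate upward, "less" downward.  When
    ``habitual_drives_methylome`` the CpG architecture acts on habitual
    intake (the questionnaire is then a noisy readout); otherwise the
    methylome tracks last-week intake directly.
    """

    p_normal: float = 0.628
    p_more: float = 0.225
    p_less: float = 0.097
    deviation_sd: float = 0.5
    habitual_drives_methylome: bool = True

    def __post_init__(self) -> None:
        for name in ("p_normal", "p_more", "p_less"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.p_normal + self.p_more + self.p_less > 1.0 + 1e-12:
            raise ValueError("reporting state probabilities sum above 1")
        if self.deviation_sd < 0:
            raise ValueError("deviation_sd must be nonnegative")

    @property
    def p_unknown(self) -> float:
        return max(0.0, 1.0 - self.p_normal - self.p_more - self.p_less)


@dataclass(frozen=True)
class CovariateEffects:
    """Covariate effects on log(units + 1), per SD of each covariate
    (sex effect per male indicator)."""

    age: float = -0.05
    sex: float = 0.35
    smoking: float = 0.15


@dataclass
class CohortTruth:
    """Ground truth recorded alongside a synthetic cohort."""

    effects: pd.Series            # standardized-M-scale effect per CpG (all CpGs)
    causal: dict                  # tier name -> list of CpG ids
    var_explained: float          # target methylome fraction of phenotypic variance
    realized_var_explained: float # R^2 of driver log-intake on the true score
    true_score: pd.Series         # per-sample planted methylome score (log scale)
    habitual_log: pd.Series       # per-sample habitual log(units + 1)
    habitual_units: pd.Series

    @property
    def causal_cpgs(self) -> list:
        out = []
        for tier in ("small", "medium", "large"):
            out.extend(self.causal.get(tier, []))
        return out


@dataclass
class SyntheticCohort:
    """A methylation matrix, a phenotype/covariate table and their truth."""

    methyl: pd.DataFrame  # samples x CpGs beta values in (0, 1)
    cohort: pd.DataFrame  # units_last_week, normal_week_flag, age, sex, batch, smoking_score
    truth: CohortTruth | None = None

    def __post_init__(self) -> None:
        if not self.methyl.index.equals(self.cohort.index):
            raise ValueError("methyl and cohort tables index different samples")
        if self.truth is not None:
            missing = set(self.truth.causal_cpgs) - set(self.methyl.columns)
            if missing:
                raise ValueError(f"causal CpGs absent from matrix: {sorted(missing)[:5]}")

    @property
    def n_samples(self) -> int:
        return self.methyl.shape[0]

    def subset(self, index) -> "SyntheticCohort":
        truth = self.truth
        if truth is not None:
            truth = replace(
                truth,
                true_score=truth.true_score.loc[index],
                habitual_log=truth.habitual_log.loc[index],
                habitual_units=truth.habitual_units.loc[index],
            )
        return SyntheticCohort(
            methyl=self.methyl.loc[index], cohort=self.cohort.loc[index], truth=truth
        )


def simulate_methylome(
    n_samples: int,
    n_cpgs: int,
    n_batches: int = 1,
    seed: int = 0,
    batch_shift_sd: float = 0.15,
    n_latent: int = 2,
    latent_sd: float = 0.15,
) -> pd.DataFrame:
    """Simulate a samples x CpGs beta-value matrix.

    Each CpG is assigned a methylation state (low / intermediate / high) with a
    state-specific mean on the M-value (logit) scale; additive per-batch shifts
    and cell-composition-like latent factors are added before mapping back
    through the logistic function, so beta values stay strictly in (0, 1)
    while all structure is linear on the M scale.

    The returned DataFrame carries generator metadata in ``.attrs``: the batch
    assignment (``batch``), planted per-(batch, CpG) shifts (``batch_shifts``)
    and the CpG state labels.
    """
    if n_samples < 2 or n_cpgs < 1 or n_batches < 1:
        raise ValueError("n_samples >= 2, n_cpgs >= 1 and n_batches >= 1 required")

    rng = substream(seed, "methylome")
    samples = pd.Index([f"S{i:06d}" for i in range(n_samples)], name="sample_id")
    cpgs = pd.Index([f"cg{i:08d}" for i in range(n_cpgs)], name="cpg")

    states = rng.choice(np.array(["low", "intermediate", "high"]), size=n_cpgs, p=[0.4, 0.2, 0.4])
    state_mean = {"low": -2.5, "intermediate": 0.0, "high": 2.5}
    state_sd = {"low": 0.5, "intermediate": 0.7, "high": 0.5}
    mu = np.array([rng.normal(state_mean[s], state_sd[s]) for s in states])

    batch = rng.integers(0, n_batches, size=n_samples)
    shifts = rng.normal(0.0, batch_shift_sd, size=(n_batches, n_cpgs))

    loadings = rng.normal(0.0, latent_sd, size=(n_latent, n_cpgs))
    factors = rng.standard_normal((n_samples, n_latent))

    noise_sd = rng.uniform(0.4, 0.8, size=n_cpgs)
    m_values = (
        mu[None, :]
        + shifts[batch, :]
        + factors @ loadings
        + rng.standard_normal((n_samples, n_cpgs)) * noise_sd[None, :]
    )
    beta = expit(m_values)

    df = pd.DataFrame(beta, index=samples, columns=cpgs)
    df.attrs["generator_version"] = GENERATOR_VERSION
    df.attrs["batch"] = pd.Series(batch, index=samples, name="batch")
    df.attrs["batch_shifts"] = pd.DataFrame(shifts, columns=cpgs)
    df.attrs["cpg_state"] = pd.Series(states, index=cpgs, name="state")
    return df


def to_m_values(methyl: pd.DataFrame) -> pd.DataFrame:
    """Logit transform of beta values (the M-value scale)."""
    return pd.DataFrame(
        logit(methyl.to_numpy()), index=methyl.index, columns=methyl.columns
    )


def simulate_phenotype(
    methyl: pd.DataFrame,
    arch: EffectArchitecture | None = None,
    report: ReportingModel | None = None,
    covariate_effects: CovariateEffects | None = None,
    seed: int = 0,
    intercept: float = 1.7,
    phenotype_sd: float = 0.8,
    age_mean: float = 47.5,
    age_sd: float = 14.9,
    p_male: float = 0.4163,
) -> SyntheticCohort:
    """Attach an alcohol phenotype with a planted CpG architecture.

    The driver log-intake is ``intercept + covariates + s * (g + e)`` where
    ``g`` is the planted score on standardized M-values, the noise ``e`` is
    scaled so ``g`` explains ``arch.total_methylome_variance`` of ``g + e``,
    and ``s`` brings the covariate-free phenotype SD to ``phenotype_sd`` log
    units.  Units are ``exp(driver) - 1`` floored at zero (the floor creates a
    realistic non-drinker mass).  Last-week reported units then follow the
    reporting model.
    """
    arch = arch or EffectArchitecture()
    report = report or ReportingModel()
    eff = covariate_effects or CovariateEffects()

    n, p = methyl.shape
    if arch.n_causal > p:
        raise ValueError(f"architecture wants {arch.n_causal} causal CpGs, matrix has {p}")

    # causal effects act on the biological M-value component: technical batch
    # shifts live only in the measured matrix and must not drive the phenotype
    z = to_m_values(methyl).to_numpy()
    batch_attr = methyl.attrs.get("batch")
    shifts = methyl.attrs.get("batch_shifts")
    if batch_attr is not None and shifts is not None:
        z = z - shifts.to_numpy()[batch_attr.to_numpy(), :]
    z = (z - z.mean(axis=0)) / z.std(axis=0)

    rng_eff = substream(seed, "effects")
    beta = np.zeros(p)
    order = rng_eff.choice(p, size=arch.n_causal, replace=False)
    tiers = {
        "small": (arch.n_cpgs_small, arch.var_fraction_small),
        "medium": (arch.n_cpgs_medium, arch.var_fraction_medium),
        "large": (arch.n_cpgs_large, arch.var_fraction_large),
    }
    causal: dict[str, list] = {}
    pos = 0
    for tier, (count, vfrac) in tiers.items():
        idx = order[pos : pos + count]
        beta[idx] = np.sqrt(vfrac) * rng_eff.choice([-1.0, 1.0], size=count)
        causal[tier] = list(methyl.columns[np.sort(idx)])
        pos += count

    g = z @ beta
    v_target = arch.total_methylome_variance
    var_g = g.var()
    rng_noise = substream(seed, "phenotype_noise")
    if var_g > 0 and v_target > 0:
        var_e = var_g * (1.0 - v_target) / v_target
        e = rng_noise.normal(0.0, np.sqrt(var_e), size=n)
        scale = phenotype_sd / np.sqrt(var_g + var_e)
    else:
        g = np.zeros(n)
        e = rng_noise.standard_normal(n)
        scale = phenotype_sd

    rng_cov = substream(seed, "covariates")
    age = np.clip(rng_cov.normal(age_mean, age_sd, size=n), 18.0, 99.0)
    male = rng_cov.random(n) < p_male
    smoking = rng_cov.standard_normal(n)

    cov_part = (
        eff.age * (age - age_mean) / age_sd
        + eff.sex * male.astype(float)
        + eff.smoking * smoking
    )
    driver_log = intercept + cov_part + scale * (g + e)
    driver_units = np.maximum(np.expm1(driver_log), 0.0)

    rng_rep = substream(seed, "reporting")
    probs = [report.p_normal, report.p_more, report.p_less, report.p_unknown]
    flag = rng_rep.choice(np.array(FLAG_STATES), size=n, p=probs)
    dev = np.abs(rng_rep.normal(0.0, report.deviation_sd, size=n))
    factor = np.ones(n)
    factor[flag == "more"] = 1.0 + dev[flag == "more"]
    factor[flag == "less"] = np.maximum(0.0, 1.0 - dev[flag == "less"])
    deviated_units = driver_units * factor

    if report.habitual_drives_methylome:
        habitual_units, reported_units = driver_units, deviated_units
    else:
        # methylome tracks what is reported; habit is the perturbed quantity
        habitual_units, reported_units = deviated_units, driver_units

    realized = 0.0
    if g.var() > 0:
        realized = float(np.corrcoef(driver_log, g)[0, 1] ** 2)

    samples = methyl.index
    batch = methyl.attrs.get("batch")
    batch = batch.to_numpy() if batch is not None else np.zeros(n, dtype=int)
    cohort = pd.DataFrame(
        {
            "units_last_week": reported_units,
            "normal_week_flag": flag,
            "age": age,
            "sex": np.where(male, "M", "F"),
            "batch": batch,
            "smoking_score": smoking,
        },
        index=samples,
    )
    truth = CohortTruth(
        effects=pd.Series(beta * scale, index=methyl.columns, name="effect"),
        causal=causal,
        var_explained=v_target if arch.n_causal else 0.0,
        realized_var_explained=realized,
        true_score=pd.Series(scale * g, index=samples, name="true_score"),
        habitual_log=pd.Series(np.log1p(habitual_units), index=samples, name="habitual_log"),
        habitual_units=pd.Series(habitual_units, index=samples, name="habitual_units"),
    )
    return SyntheticCohort(methyl=methyl, cohort=cohort, truth=truth)


def split_cohort(
    cohort: SyntheticCohort,
    fractions: tuple[float, float] = (0.52, 0.48),
    stratify_by: str | None = None,
    seed: int = 0,
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Disjoint, exhaustive train/test partition (sizes by round(f * n)).

    With ``stratify_by`` naming a cohort-table column, the split is done per
    stratum, preserving stratum proportions within one sample.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = substream(seed, "split")
    index = cohort.cohort.index

    def _pick(idx: pd.Index) -> pd.Index:
        n_train = int(round(fractions[0] * len(idx)))
        perm = rng.permutation(len(idx))
        return idx[np.sort(perm[:n_train])]

    if stratify_by is None:
        train_idx = _pick(index)
    else:
        parts = []
        for _, sub in cohort.cohort.groupby(stratify_by, sort=True):
            parts.append(_pick(sub.index))
        train_idx = index[index.isin(np.concatenate([p.to_numpy() for p in parts]))]

    test_idx = index[~index.isin(train_idx)]
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("split produced an empty partition")
    return cohort.subset(train_idx), cohort.subset(test_idx)
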