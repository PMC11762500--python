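"""DNAm EpiScores: elastic-net training, projection, and evaluation.

An EpiScore is a sparse weighted sum of standardized CpG beta values
predicting log(units + 1) of weekly alcohol consumption.  Training follows
the standard recipe: candidate CpGs are optionally pre-filtered (to a
prior-evidence list and/or a 450K-array intersection), mean-imputed,
standardized to mean zero / unit variance, and fed to an elastic net with
mixing parameter alpha = 0.5 whose shrinkage parameter lambda is chosen by
k-fold cross-validation at the minimum mean CV squared error.  Evaluation
reports the Pearson correlation of score with log units and the incremental
R^2 over an age + sex linear model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
import statsmodels.api as sm

from .phenotype import log_units
from .synthgen import SyntheticCohort

logger = logging.getLogger(__name__)


@dataclass
class EpiScoreModel:
    """Portable sparse CpG predictor (standardized-scale weights)."""

    weights: pd.Series        # nonzero coefficients only, indexed by CpG
    feature_means: pd.Series  # training means for the weighted CpGs
    feature_sds: pd.Series    # training SDs (all > 0)
    intercept: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (
            self.weights.index.equals(self.feature_means.index)
            and self.weights.index.equals(self.feature_sds.index)
        ):
            raise ValueError("weights, means and sds index different CpGs")
        if (self.feature_sds <= 0).any():
            raise ValueError("standardization SDs must be positive")

    @property
    def n_features(self) -> int:
        return int((self.weights != 0).sum())


@dataclass
class EvaluationReport:
    """Pearson r / incremental R^2 surface for one (score, subset) pair."""

    n: int
    pearson_r: float
    incremental_r2: float  # percent scale
    marginal_p: float
    subset_label: str = ""


def preselect_features(matrix: pd.DataFrame, cpg_list) -> pd.DataFrame:
    """Restrict the matrix to CpGs on a prior-evidence pre-selection list.

    Column order follows the list where present.  Empty intersection is an
    error: there would be nothing to train on.
    """
    cpg_list = list(dict.fromkeys(cpg_list))  # dedupe, keep order
    if not cpg_list:
        raise ValueError("CpG pre-selection list is empty")
    present = [c for c in cpg_list if c in matrix.columns]
    if not present:
        raise ValueError("pre-selection list has no CpGs in common with the matrix")
    logger.info("pre-selection retained %d of %d listed CpGs", len(present), len(cpg_list))
    return matrix.loc[:, present]


def intersect_450k(matrix: pd.DataFrame, probe_list) -> pd.DataFrame:
    """Restrict to probes also present on the smaller (450K-style) array."""
    uniq = list(dict.fromkeys(probe_list))
    if len(uniq) < len(list(probe_list)):
        warnings.warn("duplicate probe identifiers in list; deduplicated")
    return preselect_features(matrix, uniq)


def impute_missing(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute missing entries per CpG across all samples."""
    if not matrix.isna().any().any():
        return matrix
    fully_missing = matrix.columns[matrix.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"CpG(s) with no observed values: {list(fully_missing)[:5]}")
    return matrix.fillna(matrix.mean(axis=0))


def train_elastic_net(
    X: pd.DataFrame,
    y,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-3,
    max_iter: int = 1000,
    meta: dict | None = None,
) -> EpiScoreModel:
    """Fit a cross-validated elastic net on standardized CpG values.

    ``alpha`` is the L1/L2 mixing parameter; the lambda path (``n_lambdas``
    values down to ``lambda_min_ratio`` of the null-model lambda) is scored by
    ``folds``-fold CV with a seeded random fold assignment, and the lambda
    with minimum mean CV squared error wins (ties broken toward the smallest,
    i.e. densest, lambda).  Zero-variance CpGs are dropped with a warning;
    constant y is an error.
    """
    y_arr = np.asarray(y, dtype=float)
    n = len(y_arr)
    if n < folds:
        raise ValueError(f"n={n} below number of CV folds ({folds})")
    if np.std(y_arr) == 0:
        raise ValueError("outcome is constant; nothing to fit")
    if X.isna().any().any():
        raise ValueError("X contains missing values; run impute_missing first")

    sds = X.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance CpG(s)")
        X = X.loc[:, keep]
        sds = sds[keep]
    means = X.mean(axis=0)
    Z = (X - means) / sds

    cv = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambdas,
        eps=lambda_min_ratio,
        tol=tol,
        max_iter=max_iter,
        cv=KFold(folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # path-end convergence chatter
        cv.fit(Z.to_numpy(), y_arr)

    mean_mse = cv.mse_path_.mean(axis=1)
    best = mean_mse.min()
    tied = np.flatnonzero(mean_mse <= best * (1 + 1e-12))
    lam = float(cv.alphas_[tied].min())  # smallest lambda among ties

    if lam == cv.alpha_:
        coef, intercept = cv.coef_, float(cv.intercept_)
    else:
        fit = ElasticNet(alpha=lam, l1_ratio=alpha, tol=tol, max_iter=max_iter).fit(
            Z.to_numpy(), y_arr
        )
        coef, intercept = fit.coef_, float(fit.intercept_)

    nz = coef != 0
    model = EpiScoreModel(
        weights=pd.Series(coef[nz], index=X.columns[nz], name="weight"),
        feature_means=means[X.columns[nz]],
        feature_sds=sds[X.columns[nz]],
        intercept=intercept,
        meta={
            "alpha": alpha,
            "lambda": lam,
            "n_train": n,
            "folds": folds,
            "seed": seed,
            **(meta or {}),
        },
    )
    logger.info("elastic net selected %d features at lambda=%.5g", model.n_features, lam)
    return model


def project(
    model: EpiScoreModel,
    matrix: pd.DataFrame,
    standardize: str = "target",
) -> pd.Series:
    """Project an EpiScore into a cohort: sum of weight x standardized value.

    ``standardize='target'`` (default) scales each CpG with the target
    cohort's own mean/SD, matching how such scores are normally deployed;
    ``'training'`` reuses the stored training parameters.  Model CpGs absent
    from the matrix are skipped with a logged count; no overlap is an error.
    """
    if len(model.weights) == 0:
        # null model (all coefficients shrunk away): constant zero score
        return pd.Series(0.0, index=matrix.index, name="episcore")
    overlap = model.weights.index.intersection(matrix.columns)
    if len(overlap) == 0:
        raise ValueError("no model CpGs present in the target matrix")
    n_missing = len(model.weights) - len(overlap)
    if n_missing:
        logger.warning("projection missing %d of %d model CpGs", n_missing, len(model.weights))

    vals = matrix.loc[:, overlap].to_numpy(dtype=float)
    if standardize == "target":
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)
        sd[sd == 0] = 1.0
    elif standardize == "training":
        mu = model.feature_means[overlap].to_numpy()
        sd = model.feature_sds[overlap].to_numpy()
    else:
        raise ValueError("standardize must be 'target' or 'training'")
    z = (vals - mu) / sd
    score = z @ model.weights[overlap].to_numpy()
    return pd.Series(score, index=matrix.index, name="episcore")


def evaluate(score, units, age, sex, subset_label: str = "") -> EvaluationReport:
    """r and incremental R^2 of a score against log(units + 1).

    incremental R^2 (percent) = 100 * [R^2(log units ~ age + sex + score)
    - R^2(log units ~ age + sex)]; the p-value is the two-sided marginal test
    for the score coefficient in the full model.
    """
    score = np.asarray(score, dtype=float)
    y = log_units(np.asarray(units, dtype=float))
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 complete cases")
    if np.std(score) == 0 or np.std(y) == 0:
        raise ValueError("constant score or outcome; correlation undefined")

    sex_num = _encode_sex(sex)
    base = sm.add_constant(np.column_stack([np.asarray(age, float), sex_num]))
    full = np.column_stack([base, score])
    fit_base = sm.OLS(y, base).fit()
    fit_full = sm.OLS(y, full).fit()
    return EvaluationReport(
        n=n,
        pearson_r=float(np.corrcoef(score, y)[0, 1]),
        incremental_r2=float(100.0 * (fit_full.rsquared - fit_base.rsquared)),
        marginal_p=float(fit_full.pvalues[-1]),
        subset_label=subset_label,
    )


def _encode_sex(sex) -> np.ndarray:
    arr = np.asarray(sex)
    if arr.dtype.kind in "OUS":
        return (arr == "M").astype(float)
    return arr.astype(float)


def design_grid(
    train: SyntheticCohort,
    test: SyntheticCohort,
    feature_sets: dict | None = None,
    training_subsets: dict | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Train one model per (feature set x training subset) and evaluate each
    on the full test set and every normal-week-flag stratum.

    ``feature_sets`` maps a label to a CpG list (or None for all CpGs);
    ``training_subsets`` maps a label to a boolean mask over the training
    cohort (or None for everyone).  Returns a tidy frame with one row per
    (model, evaluation subset) and the selected-feature count.
    """
    feature_sets = feature_sets or {"all": None}
    training_subsets = training_subsets or {
        "everyone": None,
        "normal_week": (train.cohort["normal_week_flag"] == "normal").to_numpy(),
    }
    rows = []
    models = {}
    for fs_label, cpgs in feature_sets.items():
        for ts_label, mask in training_subsets.items():
            sub = train if mask is None else train.subset(train.cohort.index[mask])
            if sub.n_samples == 0:
                warnings.warn(f"empty training subset {ts_label!r}; skipped")
                continue
            X = sub.methyl if cpgs is None else preselect_features(sub.methyl, cpgs)
            model = train_elastic_net(
                impute_missing(X),
                log_units(sub.cohort["units_last_week"].to_numpy()),
                seed=seed,
                meta={"feature_set": fs_label, "training_subset": ts_label},
                **fit_kwargs,
            )
            models[(fs_label, ts_label)] = model
            if model.n_features == 0:
                warnings.warn(
                    f"null model for ({fs_label}, {ts_label}); evaluation skipped"
                )
                continue
            score = project(model, test.methyl)
            for ev_label, ev_idx in _test_subsets(test).items():
                if len(ev_idx) < 4:
                    continue
                rep = evaluate(
                    score.loc[ev_idx],
                    test.cohort.loc[ev_idx, "units_last_week"],
                    test.cohort.loc[ev_idx, "age"],
                    test.cohort.loc[ev_idx, "sex"],
                    subset_label=ev_label,
                )
                rows.append(
                    {
                        "feature_set": fs_label,
                        "training_subset": ts_label,
                        "n_train": sub.n_samples,
                        "n_selected": model.n_features,
                        "eval_subset": ev_label,
                        "n": rep.n,
                        "r": rep.pearson_r,
                        "incremental_r2": rep.incremental_r2,
                        "p": rep.marginal_p,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["models"] = models
    return out


def _test_subsets(test: SyntheticCohort) -> dict:
    flag = test.cohort["normal_week_flag"]
    subsets = {"all": test.cohort.index}
    for state in ("normal", "more", "less"):
        subsets[state] = test.cohort.index[flag == state]
    return subsets


def sex_specific_designs(
    train: SyntheticCohort,
    test: SyntheticCohort,
    feature_set=None,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[dict, pd.DataFrame]:
    """Sex-specific, opposite-sex and sex-agnostic EpiScores at matched n.

    All three training sets have size min(n_F, n_M): the smaller sex uses all
    its samples, the larger a seeded random subsample, and the sex-agnostic
    set is an even (floor/ceil) male/female split.  Each test sex is scored
    under three modes: own-sex model, opposite-sex model, and the agnostic
    model.  Returns the three models and a tidy per-(sex, mode) report.
    """
    rng = np.random.default_rng([seed, 0x5E5])
    sexes = train.cohort["sex"]
    idx_f = train.cohort.index[sexes == "F"]
    idx_m = train.cohort.index[sexes == "M"]
    if len(idx_f) == 0 or len(idx_m) == 0:
        raise ValueError("both sexes must be present in the training cohort")
    size = min(len(idx_f), len(idx_m))

    def _sample(idx, k):
        if k >= len(idx):
            return idx
        return idx[np.sort(rng.choice(len(idx), size=k, replace=False))]

    train_sets = {
        "F": _sample(idx_f, size),
        "M": _sample(idx_m, size),
        "agnostic": _sample(idx_f, size // 2).append(_sample(idx_m, size - size // 2)),
    }
    models = {}
    for label, idx in train_sets.items():
        sub = train.subset(idx)
        X = sub.methyl if feature_set is None else preselect_features(sub.methyl, feature_set)
        models[label] = train_elastic_net(
            impute_missing(X),
            log_units(sub.cohort["units_last_week"].to_numpy()),
            seed=seed,
            meta={"training_subset": f"sex:{label}", "n_train": len(idx)},
            **fit_kwargs,
        )

    rows = []
    for sex in ("F", "M"):
        idx = test.cohort.index[test.cohort["sex"] == sex]
        if len(idx) < 4:
            continue
        other = "M" if sex == "F" else "F"
        for mode, model in (
            ("sex_specific", models[sex]),
            ("opposite_sex", models[other]),
            ("sex_agnostic", models["agnostic"]),
        ):
            if model.n_features == 0:
                warnings.warn(f"null model for mode {mode!r}; evaluation skipped")
                continue
            score = project(model, test.methyl.loc[idx])
            rep = evaluate(
                score,
                test.cohort.loc[idx, "units_last_week"],
                test.cohort.loc[idx, "age"],
                test.cohort.loc[idx, "sex"],
                subset_label=f"{sex}/{mode}",
            )
            rows.append(
                {
                    "test_sex": sex,
                    "mode": mode,
                    "n": rep.n,
                    "r": rep.pearson_r,
                    "incremental_r2": rep.incremental_r2,
                    "p": rep.marginal_p,
                }
            )
    return models, pd.DataFrame(rows)
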