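"""Bayesian mixture-prior regression for joint-conditional EWAS and
methylome variance partitioning.

The model regresses a residualized phenotype jointly on all standardized CpG
M-values with a spike-and-slab mixture prior on each effect:

    y = X beta + eps,  eps ~ N(0, sigma2_e I)
    beta_j ~ pi_0 delta_0 + sum_k pi_k N(0, gamma_k)

with mixture variances gamma_k = 0.0001, 0.001, 0.01 by default.  With y
scaled to unit variance these are literal fractions of phenotypic variance, so
the three slabs correspond to CpGs explaining 0.01%, 0.1% and 1% of the
phenotype.  A Gibbs chain (see ``_gibbs``) yields per-CpG posterior
inclusion probabilities (PIP: fraction of used draws with a nonzero effect),
mixture occupancies, and per-draw variance explained var(X beta)/var(y)
(with the sum-of-squares accounting sum_j beta_j^2 reported alongside),
whose posterior mean and equal-tailed 95% credible interval form the
variance component estimate.  Geweke z-scores diagnose chain convergence.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._gibbs import run_chain
from .phenotype import residualize

DEFAULT_MIXTURE_VARIANCES = (0.0001, 0.001, 0.01)


@dataclass
class BayesRConfig:
    """Chain and prior settings for the mixture-prior sampler.

    ``draws_retained`` post-burn-in sweeps are thinned by ``thin``; summaries
    use the last ``used_iterations`` of the stored draws (set it to None to
    use all of them).  ``fixed_sigma2`` / ``fixed_pi`` freeze the residual
    variance or mixture proportions at given values instead of sampling them
    — used by the closed-form conjugate oracles in the test-suite, not in
    ordinary analyses.
    """

    mixture_variances: tuple = DEFAULT_MIXTURE_VARIANCES
    burn_in: int = 5000
    draws_retained: int = 10000
    thin: int = 5
    used_iterations: int | None = 1000
    pip_threshold: float = 0.95
    seed: int = 0
    nu0: float = 2.0            # scaled-inv-chi2 prior dof for sigma2_e
    s0sq: float | None = None   # prior scale; default var(y)/2
    fixed_sigma2: float | None = None
    fixed_pi: tuple | None = None

    def __post_init__(self) -> None:
        gam = np.asarray(self.mixture_variances, dtype=float)
        if gam.ndim != 1 or len(gam) == 0 or np.any(gam <= 0) or np.any(np.diff(gam) <= 0):
            raise ValueError("mixture_variances must be strictly increasing positives")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.pip_threshold < 1.0:
            raise ValueError("pip_threshold must be in (0, 1)")
        if self.burn_in < 0 or self.draws_retained < 1:
            raise ValueError("burn_in >= 0 and draws_retained >= 1 required")
        if self.fixed_pi is not None and len(self.fixed_pi) != len(gam) + 1:
            raise ValueError("fixed_pi must have one entry per component incl. null")

    @property
    def n_stored(self) -> int:
        return (self.draws_retained + self.thin - 1) // self.thin


@dataclass
class ChainStore:
    """Thinned post-burn-in draws from one Gibbs chain."""

    betas: np.ndarray    # (n_stored, p)
    components: np.ndarray  # (n_stored, p) int8; 0 = null
    sigma2: np.ndarray   # (n_stored,)
    pi: np.ndarray       # (n_stored, K+1)
    fit_var: np.ndarray  # (n_stored,) var(X beta) per stored draw
    cpg_ids: pd.Index
    y_variance: float    # variance of the phenotype the chain saw
    config: BayesRConfig


@dataclass
class BayesRPosterior:
    """Per-CpG posterior summaries plus variance-explained draws."""

    table: pd.DataFrame          # mean_beta, se, pip, occ_null, occ_k...
    var_explained_draws: np.ndarray  # var(X beta)/var(y) per used draw
    var_explained_mean: float
    var_explained_ci: tuple      # equal-tailed 2.5 / 97.5 percentiles
    sum_sq_draws: np.ndarray     # sum_j beta_j^2 / var(y) per used draw
    sum_sq_mean: float
    n_used: int


def precorrect(
    methyl_m: pd.DataFrame,
    units,
    covariates: pd.DataFrame,
    batch=None,
    scale_y: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Residualize phenotype and M-values on covariates, standardize X.

    The phenotype is log(units + 1) residualized on the covariates (age, sex,
    smoking score...).  Each M-value column is residualized on the covariates
    plus one-hot batch, then scaled to mean zero / unit variance; columns left
    with (near) zero variance are dropped with a warning.  With ``scale_y``
    the residual phenotype is also scaled to unit variance, making the
    mixture variances literal fractions of phenotypic variance.
    """
    y = np.log1p(np.asarray(units, dtype=float))
    C = _covariate_design(covariates)
    y_resid = residualize(y, C)

    Cx = C
    if batch is not None:
        b = pd.get_dummies(pd.Series(np.asarray(batch), name="batch"), prefix="batch")
        if b.shape[1] > 1:
            Cx = np.column_stack([C, b.to_numpy(dtype=float)[:, 1:]])

    X = methyl_m.to_numpy(dtype=float)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(len(y)), Cx]))
    Xr = X - Q @ (Q.T @ X)
    sd = Xr.std(axis=0)
    keep = sd > 1e-10
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} CpG(s) with no residual variance"
        )
    Xr = (Xr[:, keep] - Xr[:, keep].mean(axis=0)) / sd[keep]
    if scale_y:
        y_resid = y_resid / y_resid.std()
    return (
        pd.DataFrame(Xr, index=methyl_m.index, columns=methyl_m.columns[keep]),
        pd.Series(y_resid, index=methyl_m.index, name="y_resid"),
    )


def _covariate_design(covariates) -> np.ndarray:
    if isinstance(covariates, pd.DataFrame):
        cols = []
        for c in covariates.columns:
            v = covariates[c]
            if v.dtype.kind in "OUS":
                cols.append((v.to_numpy() == "M").astype(float))
            else:
                cols.append(v.to_numpy(dtype=float))
        return np.column_stack(cols)
    return np.asarray(covariates, dtype=float)


def _id_hashes(ids) -> np.ndarray:
    """Stable 64-bit hash per CpG identifier; keys the per-sweep update order
    to identities (so column permutations permute the chain exactly)."""
    out = np.empty(len(ids), dtype=np.uint64)
    for i, cpg in enumerate(ids):
        out[i] = int.from_bytes(
            hashlib.blake2b(str(cpg).encode(), digest_size=8).digest(), "little"
        )
    return out


def gibbs_sample(X_std: pd.DataFrame, y_resid, config: BayesRConfig) -> ChainStore:
    """Run the single-site Gibbs chain; deterministic for a fixed seed."""
    X = X_std.to_numpy(dtype=float)
    y = np.asarray(y_resid, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X and y have mismatched sample counts")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in sampler input")

    y_var = float(np.var(y))
    s0sq = config.s0sq if config.s0sq is not None else y_var / 2.0
    fixed_pi = (
        np.asarray(config.fixed_pi, dtype=float)
        if config.fixed_pi is not None
        else np.empty(0)
    )
    betas, comps, sigma2, pi, fit_var = run_chain(
        np.ascontiguousarray(X.T),
        y,
        _id_hashes(X_std.columns),
        np.asarray(config.mixture_variances, dtype=float),
        config.burn_in + config.draws_retained,
        config.burn_in,
        config.thin,
        float(config.nu0),
        float(s0sq),
        int(config.seed),
        float(config.fixed_sigma2) if config.fixed_sigma2 is not None else -1.0,
        fixed_pi,
    )
    return ChainStore(
        betas=betas,
        components=comps,
        sigma2=sigma2,
        pi=pi,
        fit_var=fit_var,
        cpg_ids=X_std.columns,
        y_variance=y_var,
        config=config,
    )


def summarize(chains: ChainStore, used_iterations: int | None = None) -> BayesRPosterior:
    """Posterior summaries from the last ``used_iterations`` stored draws.

    Per CpG: posterior mean effect, posterior SD (se), PIP (fraction of used
    draws in any nonzero component) and mixture occupancy fractions.  The
    variance component per draw is var(X beta)/var(y), the model-implied
    fraction of phenotypic variance explained; the sum-of-squares accounting
    sum_j beta_j^2 / var(y) is reported alongside (the two coincide when CpG
    columns are uncorrelated, but the sum of squares is unstable under
    correlated columns because cancelling or aligned coefficient pairs move
    it without changing the fit).
    """
    used = used_iterations if used_iterations is not None else chains.config.used_iterations
    n_stored = chains.betas.shape[0]
    if used is None or used > n_stored:
        used = n_stored
    if used < 2:
        raise ValueError("need at least 2 used iterations to summarize")

    betas = chains.betas[-used:]
    comps = chains.components[-used:]
    K = chains.pi.shape[1] - 1

    y_var = chains.y_variance if chains.y_variance > 0 else 1.0
    ve = chains.fit_var[-used:] / y_var
    sum_sq = (betas**2).sum(axis=1) / y_var
    occ = {"occ_null": (comps == 0).mean(axis=0)}
    for k in range(1, K + 1):
        occ[f"occ_{k}"] = (comps == k).mean(axis=0)
    table = pd.DataFrame(
        {
            "mean_beta": betas.mean(axis=0),
            "se": betas.std(axis=0, ddof=0),
            "pip": (comps > 0).mean(axis=0),
            **occ,
        },
        index=chains.cpg_ids,
    )
    lo, hi = np.percentile(ve, [2.5, 97.5])
    return BayesRPosterior(
        table=table,
        var_explained_draws=ve,
        var_explained_mean=float(ve.mean()),
        var_explained_ci=(float(lo), float(hi)),
        sum_sq_draws=sum_sq,
        sum_sq_mean=float(sum_sq.mean()),
        n_used=used,
    )


def call_significant(posterior: BayesRPosterior, threshold: float = 0.95) -> pd.DataFrame:
    """Lead CpGs with PIP strictly above the threshold, sorted by PIP
    descending then identifier."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    hits = posterior.table[posterior.table["pip"] > threshold].copy()
    hits = hits.sort_values(["pip"], ascending=False, kind="mergesort")
    order = sorted(
        hits.index, key=lambda c: (-hits.loc[c, "pip"], c)
    )
    return hits.loc[order]


def geweke(chain, frac_first: float = 0.1, frac_last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late chain segments.

    z = (mean_first - mean_last) / sqrt(var_first + var_last) where each
    segment's variance of the mean uses a batch-means spectral estimate
    (robust to autocorrelation).  A constant chain returns 0 with a warning.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    n1 = int(np.floor(frac_first * n))
    n2 = int(np.floor(frac_last * n))
    if n1 < 10 or n2 < 10:
        raise ValueError("each Geweke segment needs at least 10 draws")
    if n1 + n2 > n:
        raise ValueError("Geweke segments overlap; shrink the fractions")
    a, b = x[:n1], x[n - n2 :]
    if np.ptp(x) == 0:
        warnings.warn("constant chain; Geweke z defined as 0")
        return 0.0
    va = _batch_means_var(a)
    vb = _batch_means_var(b)
    denom = np.sqrt(va + vb)
    if denom == 0:
        warnings.warn("zero spectral variance; Geweke z defined as 0")
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _batch_means_var(x: np.ndarray) -> float:
    """Batch-means estimate of Var(mean(x)) under autocorrelation."""
    n = len(x)
    b = max(1, int(np.floor(np.sqrt(n))))
    m = n // b
    means = x[: m * b].reshape(m, b).mean(axis=1)
    if m < 2:
        return float(x.var(ddof=1) / n)
    return float(means.var(ddof=1) / m)


def autocorrelation(chain, max_lag: int = 20) -> pd.Series:
    """Lag-k autocorrelation table for chain inspection."""
    x = np.asarray(chain, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return pd.Series(np.zeros(max_lag + 1), index=range(max_lag + 1), name="acf")
    acf = [1.0] + [float(x[k:] @ x[:-k]) / denom for k in range(1, max_lag + 1)]
    return pd.Series(acf, index=range(max_lag + 1), name="acf")
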