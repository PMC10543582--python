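"""ComBat empirical-Bayes harmonization of scanner/site batch effects.

ComBat models the observed value of feature v for subject j measured on
scanner (batch) i as

    y(i,j,v) = alpha(v) + X(i,j)·beta(v) + gamma(i,v) + delta(i,v)·eps(i,j,v)

where alpha is the feature intercept, X the biological covariates (age,
diagnostic group, optionally sex), gamma and delta the additive and
multiplicative scanner effects, and eps ~ N(0, sigma²(v)).  Fitting proceeds
in three stages:

1. **Standardization** — per-feature least squares of intercept + covariates +
   batch indicators under the identifiability constraint Σ_i n_i·gamma_i = 0,
   giving alphâ, betâ and the pooled residual scale sigmâ (root-mean-square
   residual, 1/N convention); standardized data
   z = (y − alphâ − X·betâ)/sigmâ.
2. **Empirical Bayes** — per-batch location/scale estimates gammâ(i,v)
   (batch mean of z) and deltâ²(i,v) (batch variance of z, 1/n_i convention)
   are shrunk across features toward batch-level priors: a normal prior on
   gamma (hyperparameters by moments of gammâ over features) and an
   inverse-gamma prior on delta² (hyperparameters by method of moments),
   solved by iterating the conditional posterior means to a fixed point.
3. **Reconstruction** — harmonized values
   y* = sigmâ·(z − gamma*)/delta* + alphâ + X·betâ, which removes the
   scanner location/scale effects while restoring the covariate structure.

The 1/n (not 1/(n−1)) variance convention is used consistently for sigmâ and
deltâ; mixing conventions silently breaks the single-batch identity
(harmonized == input when there is nothing to harmonize).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 100


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class DesignInfo:
    """Batch assignment and biological-covariate design for a cohort.

    ``batch`` is a label per subject; ``covariates`` a numeric subjects ×
    p frame (already coded: e.g. group as a 0/1 indicator).  Every batch must
    contain at least two subjects so its scale is estimable.
    """

    batch: pd.Series
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.batch = pd.Series(self.batch)
        self.covariates = pd.DataFrame(self.covariates)
        if len(self.covariates) and not self.batch.index.equals(self.covariates.index):
            raise ValueError("batch and covariates must share a subject index")
        counts = self.batch.value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(
                f"each batch needs n >= 2 subjects; too small: {dict(small)}"
            )

    @property
    def batches(self) -> list:
        return list(pd.unique(self.batch))

    @property
    def counts(self) -> pd.Series:
        return self.batch.value_counts().reindex(self.batches)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        batch_col: str = "scanner",
        covariate_cols: Sequence[str] = ("age", "group"),
    ) -> "DesignInfo":
        """Build a design from a cohort table, dummy-coding string covariates.

        A two-level string column (e.g. group CN/AD) becomes a single 0/1
        indicator for its lexicographically larger level... more precisely, for
        every non-numeric column all levels but the first (in order of first
        appearance) get an indicator column.
        """
        cov = {}
        for c in covariate_cols:
            col = table[c]
            if pd.api.types.is_numeric_dtype(col):
                cov[c] = col.astype(float)
            else:
                levels = list(pd.unique(col))
                for lev in levels[1:]:
                    cov[f"{c}_{lev}"] = (col == lev).astype(float)
        return cls(batch=table[batch_col], covariates=pd.DataFrame(cov, index=table.index))


@dataclass
class BatchPriors:
    """Per-batch EB hyperparameters and the unshrunk per-feature estimates.

    gamma_bar/tau2 parameterize the normal prior on the additive effect;
    lambda_/theta the inverse-gamma prior on the squared multiplicative
    effect.  ``delta2_mode`` records how the delta posterior is handled:
    "eb" (proper inverse-gamma prior), "pool" (zero across-feature spread —
    complete pooling to the mean), or "none" (single feature — no shrinkage).
    """

    gamma_hat: pd.DataFrame  # batches × features
    delta2_hat: pd.DataFrame  # batches × features
    gamma_bar: pd.Series
    tau2: pd.Series
    lambda_: pd.Series
    theta: pd.Series
    delta2_pool_mean: pd.Series
    delta2_mode: pd.Series


@dataclass
class CombatFit:
    """Everything estimated by a ComBat fit, sufficient to harmonize new rows
    of the same design (same batches and covariates)."""

    features: list
    batches: list
    alpha_hat: pd.Series  # per feature
    beta_hat: pd.DataFrame  # covariates × features
    sigma_hat: pd.Series  # per feature, RMS residual scale
    priors: BatchPriors
    gamma_star: pd.DataFrame  # batches × features
    delta_star: pd.DataFrame  # batches × features, > 0
    eb: bool
    n_iter: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "batches": [str(b) for b in self.batches],
            "alpha_hat": self.alpha_hat.to_dict(),
            "beta_hat": {c: self.beta_hat[c].to_dict() for c in self.beta_hat},
            "sigma_hat": self.sigma_hat.to_dict(),
            "gamma_hat": {c: self.priors.gamma_hat[c].to_dict() for c in self.priors.gamma_hat},
            "delta2_hat": {c: self.priors.delta2_hat[c].to_dict() for c in self.priors.delta2_hat},
            "hyperpriors": {
                "gamma_bar": self.priors.gamma_bar.to_dict(),
                "tau2": self.priors.tau2.to_dict(),
                "lambda": self.priors.lambda_.to_dict(),
                "theta": self.priors.theta.to_dict(),
            },
            "gamma_star": {c: self.gamma_star[c].to_dict() for c in self.gamma_star},
            "delta_star": {c: self.delta_star[c].to_dict() for c in self.delta_star},
            "eb": self.eb,
            "n_iter": {str(k): int(v) for k, v in self.n_iter.items()},
            "converged": bool(self.converged),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _check_matrix(data: pd.DataFrame) -> pd.DataFrame:
    data = pd.DataFrame(data)
    arr = data.to_numpy(dtype=float)
    if np.isnan(arr).any():
        bad = data.columns[np.isnan(arr).any(axis=0)].tolist()
        raise ValueError(f"feature matrix contains missing values in {bad}")
    if not np.isfinite(arr).all():
        raise ValueError("feature matrix contains non-finite values")
    return data


def _design_matrix(design: DesignInfo) -> tuple[np.ndarray, list]:
    """Batch one-hot columns followed by covariates; checks full rank."""
    batches = design.batches
    onehot = np.column_stack(
        [(design.batch == b).to_numpy(float) for b in batches]
    )
    cov = design.covariates.to_numpy(dtype=float)
    D = np.column_stack([onehot, cov]) if cov.size else onehot
    names = [f"batch[{b}]" for b in batches] + list(design.covariates.columns)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # name the offending columns: those expressible from the preceding ones
        collinear = []
        for j in range(1, D.shape[1]):
            prev = D[:, :j]
            coef, *_ = np.linalg.lstsq(prev, D[:, j], rcond=None)
            if np.allclose(prev @ coef, D[:, j], atol=1e-8):
                collinear.append(names[j])
        raise ValueError(
            f"design matrix is rank deficient; collinear columns: {collinear}"
        )
    return D, names


def fit_standardize(
    data: pd.DataFrame, design: DesignInfo
) -> tuple[CombatFit, pd.DataFrame]:
    """Covariate fit and standardization (stage 1).

    Returns a partial :class:`CombatFit` (alphâ, betâ, sigmâ filled in;
    EB fields empty) and the standardized matrix z.
    """
    data = _check_matrix(data)
    if not design.batch.index.equals(data.index):
        raise ValueError("data and design must share a subject index")
    Y = data.to_numpy(dtype=float)
    D, _names = _design_matrix(design)
    batches = design.batches
    n_b = len(batches)
    counts = design.counts.to_numpy(dtype=float)

    B, *_ = np.linalg.lstsq(D, Y, rcond=None)
    batch_int = B[:n_b, :]  # per-batch intercepts
    beta = B[n_b:, :]
    # grand intercept under the constraint sum_i n_i * gamma_i = 0
    alpha = (counts[:, None] * batch_int).sum(axis=0) / counts.sum()
    resid = Y - D @ B
    sigma = np.sqrt((resid**2).mean(axis=0))  # 1/N convention
    if np.any(sigma <= 0):
        bad = data.columns[sigma <= 0].tolist()
        raise ValueError(f"zero residual variance for features {bad}")

    cov_part = design.covariates.to_numpy(dtype=float) @ beta if beta.size else 0.0
    z = (Y - alpha[None, :] - cov_part) / sigma[None, :]
    z = pd.DataFrame(z, index=data.index, columns=data.columns)

    fit = CombatFit(
        features=list(data.columns),
        batches=batches,
        alpha_hat=pd.Series(alpha, index=data.columns),
        beta_hat=pd.DataFrame(
            beta, index=design.covariates.columns, columns=data.columns
        ),
        sigma_hat=pd.Series(sigma, index=data.columns),
        priors=None,  # filled by estimate_hyperpriors / harmonize
        gamma_star=pd.DataFrame(),
        delta_star=pd.DataFrame(),
        eb=True,
    )
    return fit, z


def estimate_hyperpriors(z: pd.DataFrame, design: DesignInfo) -> BatchPriors:
    """Per-batch location/scale estimates and their EB hyperpriors (stage 2a).

    gammâ(i,v) is the batch mean of z and deltâ²(i,v) the batch variance
    (1/n_i); hyperparameters come from moments across features: gamma_bar/tau²
    are the mean/variance of gammâ(i,·), and the inverse-gamma (lambda, theta)
    match the mean m and variance s² of deltâ²(i,·) via lambda = m²/s² + 2,
    theta = m(m²/s² + 1).  Degenerate spreads fall back with a warning:
    tau² = 0 pools gamma completely; s² = 0 pools delta² to its mean; a single
    feature leaves both unshrunk.
    """
    batches = design.batches
    feats = list(z.columns)
    g_hat = pd.DataFrame(index=batches, columns=feats, dtype=float)
    d2_hat = pd.DataFrame(index=batches, columns=feats, dtype=float)
    for b in batches:
        zb = z.loc[design.batch == b]
        g_hat.loc[b] = zb.mean(axis=0)
        d2_hat.loc[b] = zb.var(axis=0, ddof=0)

    single_feature = len(feats) < 2
    gamma_bar = g_hat.mean(axis=1)
    tau2 = g_hat.var(axis=1, ddof=0)
    m = d2_hat.mean(axis=1)
    s2 = d2_hat.var(axis=1, ddof=0)

    lambda_ = pd.Series(np.nan, index=batches)
    theta = pd.Series(np.nan, index=batches)
    mode = pd.Series("eb", index=batches, dtype=object)
    for b in batches:
        if single_feature:
            mode[b] = "none"
            tau2[b] = np.inf  # no across-feature information: no shrinkage
            continue
        if s2[b] <= 0:
            mode[b] = "pool"
            warnings.warn(
                f"batch {b!r}: zero across-feature spread of delta2_hat; "
                "pooling delta completely",
                stacklevel=2,
            )
            continue
        lambda_[b] = m[b] ** 2 / s2[b] + 2.0
        theta[b] = m[b] * (m[b] ** 2 / s2[b] + 1.0)
    if (not single_feature) and (tau2 <= 0).any():
        for b in tau2.index[tau2 <= 0]:
            warnings.warn(
                f"batch {b!r}: zero across-feature spread of gamma_hat; "
                "pooling gamma completely",
                stacklevel=2,
            )

    return BatchPriors(
        gamma_hat=g_hat,
        delta2_hat=d2_hat,
        gamma_bar=gamma_bar,
        tau2=tau2,
        lambda_=lambda_,
        theta=theta,
        delta2_pool_mean=m,
        delta2_mode=mode,
    )


def eb_adjust(
    z: pd.DataFrame,
    design: DesignInfo,
    priors: BatchPriors,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, bool]:
    """Iterate the conditional posterior means to the EB fixed point (stage 2b).

    For each batch i (vectorized over features v), starting from the unshrunk
    estimates::

        gamma* = (n_i·tau²·gammâ + delta*²·gamma_bar) / (n_i·tau² + delta*²)
        delta*² = (theta + ½·Σ_j (z_ij − gamma*)²) / (n_i/2 + lambda − 1)

    until the largest absolute change falls below ``tol`` or ``max_iter`` is
    reached (non-convergence returns the last iterate with a warning).
    tau² = ∞ reproduces gammâ unshrunk; tau² = 0 pools completely to
    gamma_bar.  Returns (gamma_star, delta_star, iterations, converged).
    """
    batches = priors.gamma_hat.index
    feats = priors.gamma_hat.columns
    gamma_star = priors.gamma_hat.copy()
    delta_star = pd.DataFrame(
        np.sqrt(priors.delta2_hat.to_numpy(dtype=float)),
        index=batches,
        columns=feats,
    )
    n_iter = pd.Series(0, index=batches, dtype=int)
    converged = True

    for b in batches:
        zb = z.loc[design.batch == b].to_numpy(dtype=float)
        n_i = zb.shape[0]
        g_hat = priors.gamma_hat.loc[b].to_numpy(dtype=float)
        d2 = priors.delta2_hat.loc[b].to_numpy(dtype=float).copy()
        g = g_hat.copy()
        tau2, g_bar = priors.tau2[b], priors.gamma_bar[b]
        lam, th = priors.lambda_[b], priors.theta[b]
        mode = priors.delta2_mode[b]

        ok = False
        for it in range(1, max_iter + 1):
            if np.isinf(tau2):
                g_new = g_hat
            else:
                g_new = (n_i * tau2 * g_hat + d2 * g_bar) / (n_i * tau2 + d2)
            if mode == "eb":
                ss = ((zb - g_new[None, :]) ** 2).sum(axis=0)
                d2_new = (th + 0.5 * ss) / (n_i / 2.0 + lam - 1.0)
            elif mode == "pool":
                d2_new = np.full_like(d2, priors.delta2_pool_mean[b])
            else:  # "none": single feature, no shrinkage
                d2_new = priors.delta2_hat.loc[b].to_numpy(dtype=float)
            change = max(
                np.max(np.abs(g_new - g)), np.max(np.abs(np.sqrt(d2_new) - np.sqrt(d2)))
            )
            g, d2 = np.asarray(g_new, dtype=float), d2_new
            n_iter[b] = it
            if change < tol:
                ok = True
                break
        if not ok:
            converged = False
            warnings.warn(
                f"EB fixed point for batch {b!r} did not converge in "
                f"{max_iter} iterations (returning last iterate)",
                ConvergenceWarning,
                stacklevel=2,
            )
        if np.any(d2 <= 0):
            raise RuntimeError(f"non-positive delta*² for batch {b!r}")
        gamma_star.loc[b] = g
        delta_star.loc[b] = np.sqrt(d2)

    return gamma_star, delta_star, n_iter, converged


def apply_harmonization(data: pd.DataFrame, design: DesignInfo, fit: CombatFit) -> pd.DataFrame:
    """Reconstruct harmonized values from a fit (stage 3).

    y* = sigmâ·(z − gamma*_batch)/delta*_batch + alphâ + X·betâ — scanner
    location and scale removed on the standardized scale, covariate structure
    restored.
    """
    data = _check_matrix(data)
    if list(data.columns) != list(fit.features):
        raise ValueError(
            f"feature columns {list(data.columns)} do not match the fit's "
            f"{list(fit.features)}"
        )
    if not design.batch.index.equals(data.index):
        raise ValueError("data and design must share a subject index")
    unknown = set(design.batches) - set(fit.batches)
    if unknown:
        raise ValueError(f"batches {sorted(map(str, unknown))} were not in the fit")

    alpha = fit.alpha_hat.to_numpy(dtype=float)
    sigma = fit.sigma_hat.to_numpy(dtype=float)
    cov_part = (
        design.covariates.to_numpy(dtype=float) @ fit.beta_hat.to_numpy(dtype=float)
        if len(fit.beta_hat)
        else 0.0
    )
    z = (data.to_numpy(dtype=float) - alpha[None, :] - cov_part) / sigma[None, :]
    g = fit.gamma_star.loc[design.batch].to_numpy(dtype=float)
    d = fit.delta_star.loc[design.batch].to_numpy(dtype=float)
    y_adj = sigma[None, :] * (z - g) / d + alpha[None, :] + cov_part
    return pd.DataFrame(y_adj, index=data.index, columns=data.columns)


def harmonize(
    data: pd.DataFrame,
    design: DesignInfo,
    eb: bool = True,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[pd.DataFrame, CombatFit]:
    """Fit ComBat and return (harmonized matrix, fit).

    ``eb=False`` disables shrinkage and uses the unshrunk per-batch
    location/scale estimates directly (equivalent to re-standardizing each
    batch); useful when only two features are available and across-feature
    pooling is weakly determined.
    """
    fit, z = fit_standardize(data, design)
    priors = estimate_hyperpriors(z, design)
    fit.priors = priors
    if eb:
        gamma_star, delta_star, n_iter, converged = eb_adjust(
            z, design, priors, tol=tol, max_iter=max_iter
        )
    else:
        gamma_star = priors.gamma_hat.copy()
        delta_star = pd.DataFrame(
            np.sqrt(priors.delta2_hat.to_numpy(dtype=float)),
            index=priors.delta2_hat.index,
            columns=priors.delta2_hat.columns,
        )
        n_iter = pd.Series(0, index=gamma_star.index, dtype=int)
        converged = True
    fit.gamma_star = gamma_star
    fit.delta_star = delta_star
    fit.eb = eb
    fit.n_iter = n_iter
    fit.converged = converged
    harmonized = apply_harmonization(data, design, fit)
    return harmonized, fit
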