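"""Positional-effect correction.

Two arms:

* :func:`combat_adjust` — parametric empirical-Bayes location/scale batch
  adjustment of a complete feature matrix (the classic ComBat model):
  features are standardized against batch-structured fits, per-batch
  location (gamma) and scale (delta^2) estimates are shrunk toward
  method-of-moments normal / inverse-gamma priors by iterated posterior
  updates, and the data are back-transformed with the shrunken estimates.
* :func:`combat_counts_fi` — a count-style adjustment of fluorescence
  intensities: per feature, rounded intensities are modelled as negative
  binomial with batch-specific means and method-of-moments dispersions, and
  each observation is quantile-mapped onto a batch-free target distribution
  (geometric-mean location, batch-size-weighted pooled dispersion).  This is
  a deliberately simplified count adjustment, not a GLM-based one.

Batch labels are one factor per run (chamber or slide).  Beta-scale outputs
of :func:`combat_adjust` are clipped back to [0, 1] when requested, since an
unconstrained location/scale back-transformation can leave the unit
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CHANNELS, LowLevelArraySet, ValidationError


class SingletonBatchError(ValueError):
    """Raised when some batch has fewer than two samples (EB scale undefined)."""


def _check_batches(labels: pd.Series) -> dict:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise SingletonBatchError("need at least two batches")
    small = counts[counts < 2]
    if len(small):
        raise SingletonBatchError(
            f"batches with a single sample: {list(small.index)}"
        )
    return {b: labels.index[labels == b] for b in counts.index}


# ---------------------------------------------------------------------------
# parametric EB adjustment (beta-scale)
# ---------------------------------------------------------------------------


@dataclass
class BatchModel:
    """Fitted EB batch model on the standardized scale."""

    batches: list
    n_per_batch: np.ndarray  # (B,)
    stand_mean: np.ndarray  # per-feature grand mean (weighted by batch size)
    var_pooled: np.ndarray  # per-feature pooled residual variance
    gamma_hat: np.ndarray  # (B, features) batch locations, standardized scale
    delta2_hat: np.ndarray  # (B, features) batch scales
    gamma_bar: np.ndarray  # (B,) normal prior means
    tau2: np.ndarray  # (B,) normal prior variances
    a_prior: np.ndarray  # (B,) inverse-gamma shapes
    b_prior: np.ndarray  # (B,) inverse-gamma scales
    gamma_star: np.ndarray  # (B, features) shrunken locations
    delta2_star: np.ndarray  # (B, features) shrunken scales
    n_iter: np.ndarray  # (B,) iterations to convergence


def _aprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (2 * s2 + m * m) / s2


def _bprior(delta2: np.ndarray) -> float:
    m, s2 = delta2.mean(), delta2.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _postmean(gamma_hat, gamma_bar, n, delta2_star, tau2):
    """Posterior mean of the batch location under the conjugate normal prior."""
    return (n * tau2 * gamma_hat + delta2_star * gamma_bar) / (
        n * tau2 + delta2_star
    )


def _postvar(sum2, n, a, b):
    """Posterior expectation of the batch scale under the inverse-gamma prior."""
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _eb_iterate(z_batch, gamma_hat, delta2_hat, gamma_bar, tau2, a, b,
                conv=1e-4, max_iter=100):
    """Iterated posterior updates for one batch; returns (gamma*, delta2*, iters)."""
    n = z_batch.shape[0]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(gamma_hat, gamma_bar, n, d_old, tau2)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-30)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-30)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old, it


def fit_batch_model(
    matrix: pd.DataFrame,
    batch_labels: pd.Series,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> BatchModel:
    """Fit the parametric EB batch model to a complete features x samples matrix."""
    labels = pd.Series(batch_labels).reindex(matrix.columns)
    if labels.isna().any():
        raise ValidationError("batch labels missing for some samples")
    members = _check_batches(labels)
    data = matrix.to_numpy(float)
    if np.isnan(data).any():
        raise ValidationError("matrix must be complete; run clean_matrix first")

    batches = list(members)
    idx = [matrix.columns.get_indexer(members[b]) for b in batches]
    n_per = np.array([len(i) for i in idx])
    n_total = n_per.sum()

    batch_means = np.stack([data[:, i].mean(axis=1) for i in idx])  # (B, f)
    grand = (n_per[:, None] * batch_means).sum(axis=0) / n_total
    resid = data.astype(float).copy()
    for k, i in enumerate(idx):
        resid[:, i] -= batch_means[k][:, None]
    var_pooled = (resid ** 2).sum(axis=1) / n_total
    if (var_pooled <= 0).any():
        # constant features cannot be standardized; nudge to avoid 0/0
        var_pooled = np.maximum(var_pooled, 1e-30)

    z = (data - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.stack([z[:, i].mean(axis=1) for i in idx])
    delta2_hat = np.stack([z[:, i].var(axis=1, ddof=1) for i in idx])

    n_features = data.shape[0]
    gamma_bar = gamma_hat.mean(axis=1)
    if n_features > 1:
        tau2 = gamma_hat.var(axis=1, ddof=1)
        a = np.array([_aprior(delta2_hat[k]) for k in range(len(batches))])
        b = np.array([_bprior(delta2_hat[k]) for k in range(len(batches))])
    else:
        # single feature: no cross-feature information, flat priors
        tau2 = np.full(len(batches), np.inf)
        a = np.full(len(batches), 1.0 + 1e-12)
        b = np.zeros(len(batches))

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iter = np.zeros(len(batches), dtype=int)
    for k in range(len(batches)):
        if np.isinf(tau2[k]):
            gamma_star[k] = gamma_hat[k]
            delta2_star[k] = delta2_hat[k]
            continue
        gamma_star[k], delta2_star[k], n_iter[k] = _eb_iterate(
            z[:, idx[k]].T, gamma_hat[k], delta2_hat[k],
            gamma_bar[k], tau2[k], a[k], b[k], conv=conv, max_iter=max_iter,
        )

    return BatchModel(
        batches=batches, n_per_batch=n_per, stand_mean=grand,
        var_pooled=var_pooled, gamma_hat=gamma_hat, delta2_hat=delta2_hat,
        gamma_bar=gamma_bar, tau2=tau2, a_prior=a, b_prior=b,
        gamma_star=gamma_star, delta2_star=delta2_star, n_iter=n_iter,
    )


def combat_adjust(
    matrix: pd.DataFrame,
    batch_labels: pd.Series,
    parametric: bool = True,
    eb: bool = True,
    clip01: bool = True,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment of a complete matrix.

    With ``eb=False`` the shrinkage step is skipped and the adjustment
    reduces to per-batch standardize / restandardize with the raw batch
    estimates (the zero-prior-precision limit).  Only the parametric prior
    family is implemented.
    """
    if not parametric:
        raise NotImplementedError("only the parametric EB mode is implemented")
    model = fit_batch_model(matrix, batch_labels, conv=conv, max_iter=max_iter)
    labels = pd.Series(batch_labels).reindex(matrix.columns)
    data = matrix.to_numpy(float)
    z = (data - model.stand_mean[:, None]) / np.sqrt(model.var_pooled)[:, None]

    gamma = model.gamma_star if eb else model.gamma_hat
    delta2 = model.delta2_star if eb else model.delta2_hat

    out = np.empty_like(z)
    for k, b in enumerate(model.batches):
        cols = np.flatnonzero((labels == b).to_numpy())
        out[:, cols] = (z[:, cols] - gamma[k][:, None]) / np.sqrt(delta2[k])[:, None]
    out = out * np.sqrt(model.var_pooled)[:, None] + model.stand_mean[:, None]
    if clip01:
        out = np.clip(out, 0.0, 1.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# count-style adjustment of fluorescence intensities
# ---------------------------------------------------------------------------


def _nb_cdf(x, mu, phi):
    """Negative-binomial CDF at integer x with mean mu and dispersion phi
    (Var = mu + phi mu^2)."""
    size = 1.0 / phi
    p = size / (size + mu)
    return stats.nbinom.cdf(x, size, p)


def _nb_ppf(q, mu, phi):
    size = 1.0 / phi
    p = size / (size + mu)
    return stats.nbinom.ppf(q, size, p)


def _quantile_match_counts(counts: np.ndarray, batch_idx: list, floor_disp: float):
    """Map integer counts through batch NB fits onto a batch-free NB target.

    Returns (adjusted counts, boolean passthrough mask over features).
    """
    n_features = counts.shape[0]
    n_b = np.array([len(i) for i in batch_idx], float)
    mu = np.stack([counts[:, i].mean(axis=1) for i in batch_idx])  # (B, f)
    var = np.stack([counts[:, i].var(axis=1, ddof=1) for i in batch_idx])
    passthrough = (mu <= 0).any(axis=0)

    phi = np.maximum((var - mu) / np.maximum(mu, 1e-12) ** 2, floor_disp)
    with np.errstate(divide="ignore"):
        log_mu = np.where(mu > 0, np.log(np.maximum(mu, 1e-300)), 0.0)
    mu_target = np.exp((n_b[:, None] * log_mu).sum(axis=0) / n_b.sum())
    phi_target = (n_b[:, None] * phi).sum(axis=0) / n_b.sum()

    out = counts.astype(float).copy()
    active = ~passthrough
    for k, cols in enumerate(batch_idx):
        x = counts[np.ix_(active, cols)].astype(float)
        mu_k = mu[k][active][:, None]
        phi_k = phi[k][active][:, None]
        # mid-CDF keeps the map close to the identity under equal batches
        q = 0.5 * (_nb_cdf(x, mu_k, phi_k) + _nb_cdf(x - 1, mu_k, phi_k))
        q = np.clip(q, 1e-12, 1 - 1e-12)
        y = _nb_ppf(q, mu_target[active][:, None], phi_target[active][:, None])
        out[np.ix_(active, cols)] = y
    return out, passthrough


def combat_counts_fi(
    lowlevel: LowLevelArraySet,
    batch_labels: pd.Series,
    floor_disp: float = 0.01,
) -> LowLevelArraySet:
    """Count-style batch adjustment of per-channel fluorescence intensities.

    Intensities are rounded to integer counts; per feature and channel a
    negative-binomial model with batch-specific means and method-of-moments
    dispersions (floored) is fitted and observations are quantile-matched to
    the batch-free target.  Features with an all-zero batch pass through
    unadjusted (reported via a warning).  Non-negativity and integer support
    are preserved; betas should be recomputed from the result.
    """
    labels = pd.Series(batch_labels).reindex(lowlevel.sample_ids)
    if labels.isna().any():
        raise ValidationError("batch labels missing for some samples")
    members = _check_batches(labels)
    batch_idx = [
        [lowlevel.sample_ids.index(s) for s in members[b]] for b in members
    ]
    out = lowlevel.copy()
    n_pass = 0
    for ch in CHANNELS:
        counts = np.round(lowlevel.mean_fi[ch].to_numpy(float)).astype(np.int64)
        adjusted, passthrough = _quantile_match_counts(counts, batch_idx, floor_disp)
        n_pass += int(passthrough.sum())
        out.mean_fi[ch] = pd.DataFrame(
            adjusted, index=lowlevel.probe_ids, columns=lowlevel.sample_ids
        )
    if n_pass:
        warnings.warn(
            f"{n_pass} feature-channel rows passed through unadjusted "
            "(all-zero in some batch)",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# before/after report
# ---------------------------------------------------------------------------


def correction_report(
    before: pd.DataFrame,
    after: pd.DataFrame,
    batch_labels: pd.Series,
) -> pd.DataFrame:
    """Per-batch location/scale summary plus one-way batch F statistics.

    One row per (batch, arm) with the batch's grand mean and SD and the
    median per-feature one-way ANOVA F statistic for the batch factor in
    that arm.
    """
    from .varmetrics import oneway_f

    rows = []
    for arm, mat in (("before", before), ("after", after)):
        labels = pd.Series(batch_labels).reindex(mat.columns)
        f_med = float(np.nanmedian(oneway_f(mat, labels)))
        for b in labels.dropna().unique():
            sub = mat.loc[:, labels.index[labels == b]]
            rows.append(
                {
                    "arm": arm,
                    "batch": b,
                    "mean": float(sub.to_numpy().mean()),
                    "sd": float(sub.to_numpy().std(ddof=1)),
                    "median_batch_F": f_med,
                }
            )
    return pd.DataFrame(rows)
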