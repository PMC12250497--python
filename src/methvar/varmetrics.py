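"""Variability diagnostics for replicate-plate methylation data.

Everything here asks one question from a different angle: how much of the
variation among technical replicates is attributable to where the sample sat
on the chip?

* within-subject z-scores and per-chamber / per-slide profiles of them;
* the SD ratio (mean within-subject replicate SD over the all-replicate SD
  plus a small offset) — a reliability statistic that does not depend on
  between-subject biological spread;
* bead-level coefficients of variation per chamber;
* intensity-binned bias curves (deviation from the within-subject median as
  a function of probe brightness);
* a per-probe variance decomposition from a linear mixed model with chamber
  and slide as fixed effects and subject as a random effect (closed-form
  single-random-effect REML on a shared eigenbasis, vectorized over probes);
* PCA + Ward-D2 hierarchical clustering with a subject-purity summary;
* the one-outlier Grubbs test;
* correlations of low-level features (bead counts, channel intensities and
  their bead-level SDs) with per-probe beta variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .core import CHANNELS, LowLevelArraySet, SampleSheet, ValidationError

SD_RATIO_OFFSET = 1e-4
DEFAULT_N_BINS = 100
DEFAULT_N_COMPONENTS = 50


# ---------------------------------------------------------------------------
# within-subject z-scores and positional profiles
# ---------------------------------------------------------------------------


def within_subject_zscores(matrix: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Center and scale each probe within each subject's technical replicates.

    Uses the sample (n-1) standard deviation.  Probes constant within a
    subject come out non-finite and are set to NaN (omitted downstream).
    Subjects must have at least two replicates.
    """
    cols = [s for s in matrix.columns]
    sub = sheet.subset(cols)
    out = matrix.copy().astype(float)
    for subject, samples in sub.groups("subject").items():
        samples = [s for s in samples if s in matrix.columns]
        if len(samples) < 2:
            raise ValidationError(
                f"subject {subject!r} has fewer than 2 replicates"
            )
        block = matrix[samples].to_numpy(float)
        mu = np.nanmean(block, axis=1, keepdims=True)
        sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (block - mu) / sd
        z[~np.isfinite(z)] = np.nan
        out[samples] = z
    return out


@dataclass
class ZScoreProfile:
    """Per-probe mean z-score by positional group, plus summaries."""

    profile: pd.DataFrame  # probes x groups
    completeness: pd.Series  # per probe, finite fraction pre-filter
    summary: pd.DataFrame  # per group: mean, sd, sem, n of pooled z values
    group_by: str


def chamber_profile(
    zscores: pd.DataFrame,
    sheet: SampleSheet,
    group_by: str = "chamber",
    min_completeness: float = 0.9,
) -> ZScoreProfile:
    """Average within-subject z-scores by chamber (or slide).

    Probes with finite z-scores in fewer than ``min_completeness`` of the
    samples are excluded.  Groups with no samples are dropped with a warning.
    """
    if group_by not in ("chamber", "slide"):
        raise ValidationError("group_by must be 'chamber' or 'slide'")
    sub = sheet.subset(zscores.columns)
    completeness = zscores.notna().mean(axis=1)
    keep = completeness > min_completeness
    z = zscores.loc[keep]

    cols = {}
    rows = []
    for group, samples in sub.groups(group_by).items():
        samples = [s for s in samples if s in z.columns]
        if not samples:
            warnings.warn(f"{group_by} {group}: no samples, dropped", stacklevel=2)
            continue
        block = z[samples].to_numpy(float)
        cols[group] = np.nanmean(block, axis=1)
        pooled = block[np.isfinite(block)]
        rows.append(
            {
                group_by: group,
                "mean": pooled.mean(),
                "sd": pooled.std(ddof=1),
                "sem": pooled.std(ddof=1) / np.sqrt(len(pooled)),
                "n": len(pooled),
            }
        )
    profile = pd.DataFrame(cols, index=z.index)
    return ZScoreProfile(
        profile=profile,
        completeness=completeness,
        summary=pd.DataFrame(rows).set_index(group_by),
        group_by=group_by,
    )


# ---------------------------------------------------------------------------
# SD ratio
# ---------------------------------------------------------------------------


def sd_ratio(
    matrix: pd.DataFrame, sheet: SampleSheet, offset: float = SD_RATIO_OFFSET
) -> pd.Series:
    """Within-subject over across-subject SD ratio per probe.

    ``mean_over_subjects(SD among a subject's replicates) / (SD over all
    replicates + offset)``.  Requires >= 2 subjects with >= 2 replicates each.
    """
    sub = sheet.subset(matrix.columns)
    groups = sub.groups("subject")
    if len(groups) < 2:
        raise ValidationError("sd_ratio needs at least two subjects")
    sds = []
    for subject, samples in groups.items():
        samples = [s for s in samples if s in matrix.columns]
        if len(samples) < 2:
            raise ValidationError(f"subject {subject!r} has fewer than 2 replicates")
        sds.append(matrix[samples].std(axis=1, ddof=1))
    within = pd.concat(sds, axis=1).mean(axis=1)
    across = matrix.std(axis=1, ddof=1)
    return within / (across + offset)


# ---------------------------------------------------------------------------
# bead-level CV
# ---------------------------------------------------------------------------


@dataclass
class BeadCVResult:
    cv: dict  # channel -> probes x samples CV (NaN where mean_fi == 0)
    summary: pd.DataFrame  # per (chamber, channel): median, IQR, n, n_excluded


def bead_cv(lowlevel: LowLevelArraySet, sheet: SampleSheet) -> BeadCVResult:
    """Coefficient of variation sd_fi / mean_fi of bead-level measurements.

    Computed for Type II probes; records with zero mean FI are excluded and
    counted.  The summary aggregates per chamber and channel (median, IQR).
    """
    probes = lowlevel.manifest.type_ii_probes()
    chamber = sheet.chamber_of()
    cv = {}
    rows = []
    for ch in CHANNELS:
        mean = lowlevel.mean_fi[ch].loc[probes]
        sd = lowlevel.sd_fi[ch].loc[probes]
        with np.errstate(divide="ignore", invalid="ignore"):
            c = sd / mean
        c = c.where(mean > 0)
        cv[ch] = c
        for cham in sorted(chamber.unique()):
            samples = [
                s for s in chamber.index[chamber == cham] if s in c.columns
            ]
            vals = c[samples].to_numpy().ravel()
            ok = np.isfinite(vals)
            q1, med, q3 = np.percentile(vals[ok], [25, 50, 75])
            rows.append(
                {
                    "chamber": cham,
                    "channel": ch,
                    "median": med,
                    "iqr": q3 - q1,
                    "n": int(ok.sum()),
                    "n_excluded": int((~ok).sum()),
                }
            )
    return BeadCVResult(cv=cv, summary=pd.DataFrame(rows))


def boxplot_stats(values: np.ndarray, hide_beyond_iqr: float = 1.96) -> dict:
    """Five-number summary with far values (beyond ``hide_beyond_iqr`` x IQR
    outside the quartiles) hidden, as used for large-dataset boxplots."""
    vals = np.asarray(values, float)
    vals = vals[np.isfinite(vals)]
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - hide_beyond_iqr * iqr, q3 + hide_beyond_iqr * iqr
    shown = vals[(vals >= lo) & (vals <= hi)]
    return {
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_lo": shown.min() if len(shown) else np.nan,
        "whisker_hi": shown.max() if len(shown) else np.nan,
        "n_hidden": int(len(vals) - len(shown)),
    }


# ---------------------------------------------------------------------------
# intensity-binned bias curves
# ---------------------------------------------------------------------------


def intensity_bin_bias(
    values: pd.DataFrame,
    lowlevel: LowLevelArraySet,
    sheet: SampleSheet,
    bin_channel: str = "green",
    mode: str = "fi_deviation",
    n_bins: int = DEFAULT_N_BINS,
) -> pd.DataFrame:
    """Positional bias as a function of probe brightness.

    Type II probes are ranked per subject by their median FI in
    ``bin_channel`` and split into ``n_bins`` percentile bins (stable ties).
    Per bin and chamber the mean deviation of ``values`` from the
    within-subject median is reported: signed deviation for
    ``mode="fi_deviation"`` (FI units), absolute deviation for
    ``mode="beta_absdev"``.  Results are averaged over subjects; the
    ``bin_median_fi`` column carries the mean bin brightness for slope
    diagnostics.
    """
    if mode not in ("fi_deviation", "beta_absdev"):
        raise ValidationError("mode must be 'fi_deviation' or 'beta_absdev'")
    probes = [p for p in lowlevel.manifest.type_ii_probes() if p in values.index]
    if len(probes) < n_bins:
        n_bins = max(1, len(probes) // 2)
        warnings.warn(f"few probes: bin count reduced to {n_bins}", stacklevel=2)
    sub = sheet.subset(values.columns)
    chamber = sub.chamber_of()

    acc = {}
    fi_acc = {}
    for subject, samples in sub.groups("subject").items():
        samples = [s for s in samples if s in values.columns]
        fi = lowlevel.mean_fi[bin_channel].loc[probes, samples]
        med_fi = fi.median(axis=1)
        # stable percentile bins over median brightness
        order = np.argsort(med_fi.to_numpy(), kind="stable")
        bins = np.empty(len(probes), dtype=int)
        bins[order] = (np.arange(len(probes)) * n_bins) // len(probes)

        v = values.loc[probes, samples]
        dev = v.sub(v.median(axis=1), axis=0)
        if mode == "beta_absdev":
            dev = dev.abs()
        for s in samples:
            cham = chamber[s]
            df = pd.DataFrame({"bin": bins, "dev": dev[s].to_numpy()})
            g = df.groupby("bin")["dev"].mean()
            acc.setdefault(cham, []).append(g)
        fi_acc[subject] = pd.Series(med_fi.to_numpy()).groupby(bins).mean()

    table = pd.DataFrame(
        {cham: pd.concat(series, axis=1).mean(axis=1) for cham, series in acc.items()}
    ).sort_index(axis=1)
    table.index.name = "bin"
    table["bin_median_fi"] = pd.concat(fi_acc.values(), axis=1).mean(axis=1)
    return table


# ---------------------------------------------------------------------------
# variance decomposition (single-random-effect REML, vectorized)
# ---------------------------------------------------------------------------


@dataclass
class VarianceDecomposition:
    frame: pd.DataFrame  # per probe: F_chamber, F_slide, sigma2_subject, sigma2_resid
    lambda_grid: np.ndarray


def _factor_dummies(labels: pd.Series) -> np.ndarray | None:
    levels = sorted(pd.unique(labels))
    if len(levels) < 2:
        return None
    cols = [(labels == lv).to_numpy(float) for lv in levels[1:]]
    return np.stack(cols, axis=1)


def variance_decomposition(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    n_grid: int = 81,
    fixed_factors: tuple = ("chamber", "slide"),
) -> VarianceDecomposition:
    """Per-probe mixed model: chamber + slide fixed, subject random.

    The single random effect is profiled out on a shared eigenbasis of the
    subject-grouping structure, so the REML criterion is evaluated for all
    probes jointly on a fixed grid of variance ratios
    ``lambda = sigma^2_subject / sigma^2_resid`` (lambda = 0 included, which
    floors sigma^2_subject at 0).  Marginal Wald F statistics for chamber and
    slide use the GLS coefficient covariance at the selected lambda with
    residual variance RSS_w / (n - rank(X)).
    """
    sub = sheet.subset(matrix.columns)
    order = [s for s in sub.frame["sample_id"]]
    y = matrix[order].to_numpy(float)
    if np.isnan(y).any():
        raise ValidationError("matrix must be complete; run clean_matrix first")
    n = len(order)

    chamber = sub.chamber_of().reindex(order)
    slide = sub.slide_of().reindex(order)
    subject = sub.subject_of().reindex(order)

    parts = [np.ones((n, 1))]
    blocks = {"chamber": None, "slide": None}
    factors = [
        (name, labels)
        for name, labels in (("chamber", chamber), ("slide", slide))
        if name in fixed_factors
    ]
    for name, labels in factors:
        d = _factor_dummies(labels)
        if d is None:
            warnings.warn(f"factor {name} has one level; F reported as NaN",
                          stacklevel=2)
            blocks[name] = None
        else:
            start = sum(p.shape[1] for p in parts)
            parts.append(d)
            blocks[name] = (start, start + d.shape[1])
    X = np.concatenate(parts, axis=1)
    p = np.linalg.matrix_rank(X)
    if p < X.shape[1]:
        raise ValidationError("rank-deficient fixed design (chamber/slide aliased)")

    # eigenbasis of the subject grouping: V(lambda) diagonalizes as 1 + lambda*d
    subj_levels = sorted(pd.unique(subject))
    Z = np.stack([(subject == s).to_numpy(float) for s in subj_levels], axis=1)
    d_eig, P = np.linalg.eigh(Z @ Z.T)
    d_eig = np.maximum(d_eig, 0.0)

    Xt = P.T @ X
    Yt = y @ P  # probes x n

    lambdas = np.concatenate([[0.0], np.logspace(-4, 4, n_grid - 1)])
    n_probes = y.shape[0]
    best_crit = np.full(n_probes, np.inf)
    best_lam = np.zeros(n_probes, dtype=int)

    cache = {}
    for li, lam in enumerate(lambdas):
        w = 1.0 / (1.0 + lam * d_eig)
        Xw = Xt * w[:, None]
        A = Xt.T @ Xw
        Ainv = np.linalg.inv(A)
        M = Ainv @ Xw.T  # p x n
        beta = M @ Yt.T  # p x probes
        resid = Yt.T - Xt @ beta  # n x probes
        rss_w = (w[:, None] * resid ** 2).sum(axis=0)
        sign, logdet_A = np.linalg.slogdet(A)
        crit = (
            (n - p) * np.log(np.maximum(rss_w, 1e-300) / (n - p))
            + np.log1p(lam * d_eig).sum()
            + logdet_A
        )
        better = crit < best_crit
        best_crit[better] = crit[better]
        best_lam[better] = li
        cache[li] = (w, Ainv)

    F_chamber = np.full(n_probes, np.nan)
    F_slide = np.full(n_probes, np.nan)
    sigma2_e = np.empty(n_probes)
    sigma2_s = np.empty(n_probes)
    for li in np.unique(best_lam):
        lam = lambdas[li]
        w, Ainv = cache[li]
        sel = best_lam == li
        Xw = Xt * w[:, None]
        M = Ainv @ Xw.T
        beta = M @ Yt[sel].T  # p x k
        resid = Yt[sel].T - Xt @ beta
        rss_w = (w[:, None] * resid ** 2).sum(axis=0)
        s2 = rss_w / (n - p)
        sigma2_e[sel] = s2
        sigma2_s[sel] = lam * s2
        for name, out in (("chamber", F_chamber), ("slide", F_slide)):
            if blocks[name] is None:
                continue
            a, b = blocks[name]
            C = Ainv[a:b, a:b]
            Cinv = np.linalg.inv(C)
            bj = beta[a:b]  # q x k
            wald = np.einsum("qk,qr,rk->k", bj, Cinv, bj)
            out[sel] = wald / (b - a) / s2
    frame = pd.DataFrame(
        {
            "F_chamber": F_chamber,
            "F_slide": F_slide,
            "sigma2_subject": sigma2_s,
            "sigma2_resid": sigma2_e,
        },
        index=matrix.index,
    )
    return VarianceDecomposition(frame=frame, lambda_grid=lambdas)


def oneway_f(matrix: pd.DataFrame, labels: pd.Series) -> np.ndarray:
    """Vectorized per-feature one-way ANOVA F across the label groups."""
    labels = pd.Series(labels).reindex(matrix.columns)
    data = matrix.to_numpy(float)
    groups = [np.flatnonzero((labels == g).to_numpy()) for g in labels.dropna().unique()]
    k = len(groups)
    n = data.shape[1]
    grand = data.mean(axis=1)
    ssb = np.zeros(data.shape[0])
    ssw = np.zeros(data.shape[0])
    for idx in groups:
        gm = data[:, idx].mean(axis=1)
        ssb += len(idx) * (gm - grand) ** 2
        ssw += ((data[:, idx] - gm[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (ssb / (k - 1)) / (ssw / (n - k))


# ---------------------------------------------------------------------------
# PCA + hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class PCAClusterResult:
    scores: pd.DataFrame  # samples x components
    linkage_matrix: np.ndarray  # Ward-D2 linkage on PC scores
    clusters: pd.Series  # cut at k = n_subjects
    purity: float
    explained_variance_ratio: np.ndarray


def pca_cluster(
    matrix: pd.DataFrame,
    sheet: SampleSheet,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> PCAClusterResult:
    """Top principal components of samples, Ward-D2 clustering, subject purity.

    PCA is computed on the samples x probes matrix (features centered, not
    scaled); Ward's D2 agglomeration runs on the retained PC scores.  Purity
    is the fraction of samples whose cluster (cut at k = number of subjects)
    is labelled with their own subject by majority vote.
    """
    data = matrix.to_numpy(float).T  # samples x probes
    if np.isnan(data).any():
        raise ValidationError("matrix must be complete; run clean_matrix first")
    max_comp = min(data.shape[0] - 1, data.shape[1])
    if n_components > max_comp:
        warnings.warn(
            f"n_components reduced from {n_components} to {max_comp}", stacklevel=2
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    Zl = linkage(scores, method="ward")

    subject = sheet.subset(matrix.columns).subject_of().reindex(matrix.columns)
    k = subject.nunique()
    labels = fcluster(Zl, t=k, criterion="maxclust")
    clusters = pd.Series(labels, index=matrix.columns, name="cluster")
    correct = 0
    for c in np.unique(labels):
        member_subjects = subject[clusters == c]
        correct += int((member_subjects == member_subjects.mode().iloc[0]).sum())
    purity = correct / len(subject)
    return PCAClusterResult(
        scores=pd.DataFrame(
            scores, index=matrix.columns,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        ),
        linkage_matrix=Zl,
        clusters=clusters,
        purity=purity,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


# ---------------------------------------------------------------------------
# Grubbs one-outlier test
# ---------------------------------------------------------------------------


def grubbs_test(values) -> tuple[float, float]:
    """Two-sided Grubbs test for a single outlier.

    ``G = max|x - mean| / sd`` with the sample SD; the p-value uses the
    standard t-distribution bound ``p = min(1, 2n * P(T_{n-2} > t))`` with
    ``t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2)``.
    """
    x = np.asarray(values, float)
    n = len(x)
    if n < 3:
        raise ValidationError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise ValidationError("Grubbs statistic undefined for constant input")
    G = float(np.max(np.abs(x - x.mean())) / s)
    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:
        return G, 0.0
    t = np.sqrt(n * (n - 2) * G * G / denom)
    p = float(min(1.0, 2 * n * stats.t.sf(t, n - 2)))
    return G, p


# ---------------------------------------------------------------------------
# low-level feature correlations
# ---------------------------------------------------------------------------

LOWLEVEL_FEATURES = ("n_beads", "green_fi", "red_fi", "green_sd_fi", "red_sd_fi")


def lowlevel_correlations(
    lowlevel: LowLevelArraySet, beta_sd: pd.Series
) -> pd.DataFrame:
    """Pearson and Spearman correlation of low-level features with beta SD.

    Features are per-probe means over samples (Type II probes): bead count,
    per-channel mean FI, per-channel bead-level FI SD.  Zero-variance columns
    yield NaN correlations and are flagged.
    """
    probes = [p for p in lowlevel.manifest.type_ii_probes() if p in beta_sd.index]
    sd = beta_sd.loc[probes].to_numpy(float)
    feats = {
        "n_beads": lowlevel.n_beads["green"].loc[probes].mean(axis=1),
        "green_fi": lowlevel.mean_fi["green"].loc[probes].mean(axis=1),
        "red_fi": lowlevel.mean_fi["red"].loc[probes].mean(axis=1),
        "green_sd_fi": lowlevel.sd_fi["green"].loc[probes].mean(axis=1),
        "red_sd_fi": lowlevel.sd_fi["red"].loc[probes].mean(axis=1),
    }
    rows = []
    for name, series in feats.items():
        v = series.to_numpy(float)
        degenerate = v.std() == 0 or sd.std() == 0
        if degenerate:
            pear = spear = np.nan
        else:
            pear = stats.pearsonr(v, sd).statistic
            spear = stats.spearmanr(v, sd).statistic
        rows.append(
            {"feature": name, "pearson": pear, "spearman": spear,
             "degenerate": degenerate}
        )
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# chamber gain estimation (bias recovery)
# ---------------------------------------------------------------------------


def chamber_gain_estimate(
    lowlevel: LowLevelArraySet, sheet: SampleSheet, channel: str
) -> pd.Series:
    """Relative brightness of each chamber in one channel.

    Grand-mean Type II FI per sample, averaged per chamber, expressed
    relative to the mean of the *other* chambers.  On background-corrected
    intensities this recovers a multiplicative chamber gain directly; on raw
    intensities the additive optical background shrinks the estimate toward 1.
    """
    probes = lowlevel.manifest.type_ii_probes()
    per_sample = lowlevel.mean_fi[channel].loc[probes].mean(axis=0)
    chamber = sheet.chamber_of().reindex(per_sample.index)
    per_chamber = per_sample.groupby(chamber).mean()
    out = {}
    for c in per_chamber.index:
        others = per_chamber.drop(index=c).mean()
        out[c] = per_chamber[c] / others
    return pd.Series(out).sort_index()
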