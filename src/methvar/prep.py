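"""Simplified preprocessing stages applied before the variability diagnostics.

Three stages, composed by :func:`run_prep` in the order mask -> dye-bias ->
background:

* **Detection p-values** against the per-sample empirical distribution of
  out-of-band intensities (the pOOBAH principle): a probe whose total
  in-band fluorescence is no brighter than background cannot be
  distinguished from a failed assay and is masked.
* **Normal-exponential background correction**: in-band intensities are
  replaced by the posterior expected true signal under signal ~ Exponential,
  noise ~ Normal, with background parameters estimated robustly
  (median/MAD) from each sample's out-of-band records.
* **Dye-bias scaling**: the red channel is linearly rescaled per sample so
  the median Type II red intensity matches the median Type II green
  intensity.

These are deliberately simplified stand-ins for a full production pipeline
(quality-mask catalogues and Infinium-I channel inference are omitted; the
simulated manifest has no mislabelled channels and no external mask list).
They are not intended to reproduce any external tool's exact numerical
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr

from .core import (
    CHANNELS,
    DEFAULT_BETA_OFFSET,
    LowLevelArraySet,
    betas_from_lowlevel,
)

DEFAULT_DETECTION_ALPHA = 0.05


class MissingBackgroundError(ValueError):
    """Raised when no out-of-band records exist to estimate background from."""


class DegenerateBackgroundError(ValueError):
    """Raised when the background spread estimate is not positive."""


class DegenerateChannelError(ValueError):
    """Raised when a channel's Type II median intensity is zero."""


@dataclass
class DetectionMask:
    """Per-(probe, sample) detection p-values and the masking decision."""

    pvalues: pd.DataFrame  # probes x samples, in [0, 1]
    alpha: float

    def __post_init__(self) -> None:
        vals = self.pvalues.to_numpy(float)
        finite = vals[~np.isnan(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def masked(self) -> pd.DataFrame:
        """True where the probe failed detection (p > alpha)."""
        return self.pvalues > self.alpha

    def detected_fraction(self) -> pd.Series:
        """Per sample, the fraction of probes passing detection."""
        return (self.pvalues <= self.alpha).mean(axis=0)


def detect_poobah(
    lowlevel: LowLevelArraySet, alpha: float = DEFAULT_DETECTION_ALPHA
) -> DetectionMask:
    """Detection p-values from the out-of-band empirical distribution.

    Per sample, ``p = 1 - F_oob(total in-band FI)`` where ``F_oob`` is the
    empirical CDF (mid-rank convention) of all out-of-band intensities of the
    sample, both channels pooled.  Total in-band FI is green + red for Type
    II probes and the design-channel intensity for Type I probes.
    """
    oob_any = any(lowlevel.oob_mask(ch).any() for ch in CHANNELS)
    if not oob_any:
        raise MissingBackgroundError("no out-of-band records in the array set")

    probes = lowlevel.probe_ids
    samples = lowlevel.sample_ids
    g = lowlevel.mean_fi["green"].to_numpy(float)
    r = lowlevel.mean_fi["red"].to_numpy(float)
    in_g = lowlevel.inband_mask("green").to_numpy()
    in_r = lowlevel.inband_mask("red").to_numpy()
    total = np.where(in_g[:, None], g, 0.0) + np.where(in_r[:, None], r, 0.0)

    oob_g = lowlevel.oob_mask("green").to_numpy()
    oob_r = lowlevel.oob_mask("red").to_numpy()

    p = np.empty_like(total)
    for j in range(total.shape[1]):
        oob = np.concatenate([g[oob_g, j], r[oob_r, j]])
        oob.sort()
        n = len(oob)
        lo = np.searchsorted(oob, total[:, j], side="left")
        hi = np.searchsorted(oob, total[:, j], side="right")
        # mid-rank ECDF: (#below + 0.5 * #equal) / n
        p[:, j] = 1.0 - (lo + 0.5 * (hi - lo)) / n
    return DetectionMask(
        pvalues=pd.DataFrame(p, index=probes, columns=samples), alpha=alpha
    )


# ---------------------------------------------------------------------------
# normal-exponential background correction
# ---------------------------------------------------------------------------


def _normexp_posterior_mean(x: np.ndarray, mu: float, sigma: float, alpha: float):
    """E[signal | observed] for signal ~ Exp(mean alpha), noise ~ N(mu, sigma^2).

    Stable for strongly negative standardized residuals via log-space
    evaluation of the inverse Mills ratio; output is strictly positive.
    """
    m = x - mu - sigma * sigma / alpha
    z = m / sigma
    # phi(z) / Phi(z) computed in log space
    log_mills = stats.norm.logpdf(z) - log_ndtr(z)
    return m + sigma * np.exp(log_mills)


def estimate_background(lowlevel: LowLevelArraySet) -> pd.DataFrame:
    """Per (sample, channel) robust background location/scale from OOB records.

    Returns a frame indexed by sample with columns ``mu_<ch>`` and
    ``sigma_<ch>`` (median and scaled MAD of the out-of-band intensities).
    """
    rows = {}
    for ch in CHANNELS:
        mask = lowlevel.oob_mask(ch).to_numpy()
        if not mask.any():
            raise MissingBackgroundError(f"no out-of-band records in {ch} channel")
        vals = lowlevel.mean_fi[ch].to_numpy(float)[mask]
        mu = np.median(vals, axis=0)
        sigma = 1.4826 * np.median(np.abs(vals - mu), axis=0)
        rows[f"mu_{ch}"] = mu
        rows[f"sigma_{ch}"] = sigma
    return pd.DataFrame(rows, index=lowlevel.sample_ids)


def background_correct_normexp(lowlevel: LowLevelArraySet) -> LowLevelArraySet:
    """Replace in-band intensities by their normexp posterior expected signal.

    Background parameters come from :func:`estimate_background` per sample
    and channel; the exponential signal mean is the per-channel mean in-band
    excess over background (floored at the background spread).  Out-of-band
    records are left untouched.
    """
    bg = estimate_background(lowlevel)
    out = lowlevel.copy()
    for ch in CHANNELS:
        inband = lowlevel.inband_mask(ch).to_numpy()
        vals = out.mean_fi[ch].to_numpy(float)
        for j, sample in enumerate(lowlevel.sample_ids):
            mu = float(bg.loc[sample, f"mu_{ch}"])
            sigma = float(bg.loc[sample, f"sigma_{ch}"])
            if sigma <= 0:
                raise DegenerateBackgroundError(
                    f"background sd estimate <= 0 for sample {sample} ({ch})"
                )
            alpha = max(float(vals[inband, j].mean() - mu), sigma)
            vals[inband, j] = _normexp_posterior_mean(vals[inband, j], mu, sigma, alpha)
        out.mean_fi[ch] = pd.DataFrame(
            vals, index=lowlevel.probe_ids, columns=lowlevel.sample_ids
        )
    return out


# ---------------------------------------------------------------------------
# dye-bias scaling
# ---------------------------------------------------------------------------


def dye_bias_scale(lowlevel: LowLevelArraySet) -> LowLevelArraySet:
    """Linear per-sample dye correction.

    The whole red channel (mean and bead-level SD) is rescaled so the median
    Type II red intensity equals the median Type II green intensity.
    """
    probes_ii = lowlevel.manifest.type_ii_probes()
    if not probes_ii:
        raise DegenerateChannelError("no Type II probes to calibrate dye bias on")
    med_g = lowlevel.mean_fi["green"].loc[probes_ii].median(axis=0)
    med_r = lowlevel.mean_fi["red"].loc[probes_ii].median(axis=0)
    if (med_g <= 0).any() or (med_r <= 0).any():
        bad = med_g.index[(med_g <= 0) | (med_r <= 0)]
        raise DegenerateChannelError(
            f"zero median Type II intensity for samples: {list(bad)}"
        )
    factor = med_g / med_r
    out = lowlevel.copy()
    out.mean_fi["red"] = out.mean_fi["red"] * factor
    out.sd_fi["red"] = out.sd_fi["red"] * factor
    return out


# ---------------------------------------------------------------------------
# composed pipeline
# ---------------------------------------------------------------------------


@dataclass
class PrepResult:
    lowlevel: LowLevelArraySet
    beta: pd.DataFrame  # Type II probes x samples, NaN where masked
    mask: DetectionMask
    detection_summary: pd.DataFrame  # per sample: detected fraction, outlier flag


def _flag_detection_outlier(rates: pd.Series) -> pd.DataFrame:
    """Grubbs screen for a sample with an abnormally low detection rate."""
    from .varmetrics import grubbs_test

    flagged = pd.Series(False, index=rates.index)
    p = np.nan
    vals = rates.to_numpy(float)
    if len(vals) >= 3 and np.ptp(vals) > 0:
        _, p = grubbs_test(vals)
        worst = rates.idxmin()
        is_low_extreme = np.abs(vals - vals.mean()).argmax() == int(
            np.argmin(vals)
        )
        if p < 0.05 and is_low_extreme:
            flagged[worst] = True
    return pd.DataFrame(
        {"detected_fraction": rates, "grubbs_p": p, "low_outlier": flagged}
    )


def run_prep(
    lowlevel: LowLevelArraySet,
    alpha: float = DEFAULT_DETECTION_ALPHA,
    beta_offset: float = DEFAULT_BETA_OFFSET,
) -> PrepResult:
    """Deterministic composition: detection mask -> dye bias -> normexp -> betas.

    Masked (probe, sample) entries become NA in the beta matrix.  The
    detection summary reports each sample's detected fraction together with a
    Grubbs single-outlier screen for abnormally low detection rates.
    """
    mask = detect_poobah(lowlevel, alpha)
    corrected = background_correct_normexp(dye_bias_scale(lowlevel))
    beta = betas_from_lowlevel(corrected, offset=beta_offset)
    masked = mask.masked.loc[beta.index, beta.columns]
    beta = beta.mask(masked)
    summary = _flag_detection_outlier(mask.detected_fraction())
    return PrepResult(
        lowlevel=corrected, beta=beta, mask=mask, detection_summary=summary
    )
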