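"""Detection p-values, normexp background correction, dye-bias scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import methvar as mv
from methvar import prep, synth
from methvar.prep import (
    DegenerateBackgroundError,
    DegenerateChannelError,
    MissingBackgroundError,
    _normexp_posterior_mean,
)

from conftest import make_lowlevel


def _with_background_probes(n_type_ii=3, n_samples=2, oob_green=(10, 20, 30, 40)):
    """Tiny array set: a few Type II probes plus Type I red-design probes whose
    green channel is out-of-band background."""
    n_oob = len(oob_green)
    rows = [(f"p{i}", "II", "both") for i in range(n_type_ii)]
    rows += [(f"bg{i}", "I", "red") for i in range(n_oob)]
    manifest = mv.ProbeManifest(
        pd.DataFrame(rows, columns=["probe_id", "probe_type", "design_channel"])
    )
    n_p = n_type_ii + n_oob
    green = np.zeros((n_p, n_samples))
    red = np.zeros((n_p, n_samples))
    green[n_type_ii:] = np.array(oob_green, float)[:, None]  # OOB records
    red[n_type_ii:] = 25.0  # in-band Type I design-channel reads
    return manifest, green, red


class TestDetectPoobah:
    def test_ecdf_extremes(self):
        manifest, green, red = _with_background_probes()
        green[0] = 1000.0  # far above all background
        red[0] = 1000.0
        green[1] = 1.0  # total below every OOB value
        red[1] = 1.0
        green[2] = 0.0
        red[2] = 0.0
        lowlevel = make_lowlevel(green, red, manifest=manifest)
        mask = prep.detect_poobah(lowlevel, alpha=0.05)
        assert (mask.pvalues.loc["p0"] == 0.0).all()
        assert (mask.pvalues.loc["p1"] == 1.0).all()
        assert not mask.masked.loc["p0"].any()
        assert mask.masked.loc["p1"].all()

    def test_masked_iff_p_above_alpha(self, null_dataset):
        _, _, _, lowlevel = null_dataset
        mask = prep.detect_poobah(lowlevel, alpha=0.6)
        pd.testing.assert_frame_equal(mask.masked, mask.pvalues > 0.6)

    def test_no_oob_records_raises(self):
        lowlevel = make_lowlevel(np.full((4, 2), 50.0), np.full((4, 2), 50.0))
        with pytest.raises(MissingBackgroundError):
            prep.detect_poobah(lowlevel, 0.05)

    def test_background_probes_get_uniform_pvalues(self):
        """Probes drawn from the background distribution are calibrated."""
        rng = np.random.default_rng(0)
        n_null, n_oob = 10_000, 10_000
        rows = [(f"n{i}", "I", "green") for i in range(n_null)]
        rows += [(f"b{i}", "I", "red") for i in range(n_oob)]
        manifest = mv.ProbeManifest(
            pd.DataFrame(rows, columns=["probe_id", "probe_type", "design_channel"])
        )
        green = np.zeros((n_null + n_oob, 1))
        red = np.zeros((n_null + n_oob, 1))
        # in-band reads of the null probes and OOB reads share one distribution
        green[:n_null, 0] = rng.normal(200, 30, n_null).clip(0)
        green[n_null:, 0] = rng.normal(200, 30, n_oob).clip(0)  # OOB for red-design
        red[:n_null, 0] = rng.normal(200, 30, n_null).clip(0)  # OOB for green-design
        red[n_null:, 0] = rng.normal(200, 30, n_oob).clip(0)
        lowlevel = make_lowlevel(green, red, manifest=manifest)
        p = prep.detect_poobah(lowlevel, 0.05).pvalues.iloc[:n_null, 0].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestNormexp:
    def test_posterior_mean_matches_numerical_integration(self):
        """The closed form equals the Bayes posterior mean computed by
        peak-aware quadrature."""
        mu, sigma, alpha = 100.0, 30.0, 500.0
        for x in (0.0, 50.0, 150.0, 600.0, 2000.0):
            pts = sorted({max(0.0, x - mu - 4 * sigma), max(0.0, x - mu), x - mu + 4 * sigma, 1.0})
            kwargs = dict(points=[p for p in pts if 0 < p < 6000], limit=200)
            num = integrate.quad(
                lambda s: s * stats.norm.pdf(x - s, mu, sigma) * stats.expon.pdf(s, scale=alpha),
                0, 6000, **kwargs,
            )[0]
            den = integrate.quad(
                lambda s: stats.norm.pdf(x - s, mu, sigma) * stats.expon.pdf(s, scale=alpha),
                0, 6000, **kwargs,
            )[0]
            got = float(_normexp_posterior_mean(np.array([x]), mu, sigma, alpha)[0])
            assert got == pytest.approx(num / den, rel=1e-6)

    def test_output_strictly_positive(self):
        x = np.array([0.0, 1.0, 50.0, 1e5])
        out = _normexp_posterior_mean(x, 300.0, 50.0, 800.0)
        assert (out > 0).all()

    def test_noise_free_limit_is_identity(self):
        x = np.linspace(10, 1000, 50)
        out = _normexp_posterior_mean(x, 0.0, 1e-6, 500.0)
        assert np.allclose(out, x, rtol=1e-4)

    def test_mean_signal_recovery(self):
        """On data with known exponential signal mean, the corrected mean
        recovers it closely."""
        rng = np.random.default_rng(3)
        n = 30_000
        signal_mean = 900.0
        signal = rng.exponential(signal_mean, n)
        observed = signal + rng.normal(200.0, 30.0, n)
        corrected = _normexp_posterior_mean(observed, 200.0, 30.0, signal_mean)
        assert corrected.mean() == pytest.approx(signal_mean, rel=0.05)

    def test_degenerate_background_raises(self):
        # constant out-of-band values in both channels -> MAD = 0
        rows = [("p0", "II", "both")]
        rows += [(f"bgg{i}", "I", "green") for i in range(4)]
        rows += [(f"bgr{i}", "I", "red") for i in range(4)]
        manifest = mv.ProbeManifest(
            pd.DataFrame(rows, columns=["probe_id", "probe_type", "design_channel"])
        )
        green = np.full((9, 2), 50.0)
        red = np.full((9, 2), 50.0)
        green[0] = red[0] = 500.0
        lowlevel = make_lowlevel(green, red, manifest=manifest)
        with pytest.raises(DegenerateBackgroundError):
            prep.background_correct_normexp(lowlevel)


class TestDyeBias:
    def test_exact_factor_for_doubled_red(self):
        rng = np.random.default_rng(4)
        green = rng.uniform(100, 5000, (40, 3))
        lowlevel = make_lowlevel(green, 2 * green)
        out = prep.dye_bias_scale(lowlevel)
        np.testing.assert_allclose(
            out.mean_fi["red"].to_numpy(), green, rtol=1e-12
        )

    def test_balanced_channels_untouched(self):
        rng = np.random.default_rng(5)
        green = rng.uniform(100, 5000, (41, 3))
        red = np.vstack([green[:-1], green[-1:]])  # identical medians
        out = prep.dye_bias_scale(make_lowlevel(green, green))
        np.testing.assert_allclose(out.mean_fi["red"].to_numpy(), green, rtol=1e-12)

    def test_medians_match_after_scaling(self, null_dataset):
        _, _, _, lowlevel = null_dataset
        out = prep.dye_bias_scale(lowlevel)
        probes = lowlevel.manifest.type_ii_probes()
        ratio = (
            out.mean_fi["red"].loc[probes].median()
            / out.mean_fi["green"].loc[probes].median()
        )
        assert np.allclose(ratio.to_numpy(), 1.0, atol=1e-9)

    def test_zero_median_raises(self):
        lowlevel = make_lowlevel(np.zeros((4, 2)), np.zeros((4, 2)))
        with pytest.raises(DegenerateChannelError):
            prep.dye_bias_scale(lowlevel)


class TestRunPrep:
    def test_background_free_balanced_input_keeps_raw_betas(self):
        """With negligible background and balanced dyes the pipeline is a
        near-identity on betas."""
        rng = np.random.default_rng(6)
        n_ii, n_bg = 50, 30
        rows = [(f"p{i}", "II", "both") for i in range(n_ii)]
        rows += [(f"bgg{i}", "I", "green") for i in range(n_bg)]
        rows += [(f"bgr{i}", "I", "red") for i in range(n_bg)]
        manifest = mv.ProbeManifest(
            pd.DataFrame(rows, columns=["probe_id", "probe_type", "design_channel"])
        )
        n_p = n_ii + 2 * n_bg
        green = rng.uniform(2000, 8000, (n_p, 4))
        red = green * rng.uniform(0.99, 1.01, (n_p, 4))
        # Type I rows carry near-zero values in both channels (their OOB reads
        # define a tiny background; their in-band reads don't enter betas)
        green[n_ii:] = rng.uniform(0.9, 1.1, (2 * n_bg, 4))
        red[n_ii:] = rng.uniform(0.9, 1.1, (2 * n_bg, 4))
        lowlevel = make_lowlevel(green, red, manifest=manifest)
        raw_beta = mv.betas_from_lowlevel(lowlevel)
        result = prep.run_prep(lowlevel, alpha=0.05)
        diff = (result.beta - raw_beta).abs().to_numpy()
        assert np.nanmax(diff) < 0.02

    def test_probe_order_equivariance(self, null_dataset):
        _, _, _, lowlevel = null_dataset
        perm = np.random.default_rng(7).permutation(len(lowlevel.probe_ids))
        probes = [lowlevel.probe_ids[i] for i in perm]
        manifest_p = mv.ProbeManifest(
            lowlevel.manifest.frame.set_index("probe_id")
            .loc[probes]
            .reset_index()
        )
        shuffled = mv.LowLevelArraySet(
            manifest=manifest_p,
            mean_fi={ch: lowlevel.mean_fi[ch].loc[probes] for ch in ("green", "red")},
            sd_fi={ch: lowlevel.sd_fi[ch].loc[probes] for ch in ("green", "red")},
            n_beads={ch: lowlevel.n_beads[ch].loc[probes] for ch in ("green", "red")},
        )
        a = prep.run_prep(lowlevel).beta
        b = prep.run_prep(shuffled).beta
        pd.testing.assert_frame_equal(b.sort_index(), a.sort_index())

    def test_low_detection_sample_is_grubbs_flagged(self, null_dataset):
        _, _, _, lowlevel = null_dataset
        broken = lowlevel.copy()
        victim = broken.sample_ids[5]
        rng = np.random.default_rng(8)
        kill = rng.uniform(size=len(broken.probe_ids)) < 0.4
        for ch in ("green", "red"):
            col = broken.mean_fi[ch][victim].to_numpy()
            col[kill] = rng.normal(100, 10, kill.sum()).clip(0)
            broken.mean_fi[ch][victim] = col
        result = prep.run_prep(broken)
        summary = result.detection_summary
        assert summary.loc[victim, "low_outlier"]
        assert summary["low_outlier"].sum() == 1
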