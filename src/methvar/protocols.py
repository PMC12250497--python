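"""Canned end-to-end experiments over synthetic replicate plates.

Each function sets up one of the package's standard study protocols —
null calibration, positional-bias recovery, correction efficacy, and the
planted clock-CpG outlier screen — runs it through the library, and returns
the headline numbers.  They are used by the acceptance script and the test
suite, and are convenient entry points for exploring the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import batchcorrect, clocks, dm_audit, prep, synth, varmetrics
from .core import betas_from_lowlevel, clean_matrix
from .synth import OutlierSpec, SimulationConfig


def _dataset(config: SimulationConfig):
    sheet, truth, lowlevel = synth.simulate_dataset(config)
    beta_raw = clean_matrix(betas_from_lowlevel(lowlevel))
    return sheet, truth, lowlevel, beta_raw


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------


def null_calibration(seed: int, n_probes: int = 20_000) -> dict:
    """Bias-free plate: every diagnostic should report a null result.

    Returns the maximum |mean|/SE over chamber z-score groups, the fraction
    of intensity bins within 3 SE of zero, the median mixed-model F
    statistics, the null-design false-positive count, and the KS uniformity
    p-value of the raw differential-methylation p-values.
    """
    cfg = SimulationConfig(n_probes=n_probes, seed=seed)
    sheet, truth, lowlevel, beta_raw = _dataset(cfg)

    pooled = sheet.pooled_only()
    z = varmetrics.within_subject_zscores(beta_raw[pooled.sample_ids], pooled)
    prof = varmetrics.chamber_profile(z, pooled)
    zmax = float((prof.summary["mean"].abs() / prof.summary["sem"]).max())

    fi = lowlevel.mean_fi["green"].loc[lowlevel.manifest.type_ii_probes()]
    bins = varmetrics.intensity_bin_bias(
        fi, lowlevel, sheet, bin_channel="green", mode="fi_deviation"
    )
    dev = bins.drop(columns="bin_median_fi")
    # bins use disjoint probe sets, so per-chamber bin deviations are
    # independent draws: a chamber-level z of the mean over bins is ~N(0,1)
    chamber_z = dev.mean(axis=0) / (dev.std(axis=0, ddof=1) / np.sqrt(len(dev)))
    bin_max_z = float(chamber_z.abs().max())

    vd = varmetrics.variance_decomposition(beta_raw, sheet)
    designs = dm_audit.build_plate_designs(sheet)
    null_design = [d for d in designs if d.audit_kind == "null"][0]
    report = dm_audit.run_audit(beta_raw, sheet, [null_design])
    fp = int(report.per_design["false_positives"].iloc[0])

    # calibration is checked on a global-null comparison: pooled replicates
    # of one subject split across chambers.  (The two-subject balanced null
    # above is deliberately conservative: subject spread cancels in the
    # group-mean difference but inflates the variance estimate.)
    frame = sheet.frame
    pooled_c = frame[(frame["subject"] == frame["subject"].iloc[0]) & frame["pooled"]]
    pooled_c = pooled_c.sort_values("chamber")
    low = list(pooled_c[pooled_c["chamber"] <= 4]["sample_id"])
    high = list(pooled_c[pooled_c["chamber"] >= 5]["sample_id"])
    raw_p = dm_audit.dmp_test(beta_raw, low, high)["p"].dropna()
    ks_p = float(stats.kstest(raw_p.to_numpy(), "uniform").pvalue)

    return {
        "zscore_max_abs_mean_over_se": zmax,
        "bin_max_abs_chamber_z": bin_max_z,
        "median_F_chamber": float(vd.frame["F_chamber"].median()),
        "median_F_slide": float(vd.frame["F_slide"].median()),
        "null_false_positives": fp,
        "dm_pvalue_ks_p": ks_p,
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# bias recovery
# ---------------------------------------------------------------------------


def bias_recovery(seed: int, n_probes: int = 20_000) -> dict:
    """Biased plate (chamber-1 gain 0.8, chamber-8 red CV x1.5): recover both.

    The chamber gain is estimated from background-corrected intensities
    (grand-mean per chamber relative to the others); the CV injection is
    checked by the chamber ranking of median bead-level CV in red.
    """
    cfg = synth.biased_scenario(n_probes=n_probes, seed=seed)
    sheet, truth, lowlevel, beta_raw = _dataset(cfg)

    corrected = prep.background_correct_normexp(lowlevel)
    est = {
        ch: varmetrics.chamber_gain_estimate(corrected, sheet, ch)
        for ch in ("green", "red")
    }
    cv = varmetrics.bead_cv(lowlevel, sheet)
    red = cv.summary[cv.summary["channel"] == "red"].set_index("chamber")["median"]
    vd = varmetrics.variance_decomposition(beta_raw, sheet)
    return {
        "chamber1_gain_green": float(est["green"][1]),
        "chamber1_gain_red": float(est["red"][1]),
        "chamber8_red_cv_rank": int((-red).rank()[8]),  # 1 = highest CV
        "chamber8_red_cv_ratio": float(red[8] / red.drop(index=8).median()),
        "median_F_chamber": float(vd.frame["F_chamber"].median()),
        "median_F_slide": float(vd.frame["F_slide"].median()),
        "n_probes": n_probes,
    }


# ---------------------------------------------------------------------------
# correction efficacy
# ---------------------------------------------------------------------------


def correction_efficacy(seed: int, n_probes: int = 20_000) -> dict:
    """Clustering purity and null-design false positives before/after EB
    correction on one biased plate."""
    cfg = synth.biased_scenario(n_probes=n_probes, seed=seed)
    sheet, truth, lowlevel, beta_raw = _dataset(cfg)
    chamber = sheet.chamber_of()

    purity_before = varmetrics.pca_cluster(beta_raw, sheet).purity
    adjusted = batchcorrect.combat_adjust(beta_raw, chamber)
    purity_after = varmetrics.pca_cluster(adjusted, sheet).purity

    designs = dm_audit.build_plate_designs(sheet)
    null_design = [d for d in designs if d.audit_kind == "null"]
    fp_raw = int(
        dm_audit.run_audit(beta_raw, sheet, null_design)
        .per_design["false_positives"].iloc[0]
    )
    fp_adjusted = int(
        dm_audit.run_audit(adjusted, sheet, null_design)
        .per_design["false_positives"].iloc[0]
    )
    return {
        "purity_before": float(purity_before),
        "purity_after": float(purity_after),
        "fp_raw": fp_raw,
        "fp_adjusted": fp_adjusted,
        "fp_drop_fraction": (fp_raw - fp_adjusted) / fp_raw if fp_raw else np.nan,
        "n_probes": n_probes,
    }


def fp_pipeline_ordering(
    seeds, n_probes: int = 5000
) -> pd.DataFrame:
    """Null-design false positives per preprocessing arm over several seeds.

    Arms: raw betas, prep (mask + dye + normexp), prep + EB chamber
    correction.  Returns one row per seed.
    """
    rows = []
    for seed in seeds:
        cfg = synth.biased_scenario(n_probes=n_probes, seed=int(seed))
        sheet, truth, lowlevel, beta_raw = _dataset(cfg)
        pres = prep.run_prep(lowlevel)
        beta_prep = clean_matrix(pres.beta)
        beta_eb = batchcorrect.combat_adjust(beta_prep, sheet.chamber_of())
        null_design = [
            d for d in dm_audit.build_plate_designs(sheet) if d.audit_kind == "null"
        ]
        fp = {}
        for arm, mat in (("raw", beta_raw), ("prep", beta_prep), ("eb", beta_eb)):
            fp[arm] = int(
                dm_audit.run_audit(mat, sheet, null_design)
                .per_design["false_positives"].iloc[0]
            )
        rows.append({"seed": int(seed), **fp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted clock-CpG outlier
# ---------------------------------------------------------------------------


@dataclass
class PlantedOutlierResult:
    target: str
    victim: str
    top_probe: str
    top_subject: str
    ranked_first: bool
    grubbs_flagged: bool


def planted_outlier_experiment(
    seed: int,
    n_probes: int = 400,
    n_clock_cpgs: int = 30,
    fi_shift: float = 4000.0,
    n_beads: int = 4,
) -> PlantedOutlierResult:
    """Inject one low-bead-count, shifted-FI replicate at a high-coefficient
    clock CpG and recover it from the stability report.

    The synthetic clock draws coefficients around zero and designates one
    CpG (baseline beta away from 1, so a green-channel shift moves its beta)
    as the high-coefficient CpG; the injection lands there, in one replicate
    of one subject, green channel only.  Recovery means: that (CpG, subject)
    tops the influence ranking and the Grubbs screen flags the injected
    sample's green mean FI at p < 0.05.
    """
    cfg = SimulationConfig(n_probes=n_probes, seed=seed)
    sheet = synth.replicate_plate_layout(cfg)
    truth = synth.simulate_truth(cfg)
    manifest = synth.make_manifest(cfg.n_probes, cfg.type_i_fraction)
    rng = np.random.default_rng(seed)

    clock_probes = list(rng.choice(manifest.type_ii_probes(), n_clock_cpgs, False))
    baseline = truth.true_beta.mean(axis=1)
    candidates = [p for p in clock_probes if baseline[p] < 0.6]
    target = candidates[0] if candidates else clock_probes[0]
    coefficients = {p: float(rng.normal(0.0, 0.3)) for p in clock_probes}
    coefficients[target] = 1.0
    clock = clocks.ClockDefinition("synthetic-30cpg", 30.0, coefficients, "identity")

    subject = str(truth.true_beta.columns[0])
    victim = sheet.frame[sheet.frame["subject"] == subject]["sample_id"].iloc[3]
    cfg_out = synth.SimulationConfig(
        n_probes=n_probes,
        seed=seed,
        outlier_plan=[
            OutlierSpec(target, victim, n_beads=n_beads, fi_shift=fi_shift,
                        channel="green")
        ],
    )
    lowlevel = synth.simulate_intensities(truth, sheet, cfg_out)
    beta = betas_from_lowlevel(lowlevel)
    report = clocks.clock_stability_report(beta, sheet, clock, lowlevel=lowlevel)

    top = report.cpg_table.iloc[0]
    ranked_first = bool(top["probe_id"] == target and top["subject"] == subject)
    fl = report.flagged
    hit = fl[
        (fl["probe_id"] == target)
        & (fl["channel"] == "green")
        & (fl["quantity"] == "mean_fi")
        & (fl["p"] < 0.05)
        & (fl["outlier_sample"] == victim)
    ]
    return PlantedOutlierResult(
        target=target,
        victim=victim,
        top_probe=str(top["probe_id"]),
        top_subject=str(top["subject"]),
        ranked_first=ranked_first,
        grubbs_flagged=len(hit) == 1,
    )


def planted_outlier_recovery_rate(seed: int, n_reps: int = 100) -> float:
    """Fraction of seeded repetitions in which the planted outlier is fully
    recovered (ranked first and Grubbs-flagged in the green channel)."""
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    ok = 0
    for s in sub_seeds:
        result = planted_outlier_experiment(int(s))
        ok += result.ranked_first and result.grubbs_flagged
    return ok / n_reps
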