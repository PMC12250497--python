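"""Generic linear epigenetic-clock application and replicate-stability audit.

A clock is a linear predictor over CpG beta values, ``s = intercept +
sum_j coef_j * beta_j``, optionally passed through the standard log-linear
age transform used by published chronological-age clocks:

    age = (1 + adult_age) * exp(s) - 1        if s < 0
    age = adult_age + s * (1 + adult_age)     otherwise

(the inverse of the training-side transform that compresses childhood ages
logarithmically and is linear past ``adult_age``).

Published coefficient sets are external user-supplied inputs; this module
ships only the applier and a replicate-stability report that ranks clock
CpGs by their influence (within-subject beta range times |coefficient|) and
screens high-influence CpGs for single-sample outliers in the low-level
fluorescence data with the Grubbs test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CHANNELS, LowLevelArraySet, SampleSheet, ValidationError
from .varmetrics import grubbs_test


class CoverageError(ValueError):
    """Raised when too few clock probes are available in the matrix."""


@dataclass
class ClockDefinition:
    name: str
    intercept: float
    coefficients: dict  # probe_id -> coefficient
    age_transform: str = "identity"  # identity | log_linear
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.age_transform not in ("identity", "log_linear"):
            raise ValidationError(f"unknown age_transform {self.age_transform!r}")
        if self.age_transform == "log_linear" and self.adult_age <= 0:
            raise ValidationError("adult_age must be > 0 for log_linear")
        if len(set(self.coefficients)) != len(self.coefficients):
            raise ValidationError("duplicate clock probe ids")

    @property
    def probe_ids(self) -> list:
        return list(self.coefficients)


def inverse_age_transform(s: np.ndarray, adult_age: float) -> np.ndarray:
    """Anti-transform of the log-linear age scale (fixed point: s=0 -> adult_age)."""
    s = np.asarray(s, float)
    return np.where(
        s < 0, (1 + adult_age) * np.exp(s) - 1, adult_age + s * (1 + adult_age)
    )


# -- coefficient file round trip (CSV with a metadata header line) -----------


def write_clock_csv(clock: ClockDefinition, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# name={clock.name},intercept={clock.intercept!r},"
            f"transform={clock.age_transform},adult_age={clock.adult_age!r}\n"
        )
        fh.write("probe_id,coefficient\n")
        for probe, coef in clock.coefficients.items():
            fh.write(f"{probe},{coef!r}\n")


def read_clock_csv(path) -> ClockDefinition:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# "):
            raise ValidationError("clock file must start with a '# key=value' line")
        meta = dict(kv.split("=", 1) for kv in header[2:].split(","))
        table = pd.read_csv(fh)
    return ClockDefinition(
        name=meta["name"],
        intercept=float(meta["intercept"]),
        coefficients=dict(
            zip(table["probe_id"].astype(str), table["coefficient"].astype(float))
        ),
        age_transform=meta.get("transform", "identity"),
        adult_age=float(meta.get("adult_age", 20.0)),
    )


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------


def apply_clock(
    beta: pd.DataFrame,
    clock: ClockDefinition,
    missing_policy: str = "error",
    min_coverage: float = 0.95,
) -> pd.Series:
    """Predicted age per sample.

    ``missing_policy="error"`` refuses any missing clock probe value;
    ``"mean_impute_from_cohort"`` fills NA entries with the probe's mean over
    the samples that do have it.  Probes entirely absent from the matrix can
    never be imputed and always raise.  Coverage below ``min_coverage``
    raises listing the missing probes.
    """
    if missing_policy not in ("error", "mean_impute_from_cohort"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    probes = clock.probe_ids
    present = [p for p in probes if p in beta.index]
    absent = [p for p in probes if p not in beta.index]
    coverage = len(present) / len(probes) if probes else 1.0
    if coverage < min_coverage or (absent and missing_policy == "error"):
        raise CoverageError(
            f"clock {clock.name}: {len(absent)} probes absent "
            f"(coverage {coverage:.3f} < {min_coverage}): {absent[:10]}"
        )
    if absent:
        raise CoverageError(
            f"clock {clock.name}: probes absent from matrix cannot be imputed: "
            f"{absent[:10]}"
        )
    sub = beta.loc[present].astype(float)
    if sub.isna().any().any():
        if missing_policy == "error":
            bad = sub.index[sub.isna().any(axis=1)]
            raise CoverageError(
                f"clock {clock.name}: missing values for probes {list(bad)[:10]}"
            )
        sub = sub.apply(lambda row: row.fillna(row.mean()), axis=1)
        if sub.isna().any().any():
            raise CoverageError("some clock probes have no observed values at all")
    coef = np.array([clock.coefficients[p] for p in present])
    s = clock.intercept + coef @ sub.to_numpy(float)
    if clock.age_transform == "log_linear":
        s = inverse_age_transform(s, clock.adult_age)
    return pd.Series(s, index=beta.columns, name=f"{clock.name}_age")


# ---------------------------------------------------------------------------
# replicate-stability report
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Per clock-CpG replicate stability plus the outlier screen."""

    cpg_table: pd.DataFrame  # (probe, subject): mean, range, coefficient, influence
    prediction_spread: pd.DataFrame  # per subject: sd / n of predicted ages
    flagged: pd.DataFrame  # Grubbs screen rows for high-influence CpGs
    influence_threshold: float


def clock_stability_report(
    beta: pd.DataFrame,
    sheet: SampleSheet,
    clock: ClockDefinition,
    lowlevel: LowLevelArraySet | None = None,
    influence_threshold: float | None = None,
    missing_policy: str = "mean_impute_from_cohort",
) -> StabilityReport:
    """Replicate stability of clock CpGs and of the clock's predictions.

    Per clock CpG and subject: mean and range of betas across the subject's
    technical replicates, and influence = range x |coefficient|.  Per
    subject: SD of predicted ages across replicates.  CpG/subject rows whose
    influence exceeds the threshold (default: 5x the median positive
    influence) are screened, when low-level data are supplied, with the
    Grubbs one-outlier test on mean FI and bead-level SD in each channel
    across that subject's replicates.
    """
    probes = [p for p in clock.probe_ids if p in beta.index]
    sub = sheet.subset(beta.columns)
    groups = sub.groups("subject")
    for subject, samples in groups.items():
        if len([s for s in samples if s in beta.columns]) < 2:
            raise ValidationError(f"subject {subject!r} has fewer than 2 replicates")

    rows = []
    spread_rows = []
    for subject, samples in groups.items():
        samples = [s for s in samples if s in beta.columns]
        block = beta.loc[probes, samples]
        rng = block.max(axis=1) - block.min(axis=1)
        mean = block.mean(axis=1)
        for p in probes:
            coef = clock.coefficients[p]
            rows.append(
                {
                    "probe_id": p,
                    "subject": subject,
                    "mean": float(mean[p]),
                    "range": float(rng[p]),
                    "coefficient": coef,
                    "influence": float(rng[p]) * abs(coef),
                }
            )
        ages = apply_clock(
            beta[samples], clock, missing_policy=missing_policy, min_coverage=0.0
        )
        spread_rows.append(
            {"subject": subject, "prediction_sd": float(ages.std(ddof=1)),
             "n_replicates": len(samples)}
        )
    cpg_table = pd.DataFrame(rows).sort_values("influence", ascending=False)
    cpg_table = cpg_table.reset_index(drop=True)

    positive = cpg_table.loc[cpg_table["influence"] > 0, "influence"]
    if influence_threshold is None:
        influence_threshold = 5.0 * float(positive.median()) if len(positive) else 0.0

    flagged_rows = []
    if lowlevel is not None:
        hits = cpg_table[cpg_table["influence"] > influence_threshold]
        for _, hit in hits.iterrows():
            samples = [
                s for s in groups[hit["subject"]] if s in beta.columns
            ]
            for ch in CHANNELS:
                for quantity, table in (
                    ("mean_fi", lowlevel.mean_fi[ch]),
                    ("sd_fi", lowlevel.sd_fi[ch]),
                ):
                    vals = table.loc[hit["probe_id"], samples].to_numpy(float)
                    if len(vals) < 3 or np.ptp(vals) == 0:
                        continue
                    G, p = grubbs_test(vals)
                    outlier = samples[int(np.argmax(np.abs(vals - vals.mean())))]
                    flagged_rows.append(
                        {
                            "probe_id": hit["probe_id"],
                            "subject": hit["subject"],
                            "channel": ch,
                            "quantity": quantity,
                            "G": G,
                            "p": p,
                            "outlier_sample": outlier,
                            "n_beads": int(
                                lowlevel.n_beads[ch].loc[hit["probe_id"], outlier]
                            ),
                        }
                    )
    flag_cols = [
        "probe_id", "subject", "channel", "quantity", "G", "p",
        "outlier_sample", "n_beads",
    ]
    return StabilityReport(
        cpg_table=cpg_table,
        prediction_spread=pd.DataFrame(spread_rows).set_index("subject"),
        flagged=pd.DataFrame(flagged_rows, columns=flag_cols),
        influence_threshold=influence_threshold,
    )
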