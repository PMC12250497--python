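"""Core containers and low-level plumbing for BeadChip replicate experiments.

The objects here mirror what an Illumina-style methylation array actually
records per sample: for every probe and colour channel, the mean fluorescence
intensity (FI) across beads, the bead-level FI standard deviation, and the
number of beads.  A sample sheet maps each assay to its physical position
(slide / Sentrix barcode, chamber / Sentrix position 1-8) and to the subject
and preparation arm it belongs to; a probe manifest records the Infinium
design (Type I with a single design channel, Type II read in both channels).

Beta values (methylation fractions) are derived from Type II probe pairs as
``m / (m + u + offset)`` with the conventional intensity stabiliser.  Type I
probes contribute their out-of-band channel as an empirical background sample
and are not converted to betas here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CHANNELS = ("green", "red")

#: chamber number -> Sentrix position label (one-column EPIC-style layout)
SENTRIX_POSITIONS = {c: f"R0{c}C01" for c in range(1, 9)}

DEFAULT_BETA_OFFSET = 100.0
DEFAULT_MAX_NA_FRACTION = 0.10


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a beta value is requested for an all-zero pair with zero offset."""


class ImputeImpossibleError(ValueError):
    """Raised when a probe retained by the NA filter has no observed values."""


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Sample -> (subject, slide, chamber, pooled) mapping.

    ``frame`` holds one row per assay with columns
    ``sample_id, subject, slide, chamber, pooled``.  Invariants: sample ids
    are unique, chambers lie in 1..8, and each physical (slide, chamber) cell
    carries at most one sample.
    """

    frame: pd.DataFrame

    COLUMNS = ("sample_id", "subject", "slide", "chamber", "pooled")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate sample_id: {sorted(set(dup))}")
        chamber = pd.to_numeric(df["chamber"], errors="coerce")
        bad = df.loc[~chamber.isin(range(1, 9)), "sample_id"]
        if len(bad):
            raise ValidationError(
                f"chamber outside 1..8 for samples: {list(bad)}"
            )
        df["chamber"] = chamber.astype(int)
        df["pooled"] = df["pooled"].astype(bool)
        df["sample_id"] = df["sample_id"].astype(str)
        df["subject"] = df["subject"].astype(str)
        df["slide"] = df["slide"].astype(str)
        cells = df[["slide", "chamber"]].apply(tuple, axis=1)
        dup_cells = cells[cells.duplicated()]
        if len(dup_cells):
            raise ValidationError(
                f"(slide, chamber) cell occupied twice: {sorted(set(dup_cells))}"
            )
        self.frame = df

    # -- convenience accessors ------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def subject_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["subject"]

    def chamber_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["chamber"]

    def slide_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["slide"]

    def pooled_only(self) -> "SampleSheet":
        return SampleSheet(self.frame[self.frame["pooled"]].reset_index(drop=True))

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        keep = set(sample_ids)
        return SampleSheet(
            self.frame[self.frame["sample_id"].isin(keep)].reset_index(drop=True)
        )

    def groups(self, by: str) -> Mapping[object, list[str]]:
        """Sample ids grouped by ``subject``, ``slide`` or ``chamber``."""
        return {
            key: list(sub["sample_id"])
            for key, sub in self.frame.groupby(by, sort=True)
        }

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path)
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# probe manifest
# ---------------------------------------------------------------------------


@dataclass
class ProbeManifest:
    """Probe -> (Infinium type, design channel) mapping.

    Type II probes read methylated signal in green and unmethylated in red on
    one bead type (``design_channel == "both"``); Type I probes have a single
    design channel and an out-of-band read in the other channel.
    """

    frame: pd.DataFrame

    COLUMNS = ("probe_id", "probe_type", "design_channel")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        df["probe_id"] = df["probe_id"].astype(str)
        dup = df["probe_id"][df["probe_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate probe_id: {sorted(set(dup))[:5]}")
        bad_type = df.loc[~df["probe_type"].isin(["I", "II"]), "probe_id"]
        if len(bad_type):
            raise ValidationError(f"probe_type not in {{I, II}}: {list(bad_type)[:5]}")
        bad_chan = df.loc[
            ~df["design_channel"].isin(["green", "red", "both"]), "probe_id"
        ]
        if len(bad_chan):
            raise ValidationError(f"bad design_channel for: {list(bad_chan)[:5]}")
        ii_bad = df.loc[
            (df["probe_type"] == "II") & (df["design_channel"] != "both"), "probe_id"
        ]
        if len(ii_bad):
            raise ValidationError(
                f"Type II probes must have design_channel=both: {list(ii_bad)[:5]}"
            )
        i_bad = df.loc[
            (df["probe_type"] == "I") & (df["design_channel"] == "both"), "probe_id"
        ]
        if len(i_bad):
            raise ValidationError(
                f"Type I probes need a single design channel: {list(i_bad)[:5]}"
            )
        self.frame = df

    @property
    def probe_ids(self) -> list[str]:
        return list(self.frame["probe_id"])

    def type_ii_probes(self) -> list[str]:
        f = self.frame
        return list(f.loc[f["probe_type"] == "II", "probe_id"])

    def type_i_probes(self, design_channel: str | None = None) -> list[str]:
        f = self.frame[self.frame["probe_type"] == "I"]
        if design_channel is not None:
            f = f[f["design_channel"] == design_channel]
        return list(f["probe_id"])

    def oob_channel_of(self) -> pd.Series:
        """Per Type I probe, the channel read out-of-band (the non-design one)."""
        f = self.frame[self.frame["probe_type"] == "I"]
        other = f["design_channel"].map({"green": "red", "red": "green"})
        return pd.Series(other.values, index=f["probe_id"].values, name="oob_channel")

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def load_manifest(path) -> ProbeManifest:
    return ProbeManifest(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# low-level array set
# ---------------------------------------------------------------------------


@dataclass
class LowLevelArraySet:
    """Per-sample, per-probe, per-channel bead summaries.

    For each channel, ``mean_fi``, ``sd_fi`` and ``n_beads`` are probes x
    samples DataFrames aligned on the manifest's probe order.  Whether a
    (probe, channel) record is in-band or out-of-band is a property of the
    manifest, not stored per sample: for a Type I probe the non-design channel
    row is the out-of-band background read.
    """

    manifest: ProbeManifest
    mean_fi: dict[str, pd.DataFrame]
    sd_fi: dict[str, pd.DataFrame]
    n_beads: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        probes = self.manifest.probe_ids
        for ch in CHANNELS:
            for name, table in (
                ("mean_fi", self.mean_fi),
                ("sd_fi", self.sd_fi),
                ("n_beads", self.n_beads),
            ):
                if ch not in table:
                    raise ValidationError(f"{name} missing channel {ch}")
                if list(table[ch].index) != probes:
                    table[ch] = table[ch].reindex(probes)
            mf, sf, nb = self.mean_fi[ch], self.sd_fi[ch], self.n_beads[ch]
            if not (mf.shape == sf.shape == nb.shape):
                raise ValidationError(f"channel {ch} tables have unequal shapes")
            arr = mf.to_numpy(float)
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValidationError(f"non-finite or negative mean_fi in {ch}")
            if (sf.to_numpy(float) < 0).any():
                raise ValidationError(f"negative sd_fi in {ch}")
            few = nb.to_numpy() <= 1
            if (sf.to_numpy(float)[few] != 0).any():
                raise ValidationError("sd_fi must be 0 where n_beads <= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mean_fi["green"].columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.mean_fi["green"].index)

    def oob_mask(self, channel: str) -> pd.Series:
        """Boolean per probe: is this channel out-of-band for the probe?"""
        f = self.manifest.frame.set_index("probe_id")
        is_oob = (f["probe_type"] == "I") & (f["design_channel"] != channel)
        return is_oob.reindex(self.probe_ids).fillna(False)

    def inband_mask(self, channel: str) -> pd.Series:
        f = self.manifest.frame.set_index("probe_id")
        inband = (f["design_channel"] == "both") | (f["design_channel"] == channel)
        return inband.reindex(self.probe_ids).fillna(False)

    def oob_values(self, sample_id: str) -> np.ndarray:
        """All out-of-band intensities for one sample, both channels pooled."""
        parts = []
        for ch in CHANNELS:
            mask = self.oob_mask(ch).to_numpy()
            parts.append(self.mean_fi[ch].loc[mask, sample_id].to_numpy(float))
        return np.concatenate(parts)

    def copy(self) -> "LowLevelArraySet":
        return LowLevelArraySet(
            manifest=self.manifest,
            mean_fi={ch: self.mean_fi[ch].copy() for ch in CHANNELS},
            sd_fi={ch: self.sd_fi[ch].copy() for ch in CHANNELS},
            n_beads={ch: self.n_beads[ch].copy() for ch in CHANNELS},
        )

    # -- disk round trip ------------------------------------------------------

    def to_dir(self, outdir) -> None:
        """Write one long-format TSV per channel (plus the manifest)."""
        import os

        os.makedirs(outdir, exist_ok=True)
        for ch in CHANNELS:
            oob = self.oob_mask(ch)
            def melt(df, name):
                return (
                    df.rename_axis("probe_id")
                    .reset_index()
                    .melt(id_vars="probe_id", var_name="sample_id", value_name=name)
                )

            long = melt(self.mean_fi[ch], "mean_fi")
            long["sd_fi"] = melt(self.sd_fi[ch], "sd_fi")["sd_fi"]
            long["n_beads"] = melt(self.n_beads[ch], "n_beads")["n_beads"]
            long["oob"] = long["probe_id"].map(oob).astype(bool)
            long.to_csv(os.path.join(outdir, f"lowlevel_{ch}.tsv"), sep="\t", index=False)
        self.manifest.to_tsv(os.path.join(outdir, "manifest.tsv"))

    @classmethod
    def from_dir(cls, indir) -> "LowLevelArraySet":
        import os

        manifest = load_manifest(os.path.join(indir, "manifest.tsv"))
        mean_fi, sd_fi, n_beads = {}, {}, {}
        for ch in CHANNELS:
            long = pd.read_csv(
                os.path.join(indir, f"lowlevel_{ch}.tsv"), sep="\t",
                float_precision="round_trip",
            )
            need = {"probe_id", "sample_id", "mean_fi", "sd_fi", "n_beads"}
            if not need <= set(long.columns):
                raise ValidationError(
                    f"lowlevel_{ch}.tsv missing columns {need - set(long.columns)}"
                )
            mean_fi[ch] = long.pivot(index="probe_id", columns="sample_id", values="mean_fi")
            sd_fi[ch] = long.pivot(index="probe_id", columns="sample_id", values="sd_fi")
            n_beads[ch] = long.pivot(
                index="probe_id", columns="sample_id", values="n_beads"
            ).astype(int)
            sample_order = list(pd.unique(long["sample_id"]))
            for tbl in (mean_fi, sd_fi, n_beads):
                tbl[ch] = tbl[ch].reindex(index=manifest.probe_ids,
                                          columns=sample_order)
                tbl[ch].columns.name = None
                tbl[ch].index.name = None
        return cls(manifest=manifest, mean_fi=mean_fi, sd_fi=sd_fi, n_beads=n_beads)


# ---------------------------------------------------------------------------
# beta computation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MethylPair:
    """Methylated / unmethylated mean-FI pair (Type II: m = green, u = red)."""

    m: float
    u: float

    def __post_init__(self) -> None:
        if self.m < 0 or self.u < 0:
            raise ValidationError("MethylPair intensities must be non-negative")


def compute_beta(pair: MethylPair, offset: float = DEFAULT_BETA_OFFSET) -> float:
    """Methylation fraction beta = m / (m + u + offset), in [0, 1]."""
    if offset < 0:
        raise ValidationError("offset must be non-negative")
    denom = pair.m + pair.u + offset
    if denom == 0:
        raise UndefinedRatioError("beta undefined for m = u = offset = 0")
    return float(pair.m / denom)


def betas_from_lowlevel(
    lowlevel: LowLevelArraySet, offset: float = DEFAULT_BETA_OFFSET
) -> pd.DataFrame:
    """Beta matrix (probes x samples) for Type II probes: green / (green+red+offset)."""
    probes = lowlevel.manifest.type_ii_probes()
    g = lowlevel.mean_fi["green"].loc[probes].to_numpy(float)
    r = lowlevel.mean_fi["red"].loc[probes].to_numpy(float)
    beta = g / (g + r + offset)
    return pd.DataFrame(beta, index=probes, columns=lowlevel.sample_ids)


# ---------------------------------------------------------------------------
# missingness handling
# ---------------------------------------------------------------------------


def clean_matrix(
    beta: pd.DataFrame,
    max_na_fraction: float = DEFAULT_MAX_NA_FRACTION,
    median_convention: str = "lower",
) -> pd.DataFrame:
    """Drop high-missingness probes, then median-impute the rest.

    Probes whose NA fraction strictly exceeds ``max_na_fraction`` are removed;
    remaining NAs are replaced by the probe's median across observed samples.
    ``median_convention="lower"`` takes the lower of the two central order
    statistics for even counts; ``"midpoint"`` averages them.
    """
    if not 0 <= max_na_fraction <= 1:
        raise ValidationError("max_na_fraction must lie in [0, 1]")
    values = beta.to_numpy(float)
    na = np.isnan(values)
    keep = na.mean(axis=1) <= max_na_fraction
    values = values[keep]
    na = na[keep]
    if na.any():
        all_na = na.all(axis=1)
        if all_na.any():
            raise ImputeImpossibleError(
                f"{int(all_na.sum())} retained probe(s) have no observed values"
            )
        meds = np.empty(values.shape[0])
        for i in np.flatnonzero(na.any(axis=1)):
            obs = np.sort(values[i][~na[i]])
            k = len(obs)
            if median_convention == "lower":
                meds_i = obs[(k - 1) // 2]
            else:
                meds_i = float(np.median(obs))
            values[i][na[i]] = meds_i
        # rows without NAs never consulted meds
    out = pd.DataFrame(values, index=beta.index[keep], columns=beta.columns)
    return out


# ---------------------------------------------------------------------------
# matrix I/O (TSV, probes x samples, "NA" for missing)
# ---------------------------------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path) -> None:
    # shortest-repr floats + round_trip parsing give bit-identical round trips
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col="probe_id", na_values=["NA"],
        float_precision="round_trip",
    )
    df.index.name = None
    return df
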