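"""Replicate-plate simulator.

Generates datasets with the statistical structure of a technical-replicate
BeadChip experiment: a small number of subjects, each assayed many times
(pooled aliquots of one DNA preparation plus independently prepared
replicates), laid out across slides (Sentrix barcodes) and chambers (Sentrix
positions 1-8).  The default study design is four subjects with sixteen
assays each: eight pooled replicates covering every chamber number exactly
once across four slides, plus eight independently prepared replicates.

The intensity model, per probe and channel:

* a latent probe brightness ``B`` drawn log-normally (a probe property,
  shared across samples);
* Type II probes emit methylated signal ``B * beta * gain[chamber, green]``
  in green and unmethylated ``B * (1 - beta) * gain[chamber, red]`` in red;
* an additive optical background ``N(background_mean, background_sd)``;
* bead-sampling noise with standard error ``sd_fi / sqrt(n_beads)`` where
  the bead-level spread ``sd_fi`` is proportional to the expected total
  brightness times a per-chamber CV inflation factor;
* bead counts are shifted-Poisson, shared between the two colour channels of
  a probe (one physical bead type per Type II probe).

Chamber-specific multiplicative gains and CV inflation factors inject the
positional biases the diagnostics are meant to recover (a dim chamber 1 and
a noisy chamber 8 in the bundled scenario).  Out-of-band records of Type I
probes are pure background draws, which is what makes them usable as an
empirical background sample for detection p-values and normexp correction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNELS,
    SENTRIX_POSITIONS,
    LowLevelArraySet,
    ProbeManifest,
    SampleSheet,
    ValidationError,
)


class LayoutError(ValueError):
    """Raised when the requested plate layout cannot be constructed."""


@dataclass
class OutlierSpec:
    """A planted low-level anomaly: one probe in one sample."""

    probe_id: str
    sample_id: str
    n_beads: int
    fi_shift: float
    channel: str = "both"  # green | red | both


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the replicate-plate simulator.

    Defaults encode the study conditions the package is built around: four
    subjects, eight pooled plus eight independently prepared replicates each,
    with no positional bias.  Biased scenarios are expressed by populating
    ``chamber_gain`` / ``chamber_cv_inflation`` (see :func:`biased_scenario`).
    """

    n_subjects: int = 4
    n_pooled_per_subject: int = 8
    n_independent_per_subject: int = 8
    n_probes: int = 20_000
    #: sparse {chamber: {channel: multiplicative gain}}, default 1.0
    chamber_gain: dict = field(default_factory=dict)
    #: sparse {chamber: {channel: multiplier on bead-level noise}}, default 1.0
    chamber_cv_inflation: dict = field(default_factory=dict)
    #: SD of per-subject deviations from the probe's baseline beta
    subject_effect_sd: float = 0.01
    #: extra beta-scale noise for independently prepared replicates
    prep_noise_sd: float = 0.005
    bead_count_mean: float = 14.0
    background_mean: float = 200.0
    background_sd: float = 30.0
    #: slides available to the pooled arm (the design rule requires >= 4)
    n_pooled_slides: int = 4
    #: fraction of probes given an Infinium Type I design (background donors)
    type_i_fraction: float = 0.15
    #: log-normal brightness parameters (log scale)
    brightness_meanlog: float = 8.0
    brightness_sdlog: float = 0.5
    #: bead-level coefficient of variation at inflation 1.0
    cv_base: float = 0.10
    #: baseline-beta mixture: weights for (low, high, mid) Beta components
    mixture_weights: tuple = (0.45, 0.45, 0.10)
    mixture_params: tuple = ((0.5, 8.0), (8.0, 0.5), (2.0, 2.0))
    outlier_plan: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for table in (self.chamber_gain, self.chamber_cv_inflation):
            for chamber, per_channel in table.items():
                for ch, v in per_channel.items():
                    if v <= 0:
                        raise ValidationError(
                            f"gain/inflation must be > 0 (chamber {chamber}, {ch})"
                        )
        if not 0 <= self.type_i_fraction < 1:
            raise ValidationError("type_i_fraction must lie in [0, 1)")
        plan = []
        for entry in self.outlier_plan:
            if isinstance(entry, OutlierSpec):
                plan.append(entry)
            else:
                plan.append(OutlierSpec(**entry))
        self.outlier_plan = plan

    def gain(self, chamber: int, channel: str) -> float:
        return float(self.chamber_gain.get(chamber, {}).get(channel, 1.0))

    def cv_inflation(self, chamber: int, channel: str) -> float:
        return float(self.chamber_cv_inflation.get(chamber, {}).get(channel, 1.0))

    # -- YAML round trip ------------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["mixture_weights"] = list(self.mixture_weights)
        d["mixture_params"] = [list(p) for p in self.mixture_params]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "mixture_weights" in d:
            d["mixture_weights"] = tuple(d["mixture_weights"])
        if "mixture_params" in d:
            d["mixture_params"] = tuple(tuple(p) for p in d["mixture_params"])
        return cls(**d)


def bundled_scenario_path() -> str:
    """Path of the packaged biased-scenario YAML (``biased_plate.yaml``)."""
    from importlib import resources

    return str(resources.files("methvar").joinpath("data/biased_plate.yaml"))


def biased_scenario(**overrides) -> SimulationConfig:
    """The bundled biased scenario: chamber 1 dim (gain 0.8 in both channels)
    and chamber 8 with 1.5x bead-level CV in the red channel."""
    cfg = SimulationConfig(
        chamber_gain={1: {"green": 0.8, "red": 0.8}},
        chamber_cv_inflation={8: {"red": 1.5}},
    )
    return dataclasses.replace(cfg, **overrides)


@dataclass
class GroundTruth:
    """Recovery targets: noise-free betas per subject plus the injected biases."""

    true_beta: pd.DataFrame  # probes x subjects
    chamber_gain: dict
    outliers: list

    def __post_init__(self) -> None:
        vals = self.true_beta.to_numpy(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValidationError("true_beta must lie in [0, 1]")


# ---------------------------------------------------------------------------
# plate layout
# ---------------------------------------------------------------------------

SUBJECT_NAMES = [chr(ord("A") + i) for i in range(26)]


def _sample_id(slide: str, chamber: int) -> str:
    return f"{slide}_{SENTRIX_POSITIONS[chamber]}"


def replicate_plate_layout(config: SimulationConfig) -> SampleSheet:
    """Deterministic replicate-plate layout.

    Pooled replicates of each subject cover chambers 1-8 exactly once and are
    spread over ``n_pooled_slides`` (>= 4) slides in a rotating (Latin-square
    style) pattern.  Independently prepared replicates are placed pairwise on
    dedicated slides so that two subjects share each slide, half the chambers
    each -- which is what makes a same-slide two-group comparison possible.
    """
    s = config.n_subjects
    if s < 1 or s > len(SUBJECT_NAMES):
        raise LayoutError(f"n_subjects must be in 1..{len(SUBJECT_NAMES)}")
    if config.n_pooled_per_subject != 8:
        raise LayoutError(
            "the replicate-plate design requires 8 pooled replicates per "
            "subject (one per chamber number)"
        )
    k = config.n_pooled_slides
    if k < 4:
        raise LayoutError("pooled replicates must span at least 4 slides")
    if s > k:
        raise LayoutError(
            f"{s} subjects cannot share {k} pooled slides without collisions"
        )
    q = config.n_independent_per_subject
    if q % 2 or q > 8:
        raise LayoutError("n_independent_per_subject must be even and <= 8")

    subjects = SUBJECT_NAMES[:s]
    rows = []
    for i, subject in enumerate(subjects):
        for chamber in range(1, 9):
            slide = f"slideP{(i + chamber) % k + 1}"
            rows.append((_sample_id(slide, chamber), subject, slide, chamber, True))

    if q:
        pairs = [(i, i + 1) for i in range(0, s - 1, 2)]
        leftover = [s - 1] if s % 2 else []
        slide_no = 0
        for a, b in pairs:
            # two slides per pair; each subject gets q/2 chambers on each
            for flip in (False, True):
                slide_no += 1
                slide = f"slideQ{slide_no}"
                first, second = (b, a) if flip else (a, b)
                for chamber in range(1, q // 2 + 1):
                    rows.append(
                        (_sample_id(slide, chamber), subjects[first], slide, chamber, False)
                    )
                for chamber in range(5, 5 + q // 2):
                    rows.append(
                        (_sample_id(slide, chamber), subjects[second], slide, chamber, False)
                    )
        for a in leftover:
            slide_no += 1
            slide = f"slideQ{slide_no}"
            for chamber in range(1, q + 1):
                rows.append(
                    (_sample_id(slide, chamber), subjects[a], slide, chamber, False)
                )

    frame = pd.DataFrame(
        rows, columns=["sample_id", "subject", "slide", "chamber", "pooled"]
    )
    return SampleSheet(frame)


# ---------------------------------------------------------------------------
# manifest and ground truth
# ---------------------------------------------------------------------------


def make_manifest(n_probes: int, type_i_fraction: float = 0.15) -> ProbeManifest:
    """Deterministic manifest: probes cg00000000.. with an interleaved Type I
    subset split evenly between green and red design channels."""
    period = 40
    n_type_i = max(2, int(round(period * type_i_fraction)))
    n_type_i += n_type_i % 2  # even: half green, half red
    cut = period - n_type_i
    rows = []
    for i in range(n_probes):
        r = i % period
        if r < cut or type_i_fraction == 0:
            rows.append((f"cg{i:08d}", "II", "both"))
        elif r < cut + n_type_i // 2:
            rows.append((f"cg{i:08d}", "I", "green"))
        else:
            rows.append((f"cg{i:08d}", "I", "red"))
    return ProbeManifest(
        pd.DataFrame(rows, columns=["probe_id", "probe_type", "design_channel"])
    )


def simulate_truth(config: SimulationConfig) -> GroundTruth:
    """Noise-free per-subject betas from a bimodal Beta mixture.

    Baseline betas are drawn from a three-component mixture (modes near 0 and
    1 plus a minority mid-range component); each subject deviates from the
    baseline by ``N(0, subject_effect_sd)``, clipped to [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_probes
    w = np.asarray(config.mixture_weights, float)
    w = w / w.sum()
    comp = rng.choice(len(w), size=n, p=w)
    baseline = np.empty(n)
    for j, (a, b) in enumerate(config.mixture_params):
        idx = comp == j
        baseline[idx] = rng.beta(a, b, size=int(idx.sum()))
    subjects = SUBJECT_NAMES[: config.n_subjects]
    dev = rng.normal(0.0, config.subject_effect_sd, size=(n, len(subjects)))
    true_beta = np.clip(baseline[:, None] + dev, 0.0, 1.0)
    probes = [f"cg{i:08d}" for i in range(n)]
    return GroundTruth(
        true_beta=pd.DataFrame(true_beta, index=probes, columns=subjects),
        chamber_gain={c: dict(v) for c, v in config.chamber_gain.items()},
        outliers=list(config.outlier_plan),
    )


# ---------------------------------------------------------------------------
# intensity synthesis
# ---------------------------------------------------------------------------


def simulate_intensities(
    truth: GroundTruth, sheet: SampleSheet, config: SimulationConfig
) -> LowLevelArraySet:
    """Bead-summary fluorescence data for every (probe, sample, channel).

    See the module docstring for the generative model.  Fixed seed implies
    byte-identical output.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    manifest = make_manifest(config.n_probes, config.type_i_fraction)
    probes = manifest.probe_ids
    if list(truth.true_beta.index) != probes:
        raise ValidationError("truth probes do not match config.n_probes manifest")
    samples = sheet.sample_ids
    n_p, n_s = len(probes), len(samples)

    subject_idx = (
        sheet.frame["subject"]
        .map({s: i for i, s in enumerate(truth.true_beta.columns)})
        .to_numpy()
    )
    if np.isnan(subject_idx.astype(float)).any():
        raise ValidationError("sheet contains subjects absent from truth")
    chambers = sheet.frame["chamber"].to_numpy()
    pooled = sheet.frame["pooled"].to_numpy(bool)

    # per-sample betas (probes x samples)
    beta = truth.true_beta.to_numpy(float)[:, subject_idx]
    if config.prep_noise_sd > 0 and (~pooled).any():
        noise = rng.normal(0.0, config.prep_noise_sd, size=(n_p, int((~pooled).sum())))
        beta = beta.copy()
        beta[:, ~pooled] = np.clip(beta[:, ~pooled] + noise, 0.0, 1.0)

    brightness = rng.lognormal(
        config.brightness_meanlog, config.brightness_sdlog, size=n_p
    )

    # bead counts: shifted Poisson, shared across channels
    lam = max(config.bead_count_mean - 1.0, 0.0)
    n_beads = 1 + rng.poisson(lam, size=(n_p, n_s))

    type_mask = (manifest.frame["probe_type"] == "II").to_numpy()
    design = manifest.frame["design_channel"].to_numpy()

    gains = {
        ch: np.array([config.gain(c, ch) for c in chambers]) for ch in CHANNELS
    }
    infl = {
        ch: np.array([config.cv_inflation(c, ch) for c in chambers])
        for ch in CHANNELS
    }

    mean_fi, sd_fi, nb_out = {}, {}, {}
    for ch in CHANNELS:
        signal = np.zeros((n_p, n_s))
        frac = beta if ch == "green" else 1.0 - beta
        signal[type_mask] = (
            brightness[type_mask, None] * frac[type_mask] * gains[ch][None, :]
        )
        inband_i = (~type_mask) & (design == ch)
        # Type I in-band reads carry the full probe brightness (their beta is
        # not channel-ratiometric in this simplified design)
        signal[inband_i] = 0.6 * brightness[inband_i, None] * gains[ch][None, :]
        # out-of-band rows of Type I probes keep signal = 0: background only

        sd_true = config.cv_base * (signal + config.background_mean) * infl[ch][None, :]
        background = rng.normal(config.background_mean, config.background_sd, (n_p, n_s))
        eps = rng.standard_normal((n_p, n_s)) * sd_true / np.sqrt(n_beads)
        observed = np.maximum(signal + background + eps, 0.0)

        many = n_beads > 1
        sd_obs = np.zeros((n_p, n_s))
        chi = rng.chisquare(np.maximum(n_beads - 1, 1))
        sd_obs[many] = (sd_true * np.sqrt(chi / np.maximum(n_beads - 1, 1)))[many]

        mean_fi[ch] = pd.DataFrame(observed, index=probes, columns=samples)
        sd_fi[ch] = pd.DataFrame(sd_obs, index=probes, columns=samples)
        nb_out[ch] = pd.DataFrame(n_beads, index=probes, columns=samples)

    for spec in config.outlier_plan:
        chans = CHANNELS if spec.channel == "both" else (spec.channel,)
        for ch in chans:
            mean_fi[ch].loc[spec.probe_id, spec.sample_id] = max(
                0.0, mean_fi[ch].loc[spec.probe_id, spec.sample_id] + spec.fi_shift
            )
            sd_fi[ch].loc[spec.probe_id, spec.sample_id] += abs(spec.fi_shift) * config.cv_base
        for ch in CHANNELS:
            nb_out[ch].loc[spec.probe_id, spec.sample_id] = spec.n_beads
            if spec.n_beads <= 1:
                sd_fi[ch].loc[spec.probe_id, spec.sample_id] = 0.0

    return LowLevelArraySet(
        manifest=manifest, mean_fi=mean_fi, sd_fi=sd_fi, n_beads=nb_out
    )


def simulate_dataset(config: SimulationConfig):
    """Convenience: layout + truth + intensities in one call."""
    sheet = replicate_plate_layout(config)
    truth = simulate_truth(config)
    lowlevel = simulate_intensities(truth, sheet, config)
    return sheet, truth, lowlevel
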