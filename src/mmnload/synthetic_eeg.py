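"""Synthetic epoched EEG with known ground truth.

Emulates the recording situation of the load x tone study: five scalp
channels (Fz, Cz, Pz and the mastoid neighbours P9, P10) referenced to
the nose tip, epoched from 100 ms before to 500 ms after stimulus onset.
Every epoch is a sum of condition-dependent ERP components (half-cosine
bumps over their measurement windows), slow drift, stationary noise
(white, AR(1) or pink), and occasional large-amplitude artifact epochs.

Component amplitudes are specified as the *mean amplitude over the
component's window*, i.e. on the same scale as the downstream measures,
so a noise-free simulation reproduces injected truths exactly. The
envelope is normalised on the discrete sample grid to make this exact at
any sampling rate.

Ground-truth bookkeeping: deviants carry the standard-tone response plus
the oddball-MMN component; the critical tone in the control condition
carries the standard response plus (oddball MMN - corrected MMN), so the
deviant-minus-critical difference equals the injected corrected MMN.
Visual targets add a visual P3 in all tone conditions equally; because
targets occur on exactly 20% of each tone class, the visual P3 cancels in
every tone difference wave (and tone components cancel in the visual
target-minus-non-target contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .task_design import BlockDesign, ToneSequence, VisualSequence, compose_session

CHANNELS = ("Fz", "Cz", "Pz", "P9", "P10")

# frontocentral components weighted to Fz/Cz, parietal to Cz/Pz; the
# mastoid neighbours carry a fraction so rereferencing is non-degenerate
FRONTOCENTRAL_WEIGHTS = {"Fz": 1.0, "Cz": 1.0, "Pz": 0.4, "P9": 0.3, "P10": 0.3}
CENTROPARIETAL_WEIGHTS = {"Fz": 0.4, "Cz": 1.0, "Pz": 1.0, "P9": 0.3, "P10": 0.3}

COMPONENT_WINDOWS_MS = {
    "n1": (75.0, 105.0),
    "mmn": (125.0, 175.0),
    "p3a": (300.0, 500.0),
    "visual_p3": (300.0, 500.0),
}

COMPONENTS = ("n1", "oddball_mmn", "corrected_mmn", "p3a", "visual_p3")
LOADS = ("low", "high")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: window, scalp distribution, temporal envelope."""

    name: str
    window_ms: tuple[float, float]
    channel_weights: Mapping[str, float]
    shape: str = "half_cosine"

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-mean envelope on the discrete grid, zero outside the window."""
        lo, hi = self.window_ms
        if lo < times_ms[0] or hi > times_ms[-1]:
            raise SimulationError(
                f"component window {self.window_ms} outside epoch "
                f"[{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms"
            )
        if self.shape != "half_cosine":
            raise SimulationError(f"unknown envelope shape {self.shape!r}")
        env = np.zeros_like(times_ms, dtype=float)
        m = (times_ms >= lo) & (times_ms <= hi)
        u = (times_ms[m] - lo) / (hi - lo)
        env[m] = np.sin(np.pi * u)
        mean_in_window = env[m].mean()
        if mean_in_window <= 0:
            raise SimulationError("component window contains no interior samples")
        return env / mean_in_window


@dataclass(frozen=True)
class NoiseSpec:
    """Epoch noise model. sd is the stationary per-sample SD in microvolts."""

    sd: float = 3.0
    model: str = "ar1"  # white | ar1 | pink
    ar_coefficient: float = 0.95
    artifact_rate: float = 0.02
    artifact_amplitude: float = 300.0
    drift_sd: float = 0.5  # SD of per-epoch offset and linear drift, microvolts

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise SimulationError("noise sd must be >= 0")
        if not 0 <= self.artifact_rate < 0.3:
            raise SimulationError("artifact_rate must be in [0, 0.3)")


@dataclass
class SubjectGroundTruth:
    """True simulated amplitudes (microvolts, per load) and the WMC score."""

    subject_id: str
    amplitudes: dict[tuple[str, str], float]  # (component, load) -> microvolts
    wmc_pcu: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.wmc_pcu <= 1:
            raise SimulationError("wmc_pcu must be in [0, 1]")

    def amplitude(self, component: str, load: str) -> float:
        return self.amplitudes.get((component, load), 0.0)

    def load_effect(self, component: str) -> float:
        return self.amplitude(component, "high") - self.amplitude(component, "low")


# group-level defaults: the study's observed cell means, with
# between-subject SDs recovered from the reported 95% CIs (n=49)
DEFAULT_GROUP_MEANS: dict[tuple[str, str], float] = {
    ("n1", "low"): -0.49, ("n1", "high"): -0.15,
    ("oddball_mmn", "low"): -2.13, ("oddball_mmn", "high"): -2.26,
    ("corrected_mmn", "low"): -1.38, ("corrected_mmn", "high"): -1.26,
    ("p3a", "low"): 0.41, ("p3a", "high"): -0.18,
    ("visual_p3", "low"): 9.29, ("visual_p3", "high"): 2.73,
}
DEFAULT_GROUP_SDS: dict[str, float] = {  # SD of the low-load cell
    "n1": 1.8, "oddball_mmn": 2.1, "corrected_mmn": 2.7,
    "p3a": 2.6, "visual_p3": 6.0,
}
DEFAULT_EFFECT_SDS: dict[str, float] = {  # SD of the high-minus-low effect
    "n1": 1.0, "oddball_mmn": 2.1, "corrected_mmn": 3.0,
    "p3a": 3.5, "visual_p3": 4.4,
}


@dataclass
class CohortSpec:
    """Group-level distribution from which subjects are drawn."""

    n_subjects: int = 49
    group_means: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MEANS))
    group_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SDS))
    effect_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SDS))
    wmc_effect_correlation: float = 0.35  # WMC vs N1 load effect
    wmc_mean: float = 0.7
    wmc_sd: float = 0.12
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    design: BlockDesign = field(default_factory=BlockDesign)
    sampling_rate: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SimulationError("n_subjects must be >= 2")
        if not -1 <= self.wmc_effect_correlation <= 1:
            raise SimulationError("wmc_effect_correlation must be in [-1, 1]")
        if any(v < 0 for v in self.group_sds.values()):
            raise SimulationError("group SDs must be >= 0")


@dataclass
class EpochMatrix:
    """Per-subject epoched EEG: (epochs, channels, samples) in microvolts."""

    channels: tuple[str, ...]
    sampling_rate: float
    times_ms: np.ndarray
    data: np.ndarray  # (n_epochs, n_channels, n_times)
    info: pd.DataFrame  # per-epoch: block, load, tone_condition, role, ...
    reference: str = "nose"

    def __post_init__(self) -> None:
        if self.data.shape[1] != len(self.channels):
            raise SimulationError("channel axis mismatch")
        if self.data.shape[2] != len(self.times_ms):
            raise SimulationError("time axis mismatch")
        if len(self.info) != self.data.shape[0]:
            raise SimulationError("epoch metadata mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.channels.index(c) for c in names])
        except ValueError as err:
            raise SimulationError(f"unknown channel in {names}: {err}") from None

    def select(self, mask: np.ndarray) -> "EpochMatrix":
        return EpochMatrix(
            self.channels, self.sampling_rate, self.times_ms,
            self.data[mask], self.info.loc[mask].reset_index(drop=True),
            self.reference,
        )

    def copy(self) -> "EpochMatrix":
        return EpochMatrix(
            self.channels, self.sampling_rate, self.times_ms.copy(),
            self.data.copy(), self.info.copy(), self.reference,
        )

    def to_mne(self):
        """Export as an mne.EpochsArray (volts), for interoperability."""
        import mne

        mne_info = mne.create_info(list(self.channels), self.sampling_rate, "eeg")
        return mne.EpochsArray(
            self.data * 1e-6, mne_info, tmin=self.times_ms[0] / 1000.0, verbose=False
        )


def epoch_times_ms(fs: float, tmin_ms: float = -100.0, tmax_ms: float = 500.0) -> np.ndarray:
    """Sample grid covering [tmin, tmax] ms, always containing 0 ms."""
    k0 = int(np.ceil(tmin_ms * fs / 1000.0 - 1e-9))
    k1 = int(np.floor(tmax_ms * fs / 1000.0 + 1e-9))
    return np.arange(k0, k1 + 1) * 1000.0 / fs


def default_components() -> dict[str, ComponentSpec]:
    return {
        "n1": ComponentSpec("n1", COMPONENT_WINDOWS_MS["n1"], FRONTOCENTRAL_WEIGHTS),
        "mmn": ComponentSpec("mmn", COMPONENT_WINDOWS_MS["mmn"], FRONTOCENTRAL_WEIGHTS),
        "p3a": ComponentSpec("p3a", COMPONENT_WINDOWS_MS["p3a"], CENTROPARIETAL_WEIGHTS),
        "visual_p3": ComponentSpec(
            "visual_p3", COMPONENT_WINDOWS_MS["visual_p3"], CENTROPARIETAL_WEIGHTS),
    }


def _noise_block(noise: NoiseSpec, shape: tuple[int, ...], fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Stationary noise with per-sample SD noise.sd along the last axis."""
    if noise.sd == 0:
        return np.zeros(shape)
    n_t = shape[-1]
    if noise.model == "white":
        return rng.normal(0.0, noise.sd, size=shape)
    if noise.model == "ar1":
        phi = noise.ar_coefficient
        burn = min(max(int(8 / max(1e-6, 1 - phi)), 20), 2000)
        innov_sd = noise.sd * np.sqrt(1 - phi**2)
        w = rng.normal(0.0, innov_sd, size=shape[:-1] + (n_t + burn,))
        x = signal.lfilter([1.0], [1.0, -phi], w, axis=-1)
        return x[..., burn:]
    if noise.model == "pink":
        w = rng.normal(0.0, 1.0, size=shape)
        spec = np.fft.rfft(w, axis=-1)
        freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)
        scale = np.ones_like(freqs)
        scale[1:] = 1.0 / np.sqrt(freqs[1:])
        scale[0] = 0.0
        x = np.fft.irfft(spec * scale, n=n_t, axis=-1)
        sd = x.std()
        return x * (noise.sd / sd) if sd > 0 else x
    raise SimulationError(f"unknown noise model {noise.model!r}")


def simulate_subject(
    session: Sequence[tuple[BlockDesign, ToneSequence, VisualSequence]],
    truth: SubjectGroundTruth,
    noise: NoiseSpec | None = None,
    fs: float = 256.0,
    seed: int | np.random.Generator = 0,
    components: Mapping[str, ComponentSpec] | None = None,
) -> EpochMatrix:
    """Simulate one subject's epoched EEG for a composed session."""
    if fs < 128:
        raise SimulationError("sampling rate must be >= 128 Hz")
    noise = noise or NoiseSpec()
    comps = components or default_components()
    rng = np.random.default_rng(seed)
    times = epoch_times_ms(fs)
    n_t = len(times)
    n_ch = len(CHANNELS)

    rows = []
    for b, (design, tones, visual) in enumerate(session):
        for i in range(len(tones)):
            role = str(tones.roles[i])
            rows.append((
                b, design.load, design.tone_condition, role,
                float(tones.frequencies[i]), bool(visual.is_target[i]),
                bool(tones.is_warmup[i]),
            ))
    info = pd.DataFrame(
        rows, columns=["block", "load", "tone_condition", "role",
                       "frequency", "is_target", "is_warmup"])
    n_ep = len(info)

    # per-epoch component amplitudes (microvolts, mean-over-window scale)
    load = info["load"].to_numpy()
    role = info["role"].to_numpy()
    is_tgt = info["is_target"].to_numpy()
    amp = {name: np.zeros(n_ep) for name in ("n1", "mmn", "p3a", "visual_p3")}
    for lv in LOADS:
        m = load == lv
        amp["n1"][m] = truth.amplitude("n1", lv)
        a_odd = truth.amplitude("oddball_mmn", lv)
        a_corr = truth.amplitude("corrected_mmn", lv)
        amp["mmn"][m & (role == "deviant")] = a_odd
        amp["mmn"][m & (role == "critical")] = a_odd - a_corr
        amp["p3a"][m & (role == "deviant")] = truth.amplitude("p3a", lv)
        amp["visual_p3"][m & is_tgt] = truth.amplitude("visual_p3", lv)

    data = np.zeros((n_ep, n_ch, n_t))
    for name, a in amp.items():
        spec = comps[name]
        env = spec.envelope(times)
        w = np.array([spec.channel_weights.get(c, 0.0) for c in CHANNELS])
        data += a[:, None, None] * w[None, :, None] * env[None, None, :]

    data += _noise_block(noise, (n_ep, n_ch, n_t), fs, rng)

    if noise.drift_sd > 0:
        offs = rng.normal(0.0, noise.drift_sd, size=(n_ep, n_ch, 1))
        slope = rng.normal(0.0, noise.drift_sd, size=(n_ep, n_ch, 1))
        ramp = (times - times[0]) / (times[-1] - times[0])
        data += offs + slope * ramp[None, None, :]

    if noise.artifact_rate > 0 and noise.artifact_amplitude > 0:
        hit = rng.random(n_ep) < noise.artifact_rate
        if hit.any():
            bump = np.sin(np.pi * np.linspace(0, 1, n_t))
            sign = rng.choice([-1.0, 1.0], size=int(hit.sum()))
            scale = rng.uniform(0.7, 1.3, size=int(hit.sum()))
            data[hit] += (noise.artifact_amplitude * sign * scale)[:, None, None] \
                * bump[None, None, :]

    return EpochMatrix(CHANNELS, fs, times, data, info, reference="nose")


def draw_cohort_truths(spec: CohortSpec, rng: np.random.Generator) -> list[SubjectGroundTruth]:
    """Draw per-subject true amplitudes and WMC from the group distributions.

    Low-load cell and high-minus-low effect are drawn independently per
    component; WMC shares a latent normal with the N1 load effect at the
    configured correlation and is mapped to a PCU in [0, 1] by clipping.
    """
    truths = []
    rho = spec.wmc_effect_correlation
    for s in range(spec.n_subjects):
        amplitudes: dict[tuple[str, str], float] = {}
        z_n1_effect = np.nan
        for comp in COMPONENTS:
            mu_lo = spec.group_means.get((comp, "low"), 0.0)
            mu_hi = spec.group_means.get((comp, "high"), 0.0)
            base = rng.normal(mu_lo, spec.group_sds.get(comp, 0.0))
            z = rng.normal()
            effect = (mu_hi - mu_lo) + spec.effect_sds.get(comp, 0.0) * z
            if comp == "n1":
                z_n1_effect = z
            amplitudes[(comp, "low")] = base
            amplitudes[(comp, "high")] = base + effect
        latent = rho * z_n1_effect + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal()
        pcu = float(np.clip(spec.wmc_mean + spec.wmc_sd * latent, 0.0, 1.0))
        truths.append(SubjectGroundTruth(f"S{s + 1:02d}", amplitudes, pcu))
    return truths


def simulate_cohort(spec: CohortSpec) -> list[tuple[EpochMatrix, SubjectGroundTruth]]:
    """Simulate a full cohort: independent sessions, truths, and noise."""
    root = np.random.SeedSequence(spec.seed)
    truth_rng = np.random.default_rng(root.spawn(1)[0])
    truths = draw_cohort_truths(spec, truth_rng)
    out = []
    for s, truth in enumerate(truths):
        sub_seq = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, s))
        session_rng, noise_rng = (np.random.default_rng(ss) for ss in sub_seq.spawn(2))
        session = compose_session(session_rng, spec.design)
        epochs = simulate_subject(
            session, truth, spec.noise, spec.sampling_rate, noise_rng)
        out.append((epochs, truth))
    return out


def measure_noise_variance(
    noise: NoiseSpec,
    fs: float,
    window_ms: tuple[float, float],
    n_epochs: int,
    n_channels: int = 2,
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
) -> float:
    """Conservative analytic variance of a mean-amplitude measure.

    Variance of the window mean plus the baseline mean (their positive
    covariance is dropped, which can only overstate the total), divided
    by the number of independently-noisy channels and averaged epochs.
    """
    def mean_var(length_samples: int) -> float:
        w = length_samples
        if noise.model == "white":
            return noise.sd**2 / w
        if noise.model == "ar1":
            phi = noise.ar_coefficient
            d = np.arange(1, w)
            s = w + 2 * np.sum((w - d) * phi**d)
            return noise.sd**2 * s / w**2
        raise SimulationError("analytic variance implemented for white/ar1 only")

    times = epoch_times_ms(fs)
    n_win = int(np.sum((times >= window_ms[0]) & (times <= window_ms[1])))
    n_base = int(np.sum((times >= baseline_ms[0]) & (times < baseline_ms[1])))
    per_epoch = mean_var(n_win) + mean_var(n_base)
    return per_epoch / (n_channels * n_epochs)
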