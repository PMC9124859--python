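"""Synthetic 4-class motor-imagery EEG with ground-truth cortical activity.

Each trial is built on the 18 motor-cortex scouts: every scout carries a
band-limited mu (10-12 Hz) and beta (18-25 Hz) oscillation with random
per-trial phases and a slow amplitude envelope, on top of pink (1/f)
background.  Event-related desynchronisation (ERD) is simulated by shrinking
the oscillation amplitude by ``1 - erd_depth`` in the scouts "active" for a
class: left-fist imagery suppresses the right-hemisphere set, right-fist the
left set, both-fists both sets, and both-feet both sets but in the beta band
only (a distinct spectral signature, since the ROI set itself is fixed).
The scout series are assigned to their 20 cortical vertices, pushed through
the spherical-head leadfield, and white sensor noise is added at a configured
signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .headmodel import (Leadfield, SensorArray, SourceSpace, default_montage,
                        make_source_space, three_sphere_leadfield)
from .preprocess import MI_CLASSES, EpochSet, RawRecording
from .scouts import MOTOR_PAIR_NAMES, Scout, ScoutPairing, define_motor_scouts

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedDataset",
    "ROI_NAMES",
    "DEFAULT_CLASS_TEMPLATES",
    "generate_source_activity",
    "project_to_scalp",
    "generate_dataset",
    "simulation_forward_model",
    "to_raw_recording",
]

#: ROI order: the nine left-hemisphere scouts, then the nine right ones,
#: matching the scout ordering produced by ``define_motor_scouts``.
ROI_NAMES: tuple[str, ...] = tuple(l for l, _ in MOTOR_PAIR_NAMES) + tuple(
    r for _, r in MOTOR_PAIR_NAMES
)
LEFT_ROIS = tuple(range(9))
RIGHT_ROIS = tuple(range(9, 18))

#: Which ROI set shows ERD, and in which bands, per MI class.
DEFAULT_CLASS_TEMPLATES: dict[str, dict] = {
    "T1": {"rois": RIGHT_ROIS, "bands": ("mu", "beta")},   # left fist
    "T2": {"rois": LEFT_ROIS, "bands": ("mu", "beta")},    # right fist
    "T3": {"rois": LEFT_ROIS + RIGHT_ROIS, "bands": ("mu", "beta")},  # both fists
    "T4": {"rois": LEFT_ROIS + RIGHT_ROIS, "bands": ("beta",)},       # both feet
}

# Baseline component scales (arbitrary source units).  The narrow-band
# oscillations dominate the pink background inside their bands so that the
# mu-power contrast tracks (1 - erd_depth)^2 closely.
SIGMA_MU = 1.0
SIGMA_BETA = 0.7
SIGMA_PINK = 0.4
N_SINUSOIDS = 3
ENVELOPE_DEPTH = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulated recordings.

    Defaults mirror the public motor-imagery accession structure: 64-channel
    10-10 EEG at 160 Hz, 4 s trials, 21 trials per class (84 per subject).
    """

    n_subjects: int = 1
    trials_per_class: int = 21
    fs: float = 160.0
    epoch_s: float = 4.0
    n_channels: int = 64
    mu_band: tuple[float, float] = (10.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 25.0)
    erd_depth: float = 0.8
    sensor_snr_db: float = 10.0
    noise_floor: float = 1e-12  # absolute sensor-noise variance when signal is zero
    rest_s: float = 2.0         # inter-trial rest used by the EDF writer
    n_sources: int = 2000
    seed: int = 0
    class_templates: dict[str, dict] | None = None

    def __post_init__(self) -> None:
        n = self.fs * self.epoch_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("fs * epoch_s must be an integer sample count")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))

    def templates(self) -> dict[str, dict]:
        return (self.class_templates if self.class_templates is not None
                else DEFAULT_CLASS_TEMPLATES)


@dataclass
class GroundTruth:
    """Per-trial source truth: scout series, class, and the active ROI set."""

    series: np.ndarray  # (18, n_samples)
    label: str
    active_rois: tuple[int, ...]
    erd_bands: tuple[str, ...]


@dataclass
class SimulatedDataset:
    """A generated dataset plus everything needed to audit it."""

    epochs: EpochSet
    ground_truth: list[GroundTruth]
    subject_ids: np.ndarray
    trial_order: np.ndarray  # per-subject shuffle permutations, concatenated
    noise_std: float
    config: SimConfig


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise, flat below 1 Hz, via spectral shaping."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(np.maximum(freqs[nz], 1.0))
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _band_oscillation(
    n: int, fs: float, band: tuple[float, float], sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sum of random-phase sinusoids in ``band`` with a slow envelope."""
    t = np.arange(n) / fs
    freqs = rng.uniform(band[0], band[1], N_SINUSOIDS)
    phases = rng.uniform(0.0, 2.0 * np.pi, N_SINUSOIDS)
    amp = sigma * np.sqrt(2.0 / N_SINUSOIDS)
    x = amp * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :]
                     + phases[:, None]).sum(axis=0)
    f_env = rng.uniform(0.1, 0.5)
    phi_env = rng.uniform(0.0, 2.0 * np.pi)
    envelope = 1.0 + ENVELOPE_DEPTH * np.sin(2.0 * np.pi * f_env * t + phi_env)
    return x * envelope


def generate_source_activity(
    class_label: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> GroundTruth:
    """Generate the 18 scout source series for one trial of ``class_label``."""
    templates = config.templates()
    if class_label not in templates:
        raise ValueError(
            f"unknown MI class {class_label!r}; expected one of "
            f"{sorted(templates)}"
        )
    template = templates[class_label]
    active = tuple(template["rois"])
    bands = tuple(template["bands"])
    n = config.n_samples
    series = np.empty((len(ROI_NAMES), n))
    for roi in range(len(ROI_NAMES)):
        mu = _band_oscillation(n, config.fs, config.mu_band, SIGMA_MU, rng)
        beta = _band_oscillation(n, config.fs, config.beta_band, SIGMA_BETA, rng)
        pink = SIGMA_PINK * _pink_noise(n, config.fs, rng)
        if roi in active:
            if "mu" in bands:
                mu = mu * (1.0 - config.erd_depth)
            if "beta" in bands:
                beta = beta * (1.0 - config.erd_depth)
        series[roi] = mu + beta + pink
    return GroundTruth(series=series, label=class_label, active_rois=active,
                       erd_bands=bands)


def _vertex_indices(vertex_map) -> list[np.ndarray]:
    out = []
    for entry in vertex_map:
        if isinstance(entry, Scout):
            out.append(entry.vertex_indices)
        else:
            out.append(np.asarray(entry, dtype=int))
    return out


def _project(
    truth: GroundTruth,
    leadfield: Leadfield,
    vertex_map,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Project scout truth through the leadfield; returns (scalp, noise_std)."""
    indices = _vertex_indices(vertex_map)
    if len(indices) != truth.series.shape[0]:
        raise ValueError(
            f"vertex map has {len(indices)} entries for "
            f"{truth.series.shape[0]} ROI series"
        )
    max_idx = max(int(ix.max()) for ix in indices)
    if max_idx >= leadfield.n_sources:
        raise ValueError(
            f"vertex index {max_idx} exceeds leadfield source count "
            f"{leadfield.n_sources}"
        )
    gain_per_roi = np.stack(
        [leadfield.gain[:, ix].sum(axis=1) for ix in indices], axis=1
    )  # (n_sensors, 18): each vertex of a scout carries the scout series
    clean = gain_per_roi @ truth.series  # (n_sensors, n_samples)
    signal_power = float(np.mean(clean ** 2))
    if signal_power > 0.0:
        noise_var = signal_power / (10.0 ** (config.sensor_snr_db / 10.0))
    else:
        noise_var = config.noise_floor
    noise_std = float(np.sqrt(noise_var))
    noisy = clean + noise_std * rng.standard_normal(clean.shape)
    return noisy, noise_std


def project_to_scalp(
    truth: GroundTruth,
    leadfield: Leadfield,
    vertex_map,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-trial scalp array (channels x samples) with sensor noise.

    SNR is the ratio of mean clean-signal power to noise power across
    channels over the whole epoch; a zero signal yields pure noise at the
    configured absolute floor variance.
    """
    scalp, _ = _project(truth, leadfield, vertex_map, config, rng)
    return scalp


def simulation_forward_model(
    config: SimConfig,
) -> tuple[SensorArray, SourceSpace, Leadfield, list[Scout], ScoutPairing]:
    """Deterministic geometry shared by generation and inversion."""
    montage = default_montage()
    source_space = make_source_space(n_vertices=config.n_sources)
    leadfield = three_sphere_leadfield(montage, source_space, n_terms=200)
    scouts, pairing = define_motor_scouts(source_space, montage)
    return montage, source_space, leadfield, scouts, pairing


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full labelled dataset for all simulated subjects.

    Each subject contributes ``trials_per_class`` trials per class, shuffled
    with the dataset RNG; the shuffle permutation is recorded so that splits
    are reproducible.  Identical config + seed gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    montage, _, leadfield, scouts, _ = simulation_forward_model(config)
    classes = [c for c in MI_CLASSES if c in config.templates()]
    epochs, labels, truths, subject_ids, orders, noise_stds = [], [], [], [], [], []
    for subject in range(config.n_subjects):
        trial_labels = np.repeat(classes, config.trials_per_class)
        order = rng.permutation(len(trial_labels))
        trial_labels = trial_labels[order]
        orders.append(order)
        for label in trial_labels:
            truth = generate_source_activity(label, config, rng)
            scalp, noise_std = _project(truth, leadfield, scouts, config, rng)
            epochs.append(scalp)
            labels.append(label)
            truths.append(truth)
            noise_stds.append(noise_std)
        subject_ids.extend([subject] * len(trial_labels))
    epoch_set = EpochSet(
        epochs=np.stack(epochs),
        labels=np.array(labels, dtype="<U8"),
        fs=config.fs,
        montage=montage.names,
    )
    return SimulatedDataset(
        epochs=epoch_set,
        ground_truth=truths,
        subject_ids=np.array(subject_ids),
        trial_order=np.concatenate(orders),
        noise_std=float(np.mean(noise_stds)),
        config=config,
    )


def to_raw_recording(
    dataset: SimulatedDataset,
    subject: int = 0,
) -> RawRecording:
    """Lay one subject's trials out as a continuous annotated recording.

    Trials are separated by ``rest_s`` seconds of pure sensor noise at the
    dataset's noise level; rest stretches are annotated ``REST`` and each
    trial with its class label, which is what the epoching and baseline
    policies downstream consume.
    """
    cfg = dataset.config
    mask = dataset.subject_ids == subject
    if not mask.any():
        raise ValueError(f"no trials for subject {subject}")
    trials = dataset.epochs.epochs[mask]
    labels = dataset.epochs.labels[mask]
    n_rest = int(round(cfg.rest_s * cfg.fs))
    n_chan = trials.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 997, subject]))
    pieces, annotations = [], []
    t = 0.0

    def rest_block():
        return dataset.noise_std * rng.standard_normal((n_chan, n_rest))

    pieces.append(rest_block())
    annotations.append((t, cfg.rest_s, "REST"))
    t += cfg.rest_s
    for trial, label in zip(trials, labels):
        annotations.append((t, cfg.epoch_s, str(label)))
        pieces.append(trial)
        t += cfg.epoch_s
        annotations.append((t, cfg.rest_s, "REST"))
        pieces.append(rest_block())
        t += cfg.rest_s
    samples = np.concatenate(pieces, axis=1)
    return RawRecording(samples=samples, fs=cfg.fs,
                        channel_names=dataset.epochs.montage,
                        annotations=annotations)
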