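"""Synthetic EEG sessions with the statistical structure the decoding
chains assume.

Two paradigms are emulated on top of per-channel 1/f^alpha Gaussian
background noise:

* **Motor imagery** — trials carry mu (10 Hz) and beta (20 Hz) sensorimotor
  rhythms over the C3 and C4 electrode clusters.  Imagining a hand movement
  desynchronizes the rhythm contralateral to the imagined hand, modelled as
  amplitude attenuation by ``erd_depth`` (left hand -> C4 cluster, right
  hand -> C3 cluster, both hands -> both clusters, rest -> none).

* **P300 speller** — a 6x6 symbol matrix whose 12 rows/columns flash in
  random order, 15 repetitions per character; flashes of the attended
  symbol's row and column add a positive Gaussian voltage bump (~5 uV,
  ~300 ms latency) over centro-parietal electrodes.

Both generators are pure functions of (config, seed): the same seed yields
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_core import (
    CHANNELS_62,
    CHANNELS_64,
    Event,
    EventKind,
    MIClass,
    Recording,
)
from .p300_chain import SpellerLayout, default_layout

__all__ = [
    "MISimConfig",
    "P300SimConfig",
    "pink_noise",
    "simulate_mi_dataset",
    "simulate_p300_session",
    "oddball_schedule",
]


def pink_noise(
    n_samples: int, rng: np.random.Generator, alpha: float = 1.0, rms: float = 1.0
) -> np.ndarray:
    """1/f^alpha Gaussian noise synthesized in the frequency domain,
    normalized to the requested RMS."""
    n_freq = n_samples // 2 + 1
    spectrum = rng.normal(size=n_freq) + 1j * rng.normal(size=n_freq)
    f = np.arange(n_freq, dtype=float)
    f[0] = 1.0  # avoid the DC singularity; DC is zeroed below
    spectrum *= f ** (-alpha / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n_samples)
    sd = x.std()
    if sd > 0:
        x *= rms / sd
    return x


# ---------------------------------------------------------------------------
# motor imagery


@dataclass
class MISimConfig:
    n_channels: int = 62
    fs: float = 250.0
    trial_s: float = 3.0
    gap_s: float = 1.0
    erd_depth: float = 0.5
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    mu_amplitude: float = 10.0    # uV
    beta_amplitude: float = 5.0   # uV
    noise_alpha: float = 1.0
    noise_rms: float = 10.0       # uV
    left_cluster: tuple[str, ...] = ("C3", "FC3", "CP3")
    right_cluster: tuple[str, ...] = ("C4", "FC4", "CP4")
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS_62))
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [-1, 1] (negative = ERS)")
        labels = self.channel_labels[: self.n_channels]
        if len(labels) < self.n_channels:
            raise ValueError("not enough channel labels for n_channels")
        self.channel_labels = labels
        missing = [
            ch
            for ch in (*self.left_cluster, *self.right_cluster)
            if ch not in self.channel_labels
        ]
        if missing:
            raise ValueError(f"rhythm cluster channels not in montage: {missing}")


# which rhythm clusters each imagined movement desynchronizes
_ERD_SIDES = {
    MIClass.RIGHT: ("left",),          # right hand -> contralateral C3 cluster
    MIClass.LEFT: ("right",),
    MIClass.BOTH: ("left", "right"),
    MIClass.REST: (),
}


def simulate_mi_dataset(
    cfg: MISimConfig, n_per_class: int
) -> tuple[Recording, list[MIClass]]:
    """One continuous recording of ``4 * n_per_class`` cued trials.

    Trials are ``trial_s`` long, separated by ``gap_s`` of plain background;
    MI_CUE events mark trial onsets.  Returns the recording and the trial
    labels in cue order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    classes = [c for c in MIClass for _ in range(n_per_class)]
    order = rng.permutation(len(classes))
    labels = [classes[i] for i in order]

    n_trial = int(round(cfg.trial_s * cfg.fs))
    n_gap = int(round(cfg.gap_s * cfg.fs))
    n_block = n_trial + n_gap
    n_total = n_block * len(labels) + n_gap
    data = np.empty((cfg.n_channels, n_total))
    for c in range(cfg.n_channels):
        data[c] = pink_noise(n_total, rng, cfg.noise_alpha, cfg.noise_rms)

    idx = {ch: i for i, ch in enumerate(cfg.channel_labels)}
    clusters = {
        "left": [idx[ch] for ch in cfg.left_cluster],
        "right": [idx[ch] for ch in cfg.right_cluster],
    }
    t = np.arange(n_trial) / cfg.fs
    events = []
    for k, label in enumerate(labels):
        start = n_gap + k * n_block
        events.append(Event(sample_index=start, kind=EventKind.MI_CUE, mi_class=label))
        engaged = _ERD_SIDES[label]
        for side, rows in clusters.items():
            gain = 1.0 - cfg.erd_depth if side in engaged else 1.0
            for row in rows:
                mu = cfg.mu_amplitude * np.sin(
                    2 * np.pi * cfg.mu_freq * t + rng.uniform(0, 2 * np.pi)
                )
                beta = cfg.beta_amplitude * np.sin(
                    2 * np.pi * cfg.beta_freq * t + rng.uniform(0, 2 * np.pi)
                )
                data[row, start : start + n_trial] += gain * (mu + beta)

    rec = Recording(
        data=data, fs=cfg.fs, channel_labels=list(cfg.channel_labels), events=events
    )
    return rec, labels


# ---------------------------------------------------------------------------
# P300 speller


@dataclass
class P300SimConfig:
    n_channels: int = 64
    fs: float = 240.0
    erp_amplitude: float = 5.0    # uV
    erp_latency_s: float = 0.3
    erp_width_s: float = 0.1      # FWHM of the Gaussian bump
    repetitions: int = 15
    isi_s: float = 0.25           # stimulus onset asynchrony
    noise_alpha: float = 1.0
    noise_rms: float = 10.0       # uV
    target_channels: tuple[str, ...] = (
        "Fz", "Cz", "CPz", "CP1", "CP2", "C1", "C2", "Pz",
    )
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS_64))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erp_latency_s < 0.667:
            raise ValueError("erp_latency_s must lie inside the 0.667 s window")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        labels = self.channel_labels[: self.n_channels]
        if len(labels) < self.n_channels:
            raise ValueError("not enough channel labels for n_channels")
        self.channel_labels = labels
        missing = [ch for ch in self.target_channels if ch not in self.channel_labels]
        if missing:
            raise ValueError(f"target channels not in montage: {missing}")


def oddball_schedule(
    n_chars: int,
    n_ids: int = 12,
    repetitions: int = 15,
    seed: int | np.random.Generator = 0,
) -> list[tuple[int, int, int]]:
    """(char_index, repetition, rc_id) triples: for every character and
    repetition, a uniformly random permutation of the rc ids."""
    if min(n_chars, n_ids, repetitions) < 1:
        raise ValueError("all counts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for ci in range(n_chars):
        for rep in range(repetitions):
            for rc in rng.permutation(n_ids) + 1:
                out.append((ci, rep, int(rc)))
    return out


def simulate_p300_session(
    text: str,
    cfg: P300SimConfig,
    layout: SpellerLayout | None = None,
) -> Recording:
    """Simulate spelling ``text``: per character, ``repetitions`` random
    blocks of the 12 row/column flashes; target flashes add the ERP bump on
    the centro-parietal channels."""
    layout = layout or default_layout()
    if not text:
        raise ValueError("text must be non-empty")
    targets = [layout.rc_for_char(ch) for ch in text]  # raises on unknown symbol

    rng = np.random.default_rng(cfg.seed)
    schedule = oddball_schedule(len(text), 12, cfg.repetitions, rng)
    n_isi = int(round(cfg.isi_s * cfg.fs))
    window_n = int(np.floor(0.667 * cfg.fs))
    n_total = n_isi * len(schedule) + window_n + n_isi
    data = np.empty((cfg.n_channels, n_total))
    for c in range(cfg.n_channels):
        data[c] = pink_noise(n_total, rng, cfg.noise_alpha, cfg.noise_rms)

    # ERP template: positive Gaussian bump at erp_latency_s
    sigma = cfg.erp_width_s / 2.355  # FWHM -> sd
    t = np.arange(window_n) / cfg.fs
    erp = cfg.erp_amplitude * np.exp(-0.5 * ((t - cfg.erp_latency_s) / sigma) ** 2)
    target_rows = [cfg.channel_labels.index(ch) for ch in cfg.target_channels]

    events = []
    for k, (ci, _rep, rc) in enumerate(schedule):
        onset = n_isi * (k + 1)
        row_id, col_id = targets[ci]
        is_target = rc in (row_id, col_id)
        if is_target:
            for row in target_rows:
                data[row, onset : onset + window_n] += erp
        events.append(
            Event(
                sample_index=onset,
                kind=EventKind.INTENSIFICATION,
                rc_id=rc,
                is_target=is_target,
                char_index=ci,
            )
        )
    return Recording(
        data=data, fs=cfg.fs, channel_labels=list(cfg.channel_labels), events=events
    )
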