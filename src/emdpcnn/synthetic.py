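"""Synthetic motor-imagery EEG with controllable class separability.

The generator emulates the physiological signature that motor-imagery
classifiers exploit: event-related desynchronization (ERD), i.e.
class-dependent attenuation of mu (centre 10 Hz) and beta (centre 22 Hz)
band power over lateralized sensorimotor channels.  Each epoch is a sum
of amplitude-modulated band oscillations (sinusoid with random phase and
a slow random-phase amplitude modulation) scaled by per-class,
per-channel gains, plus 1/f-shaped Gaussian background noise.  Per-subject
multiplicative gain jitter provides a controllable distribution shift for
transfer-learning experiments.

The default montage is the three bipolar sensorimotor channels C3, Cz,
C4 sampled at 250 Hz with 2-second (500-sample) epochs, the minimal
lateralized setup used for two-class imagery; archetype helpers build
two- and four-class gain patterns (left hand attenuates the
contralateral C4 column, right hand C3, foot the vertex channel Cz,
tongue the beta band diffusely).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Epoch, RawRecording

__all__ = [
    "SynthSpec",
    "two_class_spec",
    "four_class_spec",
    "generate_dataset",
    "epochs_to_arrays",
    "write_edf",
]

MU_HZ = 10.0
BETA_HZ = 22.0


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration.

    ``classes`` maps each class to per-channel (mu, beta) amplitude gains:
    a list of ``(mu_gains, beta_gains)`` pairs, each an array of length
    ``n_channels``.  Gains are dimensionless multipliers on the base band
    amplitudes (5 uV mu, 3 uV beta).  ``trials_per_class`` counts trials
    per class *per subject*; ``subject_shift_sd`` is the standard
    deviation of the per-subject multiplicative gain jitter.
    """

    classes: tuple[tuple[tuple[float, ...], tuple[float, ...]], ...]
    n_subjects: int = 1
    trials_per_class: int = 100
    n_channels: int = 3
    rate: float = 250.0
    epoch_s: float = 2.0
    noise_sd: float = 2.0
    subject_shift_sd: float = 0.1
    seed: int = 0

    mu_amplitude_uv: float = 5.0
    beta_amplitude_uv: float = 3.0
    noise_slope: float = -1.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_class < 1:
            raise ValueError("n_subjects and trials_per_class must be >= 1")
        if self.rate < 2 * BETA_HZ:
            raise ValueError("sampling rate must resolve the beta band (Nyquist)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for mu, beta in self.classes:
            if len(mu) != self.n_channels or len(beta) != self.n_channels:
                raise ValueError("gain vectors must have n_channels entries")
            if min(mu) <= 0 or min(beta) <= 0:
                raise ValueError("gains must be positive")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_samples(self) -> int:
        return int(self.rate * self.epoch_s)


def _erd(n_channels: int, attenuated: dict[int, float]) -> tuple[float, ...]:
    g = [1.0] * n_channels
    for ch, f in attenuated.items():
        g[ch] = f
    return tuple(g)


def two_class_spec(
    erd_factor: float = 0.3, noise_sd: float = 2.0, **kwargs
) -> SynthSpec:
    """Left-hand vs right-hand imagery on C3/Cz/C4.

    ``erd_factor`` is the attenuation of mu and beta gain on the
    contralateral channel (smaller = stronger ERD contrast = easier).
    """
    classes = (
        (_erd(3, {2: erd_factor}), _erd(3, {2: erd_factor})),  # left hand -> C4
        (_erd(3, {0: erd_factor}), _erd(3, {0: erd_factor})),  # right hand -> C3
    )
    return SynthSpec(classes=classes, noise_sd=noise_sd, **kwargs)


def four_class_spec(
    erd_factor: float = 0.3, noise_sd: float = 2.0, **kwargs
) -> SynthSpec:
    """Left hand / right hand / foot / tongue archetypes on C3/Cz/C4."""
    classes = (
        (_erd(3, {2: erd_factor}), _erd(3, {2: erd_factor})),  # left hand
        (_erd(3, {0: erd_factor}), _erd(3, {0: erd_factor})),  # right hand
        (_erd(3, {1: erd_factor}), _erd(3, {1: erd_factor})),  # foot -> Cz
        # tongue: diffuse beta attenuation, mu untouched
        ((1.0, 1.0, 1.0), (0.55, 0.55, 0.55)),
    )
    return SynthSpec(classes=classes, noise_sd=noise_sd, **kwargs)


def _band_oscillation(
    rng: np.random.Generator, t: np.ndarray, centre_hz: float
) -> np.ndarray:
    """Unit-amplitude sinusoid with random phase and slow AM."""
    phase = rng.uniform(0, 2 * np.pi)
    mod_hz = rng.uniform(0.5, 2.0)
    mod_phase = rng.uniform(0, 2 * np.pi)
    am = 1.0 + 0.3 * np.sin(2 * np.pi * mod_hz * t + mod_phase)
    return am * np.sin(2 * np.pi * centre_hz * t + phase)


def _pink_noise(rng: np.random.Generator, n: int, sd: float, slope: float) -> np.ndarray:
    """Gaussian noise with power-law spectrum ``P(f) ~ f^slope``."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (slope / 2.0)
    x = np.fft.irfft(spec, n)
    return sd * x / np.std(x)


def generate_dataset(spec: SynthSpec) -> tuple[list[Epoch], dict]:
    """Draw the full labelled dataset; deterministic under ``spec.seed``.

    Returns the epoch list (grouped by subject, classes interleaved) and
    an echo dict recording the spec and the realised per-subject gains.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) / spec.rate
    epochs: list[Epoch] = []
    subject_gains: list[list] = []
    for subj in range(spec.n_subjects):
        # per-subject multiplicative jitter on every (class, band, channel) gain
        jitter = 1.0 + spec.subject_shift_sd * rng.normal(
            size=(spec.n_classes, 2, spec.n_channels)
        )
        jitter = np.clip(jitter, 0.1, None)
        gains = np.array(
            [[mu, beta] for mu, beta in spec.classes], dtype=float
        ) * jitter
        subject_gains.append(gains.tolist())
        for _trial in range(spec.trials_per_class):
            for cls in range(spec.n_classes):
                data = np.empty((spec.n_channels, spec.n_samples))
                for ch in range(spec.n_channels):
                    x = spec.mu_amplitude_uv * gains[cls, 0, ch] * _band_oscillation(
                        rng, t, MU_HZ
                    )
                    x += spec.beta_amplitude_uv * gains[cls, 1, ch] * _band_oscillation(
                        rng, t, BETA_HZ
                    )
                    x += _pink_noise(rng, spec.n_samples, spec.noise_sd, spec.noise_slope)
                    data[ch] = x
                epochs.append(Epoch(data=data, label=cls, subject=subj))
    echo = {
        "n_subjects": spec.n_subjects,
        "trials_per_class": spec.trials_per_class,
        "n_classes": spec.n_classes,
        "n_channels": spec.n_channels,
        "rate": spec.rate,
        "n_samples": spec.n_samples,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "subject_gains": subject_gains,
    }
    return epochs, echo


def epochs_to_arrays(epochs: list[Epoch]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack epochs into (data, labels, subjects) arrays."""
    X = np.stack([e.data for e in epochs])
    y = np.array([e.label for e in epochs], dtype=int)
    s = np.array([e.subject for e in epochs], dtype=int)
    return X, y, s


# ---------------------------------------------------------------------------
# Minimal EDF+ writer, sufficient for io round-trip fixtures.
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(path: str | Path, rec: RawRecording) -> None:
    """Write a RawRecording as an EDF+C file with annotation markers.

    One data record per second; signals are quantised to the 16-bit EDF
    grid over their physical range (microvolts), so round-trips are exact
    only to that quantisation.  Events are stored as EDF+ time-stamped
    annotations whose description is the integer event code.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record per signal
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : rec.n_samples] = rec.samples

    ann_bytes = 120  # per-record annotation payload (60 two-byte samples)
    ann_spr = ann_bytes // 2

    phys_min = np.minimum(padded.min(axis=1), -1.0)
    phys_max = np.maximum(padded.max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic subject", 80),
            _pad("synthetic recording", 80),
            _pad("01.01.24", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (n_ch + 2)), 8),
            _pad("EDF+C", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch + 1), 4),
        ]
    )
    labels = [_pad(lbl[:16], 16) for lbl in rec.channel_labels]
    labels.append(_pad("EDF Annotations", 16))
    fields: list[bytes] = []
    fields += labels
    fields += [_pad("", 80)] * (n_ch + 1)  # transducer
    fields += [_pad("uV", 8)] * n_ch + [_pad("", 8)]
    fields += [_pad(f"{v:.8g}"[:8], 8) for v in phys_min] + [_pad("-1", 8)]
    fields += [_pad(f"{v:.8g}"[:8], 8) for v in phys_max] + [_pad("1", 8)]
    fields += [_pad(str(dig_min), 8)] * (n_ch + 1)
    fields += [_pad(str(dig_max), 8)] * (n_ch + 1)
    fields += [_pad("", 80)] * (n_ch + 1)  # prefiltering
    fields += [_pad(str(spr), 8)] * n_ch + [_pad(str(ann_spr), 8)]
    fields += [_pad("", 32)] * (n_ch + 1)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    events_by_record: dict[int, list[tuple[float, int]]] = {}
    for onset, code in rec.events:
        onset_s = onset / rate
        events_by_record.setdefault(int(onset_s), []).append((onset_s, code))

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(fields))
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr : (r + 1) * spr].tobytes())
            tal = f"+{r}\x14\x14\x00".encode("ascii")
            for onset_s, code in events_by_record.get(r, []):
                tal += f"+{onset_s:.7f}\x14{code}\x14\x00".encode("ascii")
            if len(tal) > ann_bytes:
                raise ValueError(f"too many annotations in record {r}")
            fh.write(tal.ljust(ann_bytes, b"\x00"))
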