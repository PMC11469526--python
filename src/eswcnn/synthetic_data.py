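"""Seeded synthetic benchmarks for the image and signal classifiers.

Texture classes are oriented band-pass Gaussian random fields: a white
noise field is shaped in the frequency domain by a radial band and an
angular lobe, so classes differ exactly in the spectral orientation/scale
content that wavelet scattering is designed to discriminate.  A
multiplicative illumination gain per image emulates the lighting variation
that makes raw-pixel polyp classification hard.

Signal classes are sums of sinusoids with class-dependent spectral peaks
inside the 1-10 Hz band of a weak-magnetic acquisition instrument, plus
white noise.

Both generators are pure functions of (spec, n, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TextureClassSpec",
    "SignalClassSpec",
    "gen_texture_dataset",
    "gen_signal_dataset",
    "default_texture_specs",
    "default_signal_specs",
    "default_benchmarks",
    "write_image_dataset",
]


@dataclass(frozen=True)
class TextureClassSpec:
    """Spectral recipe of one texture class.

    ``freq_band`` is (low, high) in cycles/pixel, within (0, 0.5];
    ``orientation`` in radians; ``band_energy_ratio`` is the fraction of
    field energy drawn from the oriented band (the rest is broadband);
    ``gain_range`` is the multiplicative illumination jitter.
    """

    name: str
    orientation: float
    freq_band: tuple[float, float]
    band_energy_ratio: float = 0.85
    angular_width: float = 0.35  # radians, std of the angular lobe
    gain_range: tuple[float, float] = (0.6, 1.4)
    noise_sigma: float = 0.04

    def __post_init__(self) -> None:
        lo, hi = self.freq_band
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError(f"freq_band must satisfy 0 < low < high <= 0.5, got {self.freq_band}")
        if self.gain_range[0] <= 0:
            raise ValueError("illumination gains must be positive")


@dataclass(frozen=True)
class SignalClassSpec:
    """Spectral peaks of one signal class, all within the 1-10 Hz band."""

    name: str
    peak_freqs: tuple[float, ...]
    peak_amps: tuple[float, ...]
    sampling_rate: float = 50.0
    duration: float = 2.56
    noise_sigma: float = 1.0

    def __post_init__(self) -> None:
        if any(not 1.0 <= f <= 10.0 for f in self.peak_freqs):
            raise ValueError(f"all peaks must lie in the 1-10 Hz band, got {self.peak_freqs}")
        if len(self.peak_freqs) != len(self.peak_amps):
            raise ValueError("peak_freqs and peak_amps must have equal length")


def _band_mask(size: int, spec: TextureClassSpec) -> np.ndarray:
    """Frequency-domain weights of the oriented band for a size x size grid."""
    f = np.fft.fftfreq(size)
    fy, fx = f[:, None], f[None, :]
    r = np.hypot(fy, fx)
    lo, hi = spec.freq_band
    radial = ((r >= lo) & (r <= hi)).astype(float)
    ang = np.arctan2(fy, fx)
    # angular distance to the orientation axis, pi-periodic
    d = np.angle(np.exp(2j * (ang - spec.orientation))) / 2.0
    angular = np.exp(-(d**2) / (2.0 * spec.angular_width**2))
    return radial * angular


def _texture_image(size: int, spec: TextureClassSpec, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(size=(size, size))
    shaped = np.real(np.fft.ifft2(np.fft.fft2(noise) * _band_mask(size, spec)))
    sd = shaped.std()
    if sd > 0:
        shaped = shaped / sd
    broadband = rng.normal(size=(size, size))
    w = np.sqrt(spec.band_energy_ratio)
    tex = w * shaped + np.sqrt(1.0 - spec.band_energy_ratio) * broadband
    img = 0.5 + 0.18 * tex
    gain = rng.uniform(*spec.gain_range)
    rgb = np.repeat(img[None], 3, axis=0) * gain
    rgb = rgb + rng.normal(0.0, spec.noise_sigma, size=rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


def gen_texture_dataset(
    specs: list[TextureClassSpec],
    n_per_class: int,
    size: int = 28,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Balanced labeled image set: (images (N, 3, size, size), labels, names)."""
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    seen = set()
    for s in specs:
        key = (round(s.orientation, 6), s.freq_band)
        if key in seen:
            warnings.warn(
                f"class {s.name!r} duplicates another spec's orientation and band; "
                "classes may be inseparable"
            )
        seen.add(key)
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label, spec in enumerate(specs):
        for _ in range(n_per_class):
            images.append(_texture_image(size, spec, rng))
            labels.append(label)
    return np.stack(images), np.asarray(labels), [s.name for s in specs]


def gen_signal_dataset(
    specs: list[SignalClassSpec], n_per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Balanced labeled signal set: (signals (N, T), labels, names).

    Each signal is a sum of sinusoids at the class peaks with random phases
    plus white noise.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    signals, labels = [], []
    for label, spec in enumerate(specs):
        t = np.arange(int(spec.sampling_rate * spec.duration)) / spec.sampling_rate
        for _ in range(n_per_class):
            sig = np.zeros_like(t)
            for freq, amp in zip(spec.peak_freqs, spec.peak_amps):
                sig += amp * np.sin(2.0 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            sig += rng.normal(0.0, spec.noise_sigma, size=t.shape)
            signals.append(sig)
            labels.append(label)
    return np.stack(signals), np.asarray(labels), [s.name for s in specs]


def default_texture_specs(n_classes: int = 3) -> list[TextureClassSpec]:
    """Canonical texture classes differing in orientation and radial band."""
    specs = [
        TextureClassSpec("horizontal_low", orientation=0.0, freq_band=(0.08, 0.18)),
        TextureClassSpec("oblique_low", orientation=np.pi / 3, freq_band=(0.08, 0.18)),
        TextureClassSpec("oblique_high", orientation=2 * np.pi / 3, freq_band=(0.24, 0.42)),
    ]
    if n_classes not in (2, 3):
        raise ValueError("default specs cover 2 or 3 classes")
    return specs[:n_classes]


def default_signal_specs() -> list[SignalClassSpec]:
    """Two signal classes with distinct peak pairs in the 1-10 Hz band."""
    return [
        SignalClassSpec("negative", peak_freqs=(2.0, 5.0), peak_amps=(1.0, 0.7)),
        SignalClassSpec("positive", peak_freqs=(3.5, 8.0), peak_amps=(1.0, 0.7)),
    ]


def default_benchmarks(seed: int = 2024) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    """The three canonical fixed-seed datasets used throughout the tests.

    * ``texture3``: 3 texture classes x 400 images (1,200 total) at 28x28,
      the desk-scale stand-in for a three-class polyp frame set;
    * ``texture2``: 2 texture classes x 300 images, the two-class
      (positive/negative) analog;
    * ``signal2``: 2 signal classes x 200 sequences of 128 samples,
      emulating 1-10 Hz weak-magnetic recordings.
    """
    return {
        "texture3": gen_texture_dataset(default_texture_specs(3), 400, seed=seed),
        "texture2": gen_texture_dataset(default_texture_specs(2), 300, seed=seed + 1),
        "signal2": gen_signal_dataset(default_signal_specs(), 200, seed=seed + 2),
    }


def write_image_dataset(
    images: np.ndarray, labels: np.ndarray, class_names: list[str], out_dir: str | Path
) -> Path:
    """Write images as PNG class folders plus a ``manifest.csv`` (path,label)."""
    from PIL import Image

    out_dir = Path(out_dir)
    rows = []
    for i, (img, lab) in enumerate(zip(images, labels)):
        cls = class_names[int(lab)]
        cls_dir = out_dir / cls
        cls_dir.mkdir(parents=True, exist_ok=True)
        arr = (np.clip(img, 0, 1) * 255).round().astype(np.uint8).transpose(1, 2, 0)
        path = cls_dir / f"img_{i:05d}.png"
        Image.fromarray(arr).save(path)
        rows.append({"path": str(path.relative_to(out_dir)), "label": cls})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir
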