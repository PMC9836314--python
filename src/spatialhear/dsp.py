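"""Stimulus DSP: simulated-hearing-loss low-pass filter and SNR mixing.

Noise-induced hearing loss typically removes audibility at and above ~3 kHz;
it is emulated here by low-pass filtering speech at 2.5 kHz with a
high-order filter.  The default design is a linear-phase FIR of length
``order + 1`` (a 100th-order recursive design would be numerically fragile);
the family is configurable and recorded alongside the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = ["FilterSpec", "MixSpec", "design_lowpass", "apply_lowpass",
           "scale_to_snr", "rms", "read_wav", "write_wav"]


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filter parameters: cutoff (Hz), order, and design family."""

    cutoff_hz: float = 2500.0
    order: int = 100
    family: str = "fir"  # "fir" (windowed-sinc) or "butter" (cascaded SOS)

    def __post_init__(self):
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.family not in ("fir", "butter"):
            raise ValueError(f"unknown filter family {self.family!r}")


@dataclass(frozen=True)
class MixSpec:
    """Masker presentation level (dBA, descriptive) and target SNR (dB)."""

    masker_level_dba: float = 70.0
    target_snr_db: float = 10.0

    @property
    def target_level_dba(self) -> float:
        return self.masker_level_dba + self.target_snr_db


def design_lowpass(spec: FilterSpec, sample_rate: float):
    """Design the low-pass filter; returns FIR taps or SOS sections.

    Requires ``sample_rate > 2 * cutoff`` (cutoff below Nyquist).
    """
    if sample_rate <= 2.0 * spec.cutoff_hz:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz is at or above Nyquist for fs={sample_rate} Hz"
        )
    if spec.family == "fir":
        # length order+1 -> FIR of the stated order; Hamming window default
        return signal.firwin(spec.order + 1, spec.cutoff_hz, fs=sample_rate)
    # high-order recursive designs only stable in second-order sections
    return signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=sample_rate,
                         output="sos")


def apply_lowpass(x: np.ndarray, coeffs, family: str = "fir") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if family == "fir":
        return signal.lfilter(coeffs, [1.0], x)
    return signal.sosfilt(coeffs, x)


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x))))


def scale_to_snr(target: np.ndarray, masker: np.ndarray, mix: MixSpec) -> np.ndarray:
    """Scale ``target`` so its full-band RMS sits ``target_snr_db`` above the masker's."""
    rt, rm_ = rms(target), rms(masker)
    if rt == 0.0 or rm_ == 0.0:
        raise ValueError("target and masker must be non-silent")
    current_snr = 20.0 * np.log10(rt / rm_)
    gain = 10.0 ** ((mix.target_snr_db - current_snr) / 20.0)
    return np.asarray(target, dtype=float) * gain


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a mono WAV as float64 in [-1, 1] (integer PCM rescaled)."""
    sr, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    return int(sr), data


def write_wav(path, sample_rate: int, data: np.ndarray) -> None:
    wavfile.write(path, int(sample_rate), np.asarray(data, dtype=np.float32))
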