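"""EEG band decomposition, fNIRS HbDiff formation, channel standardization.

Band filtering uses a 4th-order Butterworth applied forward-backward
(zero-phase), so switch-locked transients are not delayed by the filter.
Blocks are reflect-padded by one second before filtering and trimmed after,
because 30-s blocks are short relative to delta-band periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .data_model import Modality, ModalityBlock

__all__ = ["BandSpec", "EEG_BANDS", "bandpass_eeg", "compute_hbdiff", "standardize_channels"]


@dataclass(frozen=True)
class BandSpec:
    """A named EEG frequency band with edges in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def validate(self, rate: float) -> None:
        nyquist = rate / 2.0
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(f"band {self.name}: need 0 < low < high")
        if self.high_hz >= nyquist:
            raise ValueError(
                f"band {self.name}: high edge {self.high_hz} Hz >= Nyquist {nyquist} Hz"
            )


EEG_BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 0.5, 3.0),
    "theta": BandSpec("theta", 4.0, 7.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
}


def bandpass_eeg(block: ModalityBlock, band: BandSpec | str) -> ModalityBlock:
    """Zero-phase band-pass filter an EEG block into one frequency band."""
    if isinstance(band, str):
        band = EEG_BANDS[band]
    if block.modality is not Modality.EEG:
        raise ValueError("bandpass_eeg expects an EEG block")
    rate = block.sampling_rate
    band.validate(rate)
    sos = signal.butter(
        4, [band.low_hz, band.high_hz], btype="bandpass", fs=rate, output="sos"
    )
    pad = int(round(rate))  # 1 s reflect padding
    x = block.data
    padded = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]], axis=0)
    filtered = signal.sosfiltfilt(sos, padded, axis=0)
    return block.with_data(filtered[pad : pad + x.shape[0]])


def compute_hbdiff(oxy: np.ndarray, deoxy: np.ndarray) -> np.ndarray:
    """HbDiff = OxyHb - deOxyHb, elementwise."""
    oxy = np.asarray(oxy, dtype=np.float64)
    deoxy = np.asarray(deoxy, dtype=np.float64)
    if oxy.shape != deoxy.shape:
        raise ValueError(f"shape mismatch: oxy {oxy.shape} vs deoxy {deoxy.shape}")
    return oxy - deoxy


def standardize_channels(block: ModalityBlock) -> ModalityBlock:
    """Z-score each channel within the block (unbiased sd; constant -> 0).

    Statistics are computed per block, never per session, so no information
    crosses block (and hence subject train/test) boundaries.
    """
    x = block.data
    if x.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    centered = x - mu
    out = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)
    return block.with_data(out)
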