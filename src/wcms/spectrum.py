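"""Core in-memory containers shared across the package.

A whole-cell MALDI-TOF profile is an ordered m/z axis with one intensity per
point; sample identity (donor, cell population, stimulation condition,
technical replicate) travels alongside as :class:`SpectrumMeta`.  Detected
peaks are held as column arrays in :class:`PeakList`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SpectrumMeta", "RawSpectrum", "PeakList"]


@dataclass(frozen=True)
class SpectrumMeta:
    """Sample identity of one acquired (or simulated) spot."""

    sample_id: str = ""
    donor: str = ""
    population: str = ""
    condition: str = ""
    replicate: int = 0
    source: str = ""

    def as_dict(self) -> dict[str, Any]:
        return {
            "sample_id": self.sample_id,
            "donor": self.donor,
            "population": self.population,
            "condition": self.condition,
            "replicate": self.replicate,
            "source": self.source,
        }


@dataclass
class RawSpectrum:
    """A profile spectrum: strictly increasing m/z axis plus intensities.

    Parameters
    ----------
    mz
        m/z values in Da, strictly increasing.
    intensity
        Non-negative intensities, same length as ``mz``.
    meta
        Sample metadata.
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D")
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"length mismatch: {self.mz.size} m/z values vs "
                f"{self.intensity.size} intensities"
            )
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.mz.size)

    def copy(self) -> "RawSpectrum":
        return RawSpectrum(self.mz.copy(), self.intensity.copy(), self.meta)

    def with_intensity(self, intensity: np.ndarray) -> "RawSpectrum":
        return RawSpectrum(self.mz, np.asarray(intensity, dtype=float), self.meta)

    def with_mz(self, mz: np.ndarray) -> "RawSpectrum":
        return RawSpectrum(np.asarray(mz, dtype=float), self.intensity, self.meta)

    def crop(self, lo: float, hi: float) -> "RawSpectrum":
        """Restrict to the closed m/z window [lo, hi]."""
        keep = (self.mz >= lo) & (self.mz <= hi)
        return RawSpectrum(self.mz[keep], self.intensity[keep], self.meta)


@dataclass
class PeakList:
    """Detected peaks of one spectrum, sorted by m/z.

    ``intensity`` is the reported peak amplitude (linear scale once the
    pipeline has back-transformed it), ``height`` the apex value on the
    processed signal scale, ``snr`` the apex-to-local-noise ratio.
    """

    mz: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    height: np.ndarray | None = None
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if self.height is not None:
            self.height = np.asarray(self.height, dtype=float)
        n = self.mz.size
        if self.intensity.size != n or self.snr.size != n:
            raise ValueError("peak columns must have equal length")
        if n > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            self.snr = self.snr[order]
            if self.height is not None:
                self.height = self.height[order]

    def __len__(self) -> int:
        return int(self.mz.size)

    def scaled(self, factor: float) -> "PeakList":
        """Return a copy with intensities (and heights) divided by ``factor``."""
        return PeakList(
            self.mz.copy(),
            self.intensity / factor,
            self.snr.copy(),
            None if self.height is None else self.height / factor,
            self.meta,
        )

    def with_mz(self, mz: np.ndarray) -> "PeakList":
        return PeakList(
            np.asarray(mz, dtype=float),
            self.intensity.copy(),
            self.snr.copy(),
            None if self.height is None else self.height.copy(),
            self.meta,
        )
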