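"""Centroided peak lists: the common currency of synthetic and real spectra."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PeakList:
    """(m/z, intensity) centroids, kept sorted by m/z.

    ``metadata`` carries run context such as the precursor charge, the
    sequence identifier and the random seed of a simulation.
    """

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    def __len__(self) -> int:
        return len(self.mz)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "intensity": self.intensity})

    @classmethod
    def empty(cls, **metadata) -> "PeakList":
        return cls(np.array([]), np.array([]), metadata)
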