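"""Mass isotopomer distributions (MIDs).

A MID is the normalized vector of isotopologue fractions of one molecular
fragment, indexed by mass shift m+0, m+1, ... Every MID in this package
sums to 1 (within 1e-9) with non-negative entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_SUM_TOL = 1e-9

#: Natural abundance of 13C used as the default envelope probability.
NATURAL_13C = 0.0107


@dataclass(frozen=True)
class MIDVector:
    """Normalized mass isotopomer distribution over shifts m+0..m+n."""

    masses: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.masses, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("MID must be a non-empty 1-D vector")
        if np.any(arr < -1e-12):
            raise ValueError(f"MID has negative mass: {arr}")
        total = float(arr.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"MID masses sum to {total}, expected 1 within {_SUM_TOL}")
        object.__setattr__(self, "masses", np.clip(arr, 0.0, None))

    @classmethod
    def from_intensities(cls, intensities) -> "MIDVector":
        """Renormalize raw non-negative intensities over shifts to a MID."""
        arr = np.asarray(intensities, dtype=float)
        total = arr.sum()
        if total <= 0:
            raise ValueError("cannot form a MID from all-zero intensities")
        return cls(arr / total)

    def mass(self, shift: int) -> float:
        """Fraction at shift m+`shift` (0 beyond the stored range)."""
        if 0 <= shift < self.masses.size:
            return float(self.masses[shift])
        return 0.0

    def __len__(self) -> int:
        return self.masses.size

    def __getitem__(self, shift: int) -> float:
        return self.mass(shift)

    def padded(self, n_shifts: int) -> np.ndarray:
        """Masses zero-padded (or validated) out to ``n_shifts`` entries."""
        if n_shifts < self.masses.size:
            if self.masses[n_shifts:].sum() > _SUM_TOL:
                raise ValueError("cannot truncate a MID with mass beyond requested range")
            return self.masses[:n_shifts].copy()
        return np.pad(self.masses, (0, n_shifts - self.masses.size))


def natural_abundance_envelope(n_carbons: int, p13c: float = NATURAL_13C) -> np.ndarray:
    """Binomial envelope over ``n_carbons`` carbons at 13C probability ``p13c``.

    Entry k is the probability of k heavy carbons purely from natural
    abundance; the envelope of a 0-carbon fragment is the identity [1].
    """
    if not 0.0 <= p13c <= 1.0:
        raise ValueError(f"p13c must be a probability, got {p13c}")
    if n_carbons < 0:
        raise ValueError("carbon count must be non-negative")
    if n_carbons == 0 or p13c == 0.0:
        env = np.zeros(n_carbons + 1)
        env[0] = 1.0
        return env
    return stats.binom.pmf(np.arange(n_carbons + 1), n_carbons, p13c)


def convolve_envelope(mid: MIDVector, envelope: np.ndarray) -> MIDVector:
    """Convolve a tracer-derived MID with a natural-abundance envelope."""
    return MIDVector(np.convolve(mid.masses, np.asarray(envelope, dtype=float)))
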