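"""Hydrophobic-moment profiling and amphipathic-helix (AH) classification.

The Eisenberg hydrophobic moment treats each residue's hydrophobicity as a
vector at the helical angle (100 deg/residue for an ideal alpha-helix) and
takes the magnitude of the vector sum, normalized per residue:

    muH = (1/w) * sqrt( (sum_i H_i sin(i*delta))^2 + (sum_i H_i cos(i*delta))^2 )

with i the 0-based residue index within a sliding window of w residues and
H the Eisenberg consensus hydrophobicity scale. A peptide is called
amphipathic-helical when some window reaches muH >= 0.4 (the conventional
boundary of hydrophobic-moment-plot analyses) with a non-negative mean
hydrophobicity over that window — the co-threshold standing in for a
membrane-association call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# Eisenberg consensus hydrophobicity scale
EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}


class PeptideError(ValueError):
    pass


@dataclass
class AhProfile:
    """Sliding-window hydrophobic-moment profile of one peptide."""

    peptide: str
    window: int
    delta: float  # degrees per residue
    per_window_muH: list[float] = field(default_factory=list)
    per_window_meanH: list[float] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.per_window_muH)

    @property
    def max_muH(self) -> float:
        return max(self.per_window_muH, default=0.0)

    @property
    def max_window_start(self) -> int:
        """1-based residue index of the highest-muH window (0 if no windows)."""
        if not self.per_window_muH:
            return 0
        return max(range(self.n_windows), key=lambda i: self.per_window_muH[i]) + 1


def hydrophobic_moment(peptide: str, window: int = 18, delta: float = 100.0) -> AhProfile:
    """Per-window Eisenberg hydrophobic moment and mean hydrophobicity.

    A peptide shorter than the window yields an empty profile (not an
    error); a non-standard residue raises :class:`PeptideError` naming its
    position.
    """
    if window < 1:
        raise PeptideError("window must be >= 1")
    pep = peptide.upper()
    for i, aa in enumerate(pep):
        if aa not in EISENBERG:
            raise PeptideError(f"non-standard residue {aa!r} at position {i + 1}")
    h = [EISENBERG[aa] for aa in pep]
    rad = math.radians(delta)
    sines = [math.sin(i * rad) for i in range(window)]
    cosines = [math.cos(i * rad) for i in range(window)]
    profile = AhProfile(peptide=pep, window=window, delta=delta)
    for start in range(0, len(pep) - window + 1):
        seg = h[start : start + window]
        sy = math.fsum(hi * si for hi, si in zip(seg, sines))
        sx = math.fsum(hi * ci for hi, ci in zip(seg, cosines))
        profile.per_window_muH.append(math.hypot(sx, sy) / window)
        profile.per_window_meanH.append(math.fsum(seg) / window)
    return profile


def classify_ah(
    profile: AhProfile, muH_threshold: float = 0.4, meanH_threshold: float = 0.0
) -> bool:
    """AH call: max muH meets the threshold and the max-muH window's mean
    hydrophobicity is at least ``meanH_threshold``. Empty profiles are False."""
    if not profile.per_window_muH:
        return False
    best = profile.max_window_start - 1
    return (
        profile.per_window_muH[best] >= muH_threshold
        and profile.per_window_meanH[best] >= meanH_threshold
    )
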