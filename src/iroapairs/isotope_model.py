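"""Carbon isotopologue envelope model for dual-label (IROA) experiments.

In an IROA experiment every biosynthesized metabolite appears twice in the
same LC/MS run: once from the sample culture grown on a ~95:5 12C:13C carbon
source, and once from the pooled internal standard grown on ~5:95.  If each
of the n carbon atoms of a metabolite is independently 13C with probability
p, the number of 13C atoms is Binomial(n, p), so the isotopologue envelope
of the sample channel peaks at the all-12C monoisotopic species (k = 0) and
the internal-standard envelope mirrors it, peaking at k = n.  The m/z gap
between the two monoisotopic species is n * (m13C - m12C) / z, which is what
makes the carbon count directly readable from the spectrum.

This module is pure computation: envelopes, the 13C spacing, carbon-count
estimation from an observed gap, and a cosine similarity used to decide
which channel an observed envelope belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "DELTA_C13",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "LabelingScheme",
    "carbon_isotopologue_envelope",
    "isotopologue_spacing",
    "estimate_carbon_count",
    "envelope_similarity",
]

#: Exact 13C - 12C mass difference (Da).
DELTA_C13 = 1.0033548

#: Mass of a proton (H+ = 1H minus one electron), Da.
PROTON_MASS = 1.0072765

#: Electron rest mass, Da.
ELECTRON_MASS = 0.00054858

#: Monoisotopic (principal isotope) masses of the elements handled here, Da.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
}


@dataclass(frozen=True)
class LabelingScheme:
    """Per-carbon 13C probabilities of the two channels of a dual-label study.

    Parameters
    ----------
    p13_sample : float
        Probability that a carbon atom is 13C in the sample channel
        (treatment/control cultures; default 0.05, i.e. 95:5 12C:13C media).
    p13_is : float
        Same for the pooled internal-standard channel (default 0.95,
        i.e. 5:95 media).
    """

    p13_sample: float = 0.05
    p13_is: float = 0.95

    def __post_init__(self) -> None:
        for name, p in (("p13_sample", self.p13_sample), ("p13_is", self.p13_is)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not self.p13_sample < 0.5 < self.p13_is:
            raise ValueError(
                "expected p13_sample < 0.5 < p13_is (light sample channel, "
                f"heavy IS channel); got {self.p13_sample}, {self.p13_is}"
            )


def carbon_isotopologue_envelope(n_carbons: int, p13: float) -> np.ndarray:
    """Binomial isotopologue envelope of an n-carbon metabolite.

    Entry k is the probability of carrying exactly k 13C atoms,
    C(n, k) * p13**k * (1 - p13)**(n - k).  The returned vector has length
    ``n_carbons + 1`` and sums to 1.
    """
    if n_carbons < 0:
        raise ValueError(f"n_carbons must be >= 0, got {n_carbons}")
    if not 0.0 <= p13 <= 1.0:
        raise ValueError(f"p13 must lie in [0, 1], got {p13}")
    # direct product form, grouped so that entry k under p equals entry n-k
    # under 1-p bitwise; also safe at extreme enrichments where library pmf
    # implementations over/underflow
    q = 1.0 - p13
    env = np.array(
        [
            comb(n_carbons, k) * (p13**k * q ** (n_carbons - k))
            for k in range(n_carbons + 1)
        ],
        dtype=float,
    )
    return env


def isotopologue_spacing(charge: int = 1) -> float:
    """m/z gap between isotopologues differing by one 13C, for charge z."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return DELTA_C13 / charge


def estimate_carbon_count(
    delta_mz: float, charge: int = 1, max_carbons: int = 60
) -> tuple[int, float]:
    """Carbon count implied by the m/z gap between the two monoisotopic ions.

    The gap between the all-12C and all-13C monoisotopic species is
    n * DELTA_C13 / z, so n is recovered by rounding.  Returns ``(n,
    residual_ppm)`` where the residual is the deviation of ``delta_mz`` from
    the ideal n-carbon gap, in ppm of that gap.  Acceptance of the residual
    is the caller's decision (pairing applies its own window).
    """
    if delta_mz <= 0:
        raise ValueError(f"delta_mz must be > 0, got {delta_mz}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    n = int(round(delta_mz * charge / DELTA_C13))
    n = max(1, min(n, max_carbons))
    ideal = n * DELTA_C13 / charge
    residual_ppm = (delta_mz - ideal) / ideal * 1e6
    return n, residual_ppm


def envelope_similarity(observed: np.ndarray, template: np.ndarray) -> float:
    """Cosine similarity of two envelopes, shorter zero-padded at the end."""
    a = np.asarray(observed, dtype=float)
    b = np.asarray(template, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("envelopes must be 1-D vectors")
    size = max(a.size, b.size)
    a = np.pad(a, (0, size - a.size))
    b = np.pad(b, (0, size - b.size))
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cannot compare a zero envelope")
    return float(np.dot(a, b) / (na * nb))
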