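"""Exact-mass arithmetic and carbon-constrained molecular formula assignment.

The dual-label design reads the carbon count of every detected metabolite
straight off the spectrum, which collapses the usual combinatorial explosion
of formula candidates: enumeration only has to search H/N/O (optionally S/P)
space for a *fixed* number of carbons.  This module provides the formula
container with valence/RDBE plausibility filters, monoisotopic mass and
adduct m/z arithmetic, the constrained enumerator, and matching of peak
pairs against a retention-time library of authentic standards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .isotope_model import ELECTRON_MASS, MONOISOTOPIC_MASS, PROTON_MASS

__all__ = [
    "Formula",
    "Adduct",
    "ADDUCTS",
    "LibraryEntry",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_from_mz",
    "enumerate_formulas",
    "library_match",
]

ELEMENTS = ("C", "H", "N", "O", "S", "P")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element-count vector over C, H, N, O, S, P."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0
    P: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if getattr(self, el) < 0:
                raise ValueError(f"negative count for {el}")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-notation formula string such as ``C6H13NO2``."""
        counts = dict.fromkeys(ELEMENTS, 0)
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text.strip()):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            if el not in counts:
                raise ValueError(f"unsupported element {el!r} in {text!r}")
            counts[el] += int(num) if num else 1
        if pos != len(text.strip()) or pos == 0:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(**counts)

    def __str__(self) -> str:
        out = []
        for el in ELEMENTS:
            n = getattr(self, el)
            if n == 1:
                out.append(el)
            elif n > 1:
                out.append(f"{el}{n}")
        return "".join(out)

    @property
    def rdbe(self) -> float:
        """Ring-and-double-bond equivalents, C - H/2 + N/2 + 1 (S, O neutral; P trivalent)."""
        return self.C - self.H / 2 + (self.N + self.P) / 2 + 1

    def is_plausible(self) -> bool:
        """Valence sanity: H <= 2C + 2 + N and integer RDBE >= 0."""
        if self.H > 2 * self.C + 2 + self.N + self.P:
            return False
        r = self.rdbe
        return r >= 0 and abs(r - round(r)) < 1e-9


def monoisotopic_mass(formula: Formula) -> float:
    """Neutral monoisotopic mass in Da (sum of principal-isotope masses)."""
    return sum(getattr(formula, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS)


@dataclass(frozen=True)
class Adduct:
    """An ionization adduct: observed m/z = (M + mass_delta) / |charge|."""

    name: str
    mass_delta: float
    charge: int
    polarity: str = field(init=False)

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge cannot be 0")
        object.__setattr__(self, "polarity", "positive" if self.charge > 0 else "negative")


#: Common ESI adducts; the electron mass is folded into the deltas so that
#: charged-species arithmetic is bit-consistent everywhere.
ADDUCTS = {
    "[M+H]+": Adduct("[M+H]+", PROTON_MASS, +1),
    "[M-H]-": Adduct("[M-H]-", -PROTON_MASS, -1),
    "[M+Na]+": Adduct("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
}


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Observed m/z of a neutral mass under the given adduct."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return (neutral_mass + adduct.mass_delta) / abs(adduct.charge)


def neutral_from_mz(mz: float, adduct: Adduct | str) -> float:
    """Inverse of :func:`adduct_mz`."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return mz * abs(adduct.charge) - adduct.mass_delta


def enumerate_formulas(
    neutral_mass: float,
    n_carbons: int,
    tol_ppm: float = 10.0,
    element_bounds: dict[str, int] | None = None,
) -> list[Formula]:
    """All plausible formulas with exactly ``n_carbons`` carbons near a mass.

    Searches N, O, S, P within ``element_bounds`` (defaults: H 100, N 20,
    O 30, S 0, P 0 — CHNO space) and solves for the hydrogen count
    analytically, keeping formulas whose monoisotopic mass lies within
    ``tol_ppm`` of ``neutral_mass`` and which pass the valence/RDBE filter.
    Sorted by absolute mass error.
    """
    if n_carbons < 1:
        raise ValueError(f"n_carbons must be >= 1, got {n_carbons}")
    bounds = {"H": 100, "N": 20, "O": 30, "S": 0, "P": 0}
    if element_bounds:
        bounds.update(element_bounds)
    tol_da = tol_ppm * 1e-6 * neutral_mass
    m_h = MONOISOTOPIC_MASS["H"]
    out: list[Formula] = []
    base_c = n_carbons * MONOISOTOPIC_MASS["C"]
    for n_n in range(bounds["N"] + 1):
        m_cn = base_c + n_n * MONOISOTOPIC_MASS["N"]
        if m_cn > neutral_mass + tol_da:
            break
        for n_o in range(bounds["O"] + 1):
            m_cno = m_cn + n_o * MONOISOTOPIC_MASS["O"]
            if m_cno > neutral_mass + tol_da:
                break
            for n_s in range(bounds["S"] + 1):
                m_cnos = m_cno + n_s * MONOISOTOPIC_MASS["S"]
                if m_cnos > neutral_mass + tol_da:
                    break
                for n_p in range(bounds["P"] + 1):
                    m_heavy = m_cnos + n_p * MONOISOTOPIC_MASS["P"]
                    if m_heavy > neutral_mass + tol_da:
                        break
                    # candidate hydrogen counts bracketing the residual mass
                    h_exact = (neutral_mass - m_heavy) / m_h
                    for n_h in {int(h_exact), int(h_exact) + 1}:
                        if not 0 <= n_h <= bounds["H"]:
                            continue
                        f = Formula(C=n_carbons, H=n_h, N=n_n, O=n_o, S=n_s, P=n_p)
                        if abs(monoisotopic_mass(f) - neutral_mass) <= tol_da and f.is_plausible():
                            out.append(f)
    out.sort(key=lambda f: (abs(monoisotopic_mass(f) - neutral_mass), str(f)))
    return out


@dataclass(frozen=True)
class LibraryEntry:
    """One authentic standard: name, formula, retention time, polarity."""

    name: str
    formula: Formula
    rt_sec: float
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.rt_sec < 0:
            raise ValueError("rt_sec must be >= 0")


def library_match(
    carbon_count: int,
    mz12: float,
    rt_sec: float,
    polarity: str,
    library: list[LibraryEntry],
    adducts: list[Adduct | str] | None = None,
    tol_ppm: float = 10.0,
    rt_tol: float = 30.0,
) -> list[dict]:
    """Identify a peak pair against a standards library.

    An entry matches when the carbon counts are equal, some adduct m/z of
    the entry's formula lies within ``tol_ppm`` of the observed 12C
    monoisotopic m/z, retention times agree within ``rt_tol`` seconds, and
    polarities are compatible.  Matches are ranked by absolute mass error.
    """
    if adducts is None:
        adducts = ["[M+H]+"] if polarity == "positive" else ["[M-H]-"]
    adducts = [ADDUCTS[a] if isinstance(a, str) else a for a in adducts]
    hits = []
    for entry in library:
        if entry.polarity != polarity or entry.formula.C != carbon_count:
            continue
        if abs(entry.rt_sec - rt_sec) > rt_tol:
            continue
        for ad in adducts:
            if ad.polarity != polarity:
                continue
            expected = adduct_mz(monoisotopic_mass(entry.formula), ad)
            err_ppm = (mz12 - expected) / expected * 1e6
            if abs(err_ppm) <= tol_ppm:
                hits.append(
                    {
                        "name": entry.name,
                        "formula": str(entry.formula),
                        "adduct": ad.name,
                        "mass_error_ppm": err_ppm,
                        "rt_error_sec": rt_sec - entry.rt_sec,
                    }
                )
    hits.sort(key=lambda h: abs(h["mass_error_ppm"]))
    return hits
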