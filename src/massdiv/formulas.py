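"""Chemical-formula arithmetic for CHNOSP molecular formulas.

Everything downstream of an ultrahigh-resolution mass spectrum works on
neutral molecular formulas over C, H, N, O, S and P: exact monoisotopic
masses, the deprotonated-ion m/z observed in negative-mode electrospray,
unsaturation (double-bond equivalents, DBE), the modified aromaticity
index (AImod), heteroatomic grouping (CHO / CHON / CHOS / CHOP / others)
and van Krevelen style compound-class labels.

Conventions
-----------
* Formulas are written and parsed in plain Hill notation (``C6H8O6``),
  no subscripts, charges or adducts.
* DBE = 1 + C - H/2 + (N + P)/2, treating N and P as trivalent.
* AImod = (1 + C - O/2 - S - (N + P + H)/2) / (C - O/2 - N - S - P),
  clamped to 0 whenever numerator or denominator is non-positive.
* Ion m/z for [M-H]- is the neutral monoisotopic mass minus the proton
  mass (1.00727646688 Da), which bundles the removed H with the gained
  electron.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterator

__all__ = [
    "MolecularFormula",
    "FormulaDescriptors",
    "CompoundClass",
    "OxygenClass",
    "CompoundClassLabel",
    "FormulaError",
    "parse_formula",
    "hill_string",
    "monoisotopic_mass",
    "mz_deprotonated",
    "dbe",
    "aimod",
    "heteroatomic_group",
    "compound_class",
    "descriptors",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "C13_C12_DELTA",
    "C13_ABUNDANCE_RATIO",
]

# IUPAC/CODATA monoisotopic masses of the lightest stable isotopes, Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass removed on deprotonation (H atom minus the retained electron), Da.
PROTON_MASS: float = 1.00727646688

#: Mass difference between a 13C and a 12C atom, Da.
C13_C12_DELTA: float = 1.003355

#: Natural 13C/12C abundance ratio (per carbon atom).
C13_ABUNDANCE_RATIO: float = 0.010816

_ELEMENT_ORDER = ("C", "H", "N", "O", "P", "S")  # Hill: C, H, then alphabetical
_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Neutral molecular formula over C, H, N, O, S, P (element counts)."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise FormulaError(f"element count {name}={v!r} must be a non-negative integer")
        if self.c < 1:
            raise FormulaError("formula must contain at least one carbon")
        if self.h + self.n + self.o + self.s + self.p == 0:
            raise FormulaError("bare carbon clusters are not supported (no H or heteroatom)")

    # -- convenience -------------------------------------------------
    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "P": self.p, "S": self.s}

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts().items())

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s, self.p + other.p,
        )

    def __str__(self) -> str:
        return hill_string(self)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    @property
    def hill(self) -> str:
        return hill_string(self)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string over C, H, N, O, S, P.

    Raises
    ------
    FormulaError
        On unsupported element symbols, malformed counts, repeated
        elements, or a formula without carbon.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} near position {pos}")
        if not m.group(0):
            break
        sym, digits = m.group(1), m.group(2)
        if sym not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {sym!r} in {text!r}")
        if sym in counts:
            raise FormulaError(f"element {sym} repeated in {text!r}")
        counts[sym] = int(digits) if digits else 1
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} near position {pos}")
    return MolecularFormula(
        c=counts.get("C", 0), h=counts.get("H", 0), n=counts.get("N", 0),
        o=counts.get("O", 0), s=counts.get("S", 0), p=counts.get("P", 0),
    )


def hill_string(f: MolecularFormula) -> str:
    """Canonical Hill-order rendering (C, H, then alphabetical; count 1 implicit)."""
    parts = []
    for sym in _ELEMENT_ORDER:
        cnt = f.counts()[sym]
        if cnt == 1:
            parts.append(sym)
        elif cnt > 1:
            parts.append(f"{sym}{cnt}")
    return "".join(parts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Neutral monoisotopic mass in Da (lightest isotope of every element)."""
    return sum(MONOISOTOPIC_MASS[sym] * cnt for sym, cnt in f)


def mz_deprotonated(f: MolecularFormula) -> float:
    """m/z of the singly deprotonated even-electron ion [M-H]-."""
    return monoisotopic_mass(f) - PROTON_MASS


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents: 1 + C - H/2 + (N + P)/2 (trivalent N, P)."""
    return 1.0 + f.c - f.h / 2.0 + (f.n + f.p) / 2.0


def aimod(f: MolecularFormula) -> float:
    """Modified aromaticity index; half the oxygen is treated as carbonyl-like.

    Returns 0 whenever the numerator or denominator is non-positive, so
    aliphatic, oxygen-rich formulas cleanly map to zero aromaticity.
    """
    num = 1.0 + f.c - f.o / 2.0 - f.s - (f.n + f.p + f.h) / 2.0
    den = f.c - f.o / 2.0 - f.n - f.s - f.p
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


class CompoundClass(str, Enum):
    SATURATED = "saturated"
    AROMATIC = "aromatic"
    POLYPHENOL = "polyphenol"
    HIGHLY_UNSATURATED = "highly_unsaturated"
    UNSATURATED = "unsaturated"


class OxygenClass(str, Enum):
    O_RICH = "O_rich"
    O_POOR = "O_poor"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class CompoundClassLabel:
    major: CompoundClass
    oxygen: OxygenClass
    with_n: bool = False

    def __str__(self) -> str:
        major = self.major.value.replace("_", " ")
        if self.with_n:
            return f"{major} (with N)"
        if self.oxygen is OxygenClass.NOT_APPLICABLE:
            return major
        return f"{major} ({'O rich' if self.oxygen is OxygenClass.O_RICH else 'O poor'})"


@dataclass(frozen=True)
class FormulaDescriptors:
    """Per-formula descriptor bundle used throughout profiling."""

    monoisotopic_mass: float
    mz_deprotonated: float
    dbe: float
    aimod: float
    h_c: float
    o_c: float


def descriptors(f: MolecularFormula) -> FormulaDescriptors:
    m = monoisotopic_mass(f)
    return FormulaDescriptors(
        monoisotopic_mass=m,
        mz_deprotonated=m - PROTON_MASS,
        dbe=dbe(f),
        aimod=aimod(f),
        h_c=f.h / f.c,
        o_c=f.o / f.c,
    )


def heteroatomic_group(f: MolecularFormula) -> str:
    """Heteroatomic family by element content.

    CHO, CHON, CHOS and CHOP denote exactly one class of heteroatom
    beyond oxygen; any co-occurrence of N, S, P collapses to "others".
    Formulas without oxygen fold into the same families by their N/S/P
    content (a pure hydrocarbon is CHO-family).
    """
    present = [sym for sym in ("N", "S", "P") if f.counts()[sym] > 0]
    if len(present) == 0:
        return "CHO"
    if len(present) == 1:
        return f"CHO{present[0]}"
    return "others"


def compound_class(f: MolecularFormula) -> CompoundClassLabel:
    """Van Krevelen / aromaticity compound-class label.

    Evaluation order: saturated (DBE = 0) first, then aromatic
    (AImod > 0.666), polyphenol (0.5 < AImod <= 0.666), highly
    unsaturated (AImod < 0.5 and H/C < 1.5); everything else —
    including H/C > 2 with DBE > 0 — is unsaturated.  Classes are
    subdivided by oxygen content (O rich: O/C > 0.5; O poor otherwise),
    except that nitrogen-containing unsaturated formulas are flagged
    "with N" instead.
    """
    ai = aimod(f)
    hc = f.h / f.c
    oc = f.o / f.c
    if dbe(f) == 0:
        major = CompoundClass.SATURATED
    elif ai > 0.666:
        major = CompoundClass.AROMATIC
    elif ai > 0.5:
        major = CompoundClass.POLYPHENOL
    elif hc < 1.5:
        major = CompoundClass.HIGHLY_UNSATURATED
    else:
        major = CompoundClass.UNSATURATED
    if major is CompoundClass.UNSATURATED and f.n >= 1:
        return CompoundClassLabel(major, OxygenClass.NOT_APPLICABLE, with_n=True)
    oxygen = OxygenClass.O_RICH if oc > 0.5 else OxygenClass.O_POOR
    return CompoundClassLabel(major, oxygen)
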