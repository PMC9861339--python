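"""Per-extract molecular profiles and composition summaries.

A :class:`SampleProfile` is the normalized formula-intensity vector of
one extract (fractions summing to one).  From profiles the module
derives intensity-weighted mean descriptors (H/C_w, O/C_w, DBE_w,
AImod_w), heteroatomic and compound-class composition percentages,
shared/exclusive formula sets across extracts, and targeted series
queries (e.g. the C10H16O1..5 monoterpene ladder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import AssignmentSet
from .formulas import (
    MolecularFormula,
    aimod,
    compound_class,
    dbe,
    heteroatomic_group,
    hill_string,
    parse_formula,
)

__all__ = [
    "SampleProfile",
    "DescriptorSummary",
    "build_profile",
    "weighted_descriptors",
    "composition_percentages",
    "shared_exclusive",
    "series_query",
    "profiles_to_matrix",
    "matrix_to_profiles",
]


@dataclass
class SampleProfile:
    """Normalized formula-intensity profile of one extract."""

    sample_id: str
    intensities: dict[MolecularFormula, float]
    metadata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ValueError(f"profile {self.sample_id!r} has no formulas")
        total = sum(self.intensities.values())
        if any(v <= 0 for v in self.intensities.values()):
            raise ValueError("profile intensities must be positive")
        if abs(total - 1.0) > 1e-9:
            self.intensities = {f: v / total for f, v in self.intensities.items()}

    @property
    def formulas(self) -> set[MolecularFormula]:
        return set(self.intensities)

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass(frozen=True)
class DescriptorSummary:
    """Intensity-weighted mean descriptors of a profile (subscript-w)."""

    h_c_w: float
    o_c_w: float
    dbe_w: float
    aimod_w: float


def build_profile(a: AssignmentSet, sample_id: str,
                  metadata: Mapping[str, float] | None = None) -> SampleProfile:
    """Normalized profile of one sample from an assignment set."""
    raw = a.formula_intensities(sample_id)
    if not raw:
        raise ValueError(f"sample {sample_id!r} has no assigned formulas")
    return SampleProfile(sample_id, raw, dict(metadata or {}))


def weighted_descriptors(p: SampleProfile) -> DescriptorSummary:
    """Intensity-weighted means of H/C, O/C, DBE and AImod."""
    w = np.array(list(p.intensities.values()))
    fs = list(p.intensities)
    return DescriptorSummary(
        h_c_w=float(np.dot(w, [f.h / f.c for f in fs])),
        o_c_w=float(np.dot(w, [f.o / f.c for f in fs])),
        dbe_w=float(np.dot(w, [dbe(f) for f in fs])),
        aimod_w=float(np.dot(w, [aimod(f) for f in fs])),
    )


def composition_percentages(
    p: SampleProfile,
    basis: str = "count",
    grouping: str = "heteroatomic",
) -> dict[str, float]:
    """Composition of a profile as percentages summing to 100.

    ``basis`` is ``"count"`` (fraction of the number of formulas) or
    ``"intensity"`` (fraction of total normalized intensity);
    ``grouping`` is ``"heteroatomic"`` (CHO/CHON/CHOS/CHOP/others) or
    ``"compound_class"`` (aromatic (O rich) ... unsaturated (with N)).
    """
    if basis not in ("count", "intensity"):
        raise ValueError(f"unknown basis {basis!r}")
    if grouping == "heteroatomic":
        label = lambda f: heteroatomic_group(f)
    elif grouping == "compound_class":
        label = lambda f: str(compound_class(f))
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    acc: dict[str, float] = {}
    for f, w in p.intensities.items():
        acc[label(f)] = acc.get(label(f), 0.0) + (1.0 if basis == "count" else w)
    total = sum(acc.values())
    return {k: 100.0 * v / total for k, v in sorted(acc.items())}


def shared_exclusive(
    profiles: Sequence[SampleProfile],
) -> tuple[dict[str, set[MolecularFormula]], set[MolecularFormula]]:
    """Per-sample exclusive formula sets and the globally shared set.

    A formula is exclusive to a sample when no other profile contains
    it; the shared set is the intersection over all profiles.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among profiles")
    sets = {p.sample_id: p.formulas for p in profiles}
    shared = set.intersection(*sets.values())
    exclusive: dict[str, set[MolecularFormula]] = {}
    for sid, fs in sets.items():
        others = set.union(*(s for other, s in sets.items() if other != sid))
        exclusive[sid] = fs - others
    return exclusive, shared


def series_query(
    formulas: Iterable[MolecularFormula],
    base_c: int,
    base_h: int,
    o_range: tuple[int, int],
    extra_elements: Mapping[str, int] | None = None,
) -> list[MolecularFormula]:
    """Formulas with fixed C and H counts and O within a range.

    ``extra_elements`` pins N/S/P counts (default: all zero), so e.g.
    ``series_query(fs, 10, 16, (1, 5))`` returns the monoterpene-like
    C10H16O1..5 ladder and ``extra_elements={"N": 2}`` instead matches
    C10H16N2O_x.
    """
    if o_range[0] > o_range[1]:
        raise ValueError("empty o_range")
    extra = {"N": 0, "S": 0, "P": 0}
    for k, v in (extra_elements or {}).items():
        if k.upper() not in extra:
            raise ValueError(f"unsupported extra element {k!r}")
        extra[k.upper()] = v
    hits = [f for f in formulas
            if f.c == base_c and f.h == base_h
            and o_range[0] <= f.o <= o_range[1]
            and f.n == extra["N"] and f.s == extra["S"] and f.p == extra["P"]]
    return sorted(hits, key=lambda f: (f.o, hill_string(f)))


def profiles_to_matrix(profiles: Sequence[SampleProfile]) -> pd.DataFrame:
    """Formulas x samples matrix of normalized intensities (absent = 0)."""
    universe = sorted({f for p in profiles for f in p.formulas},
                      key=lambda f: (f.mass, hill_string(f)))
    data = {p.sample_id: [p.intensities.get(f, 0.0) for f in universe] for p in profiles}
    return pd.DataFrame(data, index=[hill_string(f) for f in universe])


def matrix_to_profiles(df: pd.DataFrame,
                       metadata: pd.DataFrame | None = None) -> list[SampleProfile]:
    """Inverse of :func:`profiles_to_matrix` (rows formulas, columns samples)."""
    out = []
    for sid in df.columns:
        col = df[sid]
        intensities = {parse_formula(str(f)): float(v) for f, v in col.items() if v > 0}
        meta = {}
        if metadata is not None and sid in metadata.index:
            meta = {k: float(v) for k, v in metadata.loc[sid].items()}
        out.append(SampleProfile(str(sid), intensities, meta))
    return out
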