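"""Molecular-formula attribution for aligned mass features.

Each consensus feature (an [M-H]- ion mass) is attributed a neutral
CHNOSP formula by exact-mass search within a ppm tolerance, followed by
the filters the field applies to weed out spurious hits:

* an element-ratio / valence plausibility screen (the "N, S, P rule"):
  0.3 <= H/C <= 2.5, O/C <= 1.5, N <= 4, S <= 2, P <= 2, integer
  non-negative DBE, and at least one exchangeable H for deprotonation;
* 13C isotopologue verification: a candidate whose predicted M+1 peak
  should have been detectable is vetoed when the observed M+1/M ratio
  is incompatible with its carbon count (or the peak is missing);
* homologous-series support: candidates that chain into CH2 series
  across features are preferred, since natural mixtures are rich in
  such series while random isobaric interlopers are not.

Ties are broken deterministically: longest CH2 series, then smallest
|mass error|, then fewest heteroatoms (N+S+P), then Hill string.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .formulas import (
    C13_ABUNDANCE_RATIO,
    C13_C12_DELTA,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    MolecularFormula,
    dbe,
    hill_string,
)
from .spectra import DEFAULT_MZ_WINDOW, AlignedPeakTable, Spectrum

__all__ = [
    "ElementBounds",
    "AssignmentCandidate",
    "AssignmentConfig",
    "AssignmentSet",
    "nsp_valence_ok",
    "enumerate_candidates",
    "isotope_check",
    "build_homologous_series",
    "assign_peaks",
]

logger = logging.getLogger(__name__)

_mC = MONOISOTOPIC_MASS["C"]
_mH = MONOISOTOPIC_MASS["H"]
_mN = MONOISOTOPIC_MASS["N"]
_mO = MONOISOTOPIC_MASS["O"]
_mS = MONOISOTOPIC_MASS["S"]
_mP = MONOISOTOPIC_MASS["P"]


@dataclass(frozen=True)
class ElementBounds:
    """Per-element maximum counts for the formula search."""

    c: int = 60
    h: int = 120
    n: int = 4
    o: int = 40
    s: int = 2
    p: int = 2


@dataclass(frozen=True)
class AssignmentCandidate:
    formula: MolecularFormula
    theoretical_mass: float           # neutral monoisotopic mass, Da
    theoretical_mz: float             # [M-H]- ion m/z, Da
    error_ppm: float                  # (observed - theoretical) / theoretical * 1e6
    isotope_verified: bool = False
    series_length: int = 1


def nsp_valence_ok(f: MolecularFormula) -> bool:
    """Element-ratio and valence plausibility screen.

    True iff 0.3 <= H/C <= 2.5, O/C <= 1.5, N <= 4, S <= 2, P <= 2,
    DBE is a non-negative integer (even-electron neutral molecule), and
    there is at least one H to lose on deprotonation.
    """
    hc = f.h / f.c
    if not (0.3 <= hc <= 2.5):
        return False
    if f.o / f.c > 1.5:
        return False
    if f.n > 4 or f.s > 2 or f.p > 2:
        return False
    if f.h < 1:
        return False
    d = dbe(f)
    return d >= 0 and float(d).is_integer()


def enumerate_candidates(
    neutral_mass: float,
    tol_ppm: float = 0.2,
    bounds: ElementBounds = ElementBounds(),
) -> list[AssignmentCandidate]:
    """All valence-plausible formulas within ``tol_ppm`` of a neutral mass.

    Exhaustive search over the bounded CHNOSP space, pruned by the mass
    window; sorted by |error_ppm| (ties by Hill string for determinism).
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be non-negative")
    lo = neutral_mass * (1.0 - tol_ppm * 1e-6)
    hi = neutral_mass * (1.0 + tol_ppm * 1e-6)
    out: list[AssignmentCandidate] = []
    for n in range(bounds.n + 1):
        m_n = n * _mN
        if m_n + _mC + _mH > hi:
            break
        for s in range(bounds.s + 1):
            m_ns = m_n + s * _mS
            if m_ns + _mC + _mH > hi:
                break
            for p in range(bounds.p + 1):
                m_nsp = m_ns + p * _mP
                if m_nsp + _mC + _mH > hi:
                    break
                o_max = min(bounds.o, int((hi - m_nsp - _mC - _mH) / _mO))
                for o in range(o_max + 1):
                    base = m_nsp + o * _mO
                    # O/C <= 1.5 bounds carbon from below
                    c_lo = max(1, math.ceil(o / 1.5))
                    c_hi = min(bounds.c, int((hi - base - _mH) / _mC))
                    for c in range(c_lo, c_hi + 1):
                        bc = base + c * _mC
                        h_lo = max(1, math.ceil((lo - bc) / _mH - 1e-12),
                                   math.ceil(0.3 * c - 1e-12))
                        h_hi = min(bounds.h, int((hi - bc) / _mH + 1e-12),
                                   int(2.5 * c + 1e-12), 2 + 2 * c + n + p)
                        # integer DBE: h must share parity with n+p
                        parity = (n + p) % 2
                        if h_lo % 2 != parity:
                            h_lo += 1
                        for h in range(h_lo, h_hi + 1, 2):
                            mass = bc + h * _mH
                            if not (lo <= mass <= hi):
                                continue
                            f = MolecularFormula(c, h, n, o, s, p)
                            err = (neutral_mass - mass) / mass * 1e6
                            out.append(AssignmentCandidate(
                                formula=f, theoretical_mass=mass,
                                theoretical_mz=mass - PROTON_MASS, error_ppm=err))
    out.sort(key=lambda cand: (abs(cand.error_ppm), hill_string(cand.formula)))
    return out


def isotope_check(
    c: AssignmentCandidate,
    s: Spectrum,
    mz_tol_ppm: float = 1.0,
    ratio_tol: float = 0.3,
    mdl_threshold: float | None = None,
) -> bool:
    """Verify a candidate against its 13C1 isotopologue in a spectrum.

    The expected M+1 relative intensity is ``carbons * 0.010816``.  A
    candidate is vetoed when an M+1 peak is found whose relative
    intensity deviates from expectation by more than ``ratio_tol``
    (fractional), or when no M+1 peak is found although the expected
    intensity lies above the detection threshold.  When the expected
    isotopologue would be undetectable, the candidate passes by default.
    """
    parent = _nearest_intensity(s.mz, s.intensity, c.theoretical_mz, mz_tol_ppm)
    if parent is None:
        raise ValueError("candidate's monoisotopic peak not found in spectrum")
    return _isotope_ok(c.formula.c, parent,
                       _nearest_intensity(s.mz, s.intensity,
                                          c.theoretical_mz + C13_C12_DELTA, mz_tol_ppm),
                       ratio_tol, mdl_threshold)


def _nearest_intensity(mz: np.ndarray, inten: np.ndarray, target: float,
                       tol_ppm: float) -> float | None:
    idx = np.searchsorted(mz, target)
    best: float | None = None
    best_d = tol_ppm * 1e-6 * target
    for i in (idx - 1, idx):
        if 0 <= i < mz.size and abs(mz[i] - target) <= best_d:
            d = abs(mz[i] - target)
            if best is None or d < best_d:
                best, best_d = float(inten[i]), d
    return best


def _isotope_ok(carbons: int, parent_intensity: float, iso_intensity: float | None,
                ratio_tol: float, mdl_threshold: float | None) -> bool:
    expected_ratio = carbons * C13_ABUNDANCE_RATIO
    expected_intensity = expected_ratio * parent_intensity
    if iso_intensity is None:
        if mdl_threshold is not None and expected_intensity >= mdl_threshold:
            return False
        return True  # expected signal undetectable: pass by default
    observed_ratio = iso_intensity / parent_intensity
    return abs(observed_ratio - expected_ratio) <= ratio_tol * expected_ratio


def build_homologous_series(
    formulas: Iterable[MolecularFormula],
) -> dict[MolecularFormula, tuple[int, int]]:
    """CH2-homologous series: formula -> (series id, series length).

    Formulas differing by exactly one CH2 are linked; series are the
    connected components of that graph and series length the component
    size.  Singletons get length 1.
    """
    formulas = set(formulas)
    g = nx.Graph()
    g.add_nodes_from(formulas)
    for f in formulas:
        up = MolecularFormula(f.c + 1, f.h + 2, f.n, f.o, f.s, f.p)
        if up in formulas:
            g.add_edge(f, up)
    out: dict[MolecularFormula, tuple[int, int]] = {}
    for sid, comp in enumerate(sorted(nx.connected_components(g),
                                      key=lambda comp: min(hill_string(f) for f in comp))):
        for f in comp:
            out[f] = (sid, len(comp))
    return out


@dataclass(frozen=True)
class AssignmentConfig:
    tolerance_ppm: float = 0.2
    bounds: ElementBounds = ElementBounds()
    mz_window: tuple[float, float] = DEFAULT_MZ_WINDOW
    isotope_verification: bool = True
    isotope_mz_tol_ppm: float = 1.0
    isotope_ratio_tol: float = 0.3
    mdl_threshold: float | None = None   # absolute intensity; None = pass-by-default


@dataclass
class AssignmentSet:
    """Per-feature formula attributions over an aligned peak table."""

    table: AlignedPeakTable
    frame: pd.DataFrame    # columns: mz, formula, error_ppm, isotope_verified, series_length, reason

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_assigned(self) -> int:
        return int(self.frame["formula"].notna().sum())

    def assigned(self) -> pd.DataFrame:
        return self.frame[self.frame["formula"].notna()]

    def formula_intensities(self, sample_id: str) -> dict[MolecularFormula, float]:
        """Formula -> consensus intensity for one sample (zeros dropped)."""
        try:
            col = self.table.samples.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"unknown sample {sample_id!r}") from exc
        j = [i for i, (sid, _) in enumerate(self.table.columns)
             if sid == sample_id]
        inten = self.table.intensities[:, j].mean(axis=1)
        out: dict[MolecularFormula, float] = {}
        for i, fstr in enumerate(self.frame["formula"]):
            if isinstance(fstr, str) and inten[i] > 0:
                from .formulas import parse_formula
                out[parse_formula(fstr)] = float(inten[i])
        return out

    def to_tsv(self, path: str | Path, unassigned_path: str | Path | None = None) -> None:
        df = self.frame.copy()
        for i, (sid, rid) in enumerate(self.table.columns):
            name = sid if rid is None else f"{sid}/{rid}"
            df[name] = self.table.intensities[:, i]
        df[df["formula"].notna()].drop(columns="reason").to_csv(
            path, sep="\t", index=False, float_format="%.10g")
        if unassigned_path is not None:
            df[df["formula"].isna()][["mz", "reason"]].to_csv(
                unassigned_path, sep="\t", index=False, float_format="%.10g")


def assign_peaks(t: AlignedPeakTable, config: AssignmentConfig = AssignmentConfig()) -> AssignmentSet:
    """Attribute one formula (or none) to each feature of an aligned table.

    Pipeline per feature: recover the neutral mass (add the proton
    mass), enumerate candidates within tolerance (valence-screened),
    veto isotope-incompatible candidates using the table's own M+1
    features, then select by longest CH2 series, smallest |error|,
    fewest heteroatoms, Hill string.  A formula claimed by several
    features is kept only at its best-matching feature.  Failures are
    per-feature, logged, never fatal.
    """
    mz = t.mz
    total_intensity = t.intensities.sum(axis=1)
    neutral = mz + PROTON_MASS

    per_feature: list[list[AssignmentCandidate]] = []
    reasons: list[str | None] = []
    iso_checked: list[bool] = []
    lo_w, hi_w = config.mz_window
    for i in range(t.n_features):
        if not (lo_w <= mz[i] <= hi_w):
            per_feature.append([])
            reasons.append("out_of_range")
            iso_checked.append(False)
            continue
        cands = enumerate_candidates(neutral[i], config.tolerance_ppm, config.bounds)
        if not cands:
            per_feature.append([])
            reasons.append("no_candidates")
            iso_checked.append(False)
            continue
        checked = False
        if config.isotope_verification:
            kept = []
            for cand in cands:
                iso_int = _nearest_intensity(mz, total_intensity,
                                             mz[i] + C13_C12_DELTA,
                                             config.isotope_mz_tol_ppm)
                if _isotope_ok(cand.formula.c, float(total_intensity[i]), iso_int,
                               config.isotope_ratio_tol, config.mdl_threshold):
                    kept.append(AssignmentCandidate(
                        formula=cand.formula, theoretical_mass=cand.theoretical_mass,
                        theoretical_mz=cand.theoretical_mz, error_ppm=cand.error_ppm,
                        isotope_verified=iso_int is not None))
                    checked = checked or iso_int is not None
            if not kept:
                per_feature.append([])
                reasons.append("isotope_vetoed")
                iso_checked.append(False)
                continue
            cands = kept
        per_feature.append(cands)
        reasons.append(None)
        iso_checked.append(checked)

    # series support over the union of surviving candidates
    universe = {c.formula for cands in per_feature for c in cands}
    series = build_homologous_series(universe)

    chosen: list[AssignmentCandidate | None] = []
    for cands in per_feature:
        if not cands:
            chosen.append(None)
            continue
        best = min(cands, key=lambda c: (-series[c.formula][1], abs(c.error_ppm),
                                         c.formula.n + c.formula.s + c.formula.p,
                                         hill_string(c.formula)))
        chosen.append(AssignmentCandidate(
            formula=best.formula, theoretical_mass=best.theoretical_mass,
            theoretical_mz=best.theoretical_mz, error_ppm=best.error_ppm,
            isotope_verified=best.isotope_verified,
            series_length=series[best.formula][1]))

    # a formula may back only one feature: keep the best |error|
    by_formula: dict[MolecularFormula, list[int]] = {}
    for i, cand in enumerate(chosen):
        if cand is not None:
            by_formula.setdefault(cand.formula, []).append(i)
    for f, idxs in by_formula.items():
        if len(idxs) > 1:
            idxs.sort(key=lambda i: abs(chosen[i].error_ppm))  # type: ignore[union-attr]
            for i in idxs[1:]:
                chosen[i] = None
                reasons[i] = "duplicate_formula"
            logger.info("assign_peaks: formula %s claimed by %d features; kept best",
                        hill_string(f), len(idxs))

    frame = pd.DataFrame({
        "mz": mz,
        "formula": [hill_string(c.formula) if c else None for c in chosen],
        "error_ppm": [c.error_ppm if c else np.nan for c in chosen],
        "isotope_verified": [bool(c.isotope_verified) if c else False for c in chosen],
        "series_length": [c.series_length if c else 0 for c in chosen],
        "reason": reasons,
    })
    n_assigned = int(frame["formula"].notna().sum())
    logger.info("assign_peaks: %d/%d features assigned", n_assigned, t.n_features)
    return AssignmentSet(table=t, frame=frame)
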