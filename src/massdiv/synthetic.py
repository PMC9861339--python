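"""Ground-truth simulator for negative-mode ultrahigh-resolution spectra.

Simulates the study design the rest of the package is built for: two
algal species extracted with five solvents, each extract measured in
duplicate on a negative-mode FT-ICR instrument over 100-1000 Da with
sub-0.1-ppm mass accuracy.  Every emitted peak is recorded in a truth
ledger (formula, true and emitted mass, intensity, noise/isotopologue
flags), so noise filtering, alignment, replicate consensus, formula
assignment and the downstream statistics can all be scored exactly.

What is emulated: lognormal intensity dynamic range, Gaussian ppm-scale
mass error, 13C1 isotopologues at their natural relative abundance,
Poisson-count noise peaks uniform in m/z with log-uniform intensity
around the detection limit, replicate-independent noise, CH2-homologous
family structure of the formula library, and group-specific chemistry
(one species enriched in nitrogen-bearing formulas, the other dominated
by CHO).  What is not: transients, resolution profiles, space-charge
artefacts, adducts, multiply charged ions, chromatography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import ElementBounds, nsp_valence_ok
from .formulas import (
    C13_ABUNDANCE_RATIO,
    C13_C12_DELTA,
    PROTON_MASS,
    MolecularFormula,
    hill_string,
    monoisotopic_mass,
)
from .spectra import Spectrum

__all__ = [
    "LibraryConfig",
    "SpectrumModel",
    "StudyDesign",
    "EffectModel",
    "TruthLedger",
    "StudyData",
    "generate_formula_library",
    "simulate_spectrum",
    "simulate_study",
    "SOLVENTS",
]

#: Filename-safe names of the five extraction solvents of the design.
SOLVENTS: tuple[str, ...] = (
    "dH2O", "dH2O-EtOH-1-1", "dH2O-EtOH-1-4", "dH2O-MeOH-1-1", "dH2O-MeOH-1-4",
)


@dataclass(frozen=True)
class LibraryConfig:
    """Random formula-library model.

    Libraries are built as CH2-homologous families (natural mixtures
    are rich in such series) whose members must pass the valence screen,
    fall inside the mass window, and keep a minimum relative mass gap to
    every other member so that the library itself contains no
    unresolvable near-isobars.  ``hetero_weights`` give the sampling
    probabilities of the N count (index = number of N atoms) and steer
    the CHON-vs-CHO balance of a library.
    """

    mass_range: tuple[float, float] = (100.0, 1000.0)
    min_gap_ppm: float = 1.0
    family_mean_length: float = 3.0
    c_range: tuple[int, int] = (6, 35)
    o_range: tuple[int, int] = (1, 14)
    hetero_weights: tuple[float, ...] = (0.55, 0.20, 0.13, 0.08, 0.04)
    s_weights: tuple[float, ...] = (0.82, 0.13, 0.05)
    p_weights: tuple[float, ...] = (0.88, 0.09, 0.03)
    bounds: ElementBounds = ElementBounds()


def generate_formula_library(
    n: int,
    seed: int | np.random.Generator = 0,
    config: LibraryConfig = LibraryConfig(),
    include_formulas: Iterable[MolecularFormula] = (),
) -> list[MolecularFormula]:
    """Draw ``n`` distinct valence-valid formulas with ledger-grade determinism.

    ``include_formulas`` are seeded first (e.g. the published isomer-table
    formulas) and count towards ``n``.  Raises if the constraints cannot
    be satisfied within a bounded number of attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = config.mass_range
    out: list[MolecularFormula] = []
    masses: list[float] = []

    def gap_ok(m: float) -> bool:
        return all(abs(m - m2) > config.min_gap_ppm * 1e-6 * max(m, m2) for m2 in masses)

    def try_add(f: MolecularFormula) -> bool:
        m = monoisotopic_mass(f)
        if not (lo <= m <= hi) or not nsp_valence_ok(f) or f in out or not gap_ok(m):
            return False
        b = config.bounds
        if f.c > b.c or f.h > b.h or f.n > b.n or f.o > b.o or f.s > b.s or f.p > b.p:
            return False
        out.append(f)
        masses.append(m)
        return True

    for f in include_formulas:
        if len(out) >= n:
            break
        if not try_add(f):
            raise ValueError(f"seed formula {hill_string(f)} violates the library constraints")

    attempts = 0
    max_attempts = 2000 * n
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"library constraints unsatisfiable: {len(out)}/{n} formulas "
                f"after {attempts} attempts")
        c = int(rng.integers(config.c_range[0], config.c_range[1] + 1))
        nn = int(rng.choice(len(config.hetero_weights), p=config.hetero_weights))
        s = int(rng.choice(len(config.s_weights), p=config.s_weights))
        p = int(rng.choice(len(config.p_weights), p=config.p_weights))
        o = int(rng.integers(config.o_range[0], min(config.o_range[1], max(1, int(1.4 * c))) + 1))
        h_lo = max(1, math.ceil(0.35 * c))
        h_hi = min(int(2.2 * c), 2 + 2 * c + nn + p)
        if h_hi < h_lo:
            continue
        h = int(rng.integers(h_lo, h_hi + 1))
        # integer-DBE parity
        if (h + nn + p) % 2 == 1:
            h += 1
        fam_len = 1 + int(rng.geometric(1.0 / config.family_mean_length))
        for k in range(fam_len):
            if len(out) >= n:
                break
            try:
                f = MolecularFormula(c + k, h + 2 * k, nn, o, s, p)
            except ValueError:
                continue
            try_add(f)
    return out


@dataclass(frozen=True)
class SpectrumModel:
    """Peak-level generative model for one measurement.

    Signal intensities are lognormal (median ``intensity_median``,
    shape ``intensity_sigma`` on the natural log); masses carry
    Gaussian relative error with standard deviation
    ``mass_error_ppm_sd`` (the instrument calibrates below 0.1 ppm, so
    0.05 ppm is the default).  Each formula also emits its 13C1
    isotopologue at ``carbons * 0.010816`` relative intensity.  Noise:
    Poisson(``noise_mean_count``) peaks, uniform in m/z over the
    acquisition window, log-uniform intensity between
    ``noise_floor_factor`` and ``noise_ceiling_factor`` times the noise
    level — i.e. straddling the method detection limit so that both the
    MDL rule and replicate consensus have real work to do.
    """

    mass_error_ppm_sd: float = 0.05
    intensity_median: float = 1.0e6
    intensity_sigma: float = 1.0
    noise_level: float = 1000.0
    noise_mean_count: int = 150
    noise_floor_factor: float = 0.2
    noise_ceiling_factor: float = 4.0
    mz_window: tuple[float, float] = (100.0, 1000.0)
    isotopologues: bool = True


@dataclass
class TruthLedger:
    """Per-peak provenance of simulated spectra.

    One row per emitted peak: sample/replicate, kind (signal,
    isotopologue or noise), the true formula (empty for noise), the
    exact and the emitted m/z, and the intensity.  Seeds and model
    parameters are stored alongside.
    """

    frame: pd.DataFrame
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def signal_formulas(self, sample_id: str, replicate_id: str | None = None) -> set[str]:
        df = self.frame
        m = (df["sample_id"] == sample_id) & (df["kind"] == "signal")
        if replicate_id is not None:
            m &= df["replicate_id"] == replicate_id
        return set(df.loc[m, "formula"])

    def noise_mz(self, sample_id: str, replicate_id: str) -> np.ndarray:
        df = self.frame
        m = ((df["sample_id"] == sample_id) & (df["replicate_id"] == replicate_id)
             & (df["kind"] == "noise"))
        return df.loc[m, "emitted_mz"].to_numpy()

    def concat(self, other: "TruthLedger") -> "TruthLedger":
        return TruthLedger(pd.concat([self.frame, other.frame], ignore_index=True),
                           seed=self.seed, params=self.params)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=0)


def simulate_spectrum(
    library: Sequence[MolecularFormula],
    seed: int | np.random.Generator = 0,
    model: SpectrumModel = SpectrumModel(),
    *,
    sample_id: str = "S",
    replicate_id: str = "r1",
    expected_intensity: Mapping[MolecularFormula, float] | None = None,
) -> tuple[Spectrum, TruthLedger]:
    """Simulate one measurement of a formula library.

    Draw order (fixed for reproducibility): per formula in library
    order, intensity then parent mass error then isotopologue mass
    error; then the noise count, noise masses, noise intensities.
    ``expected_intensity`` overrides the lognormal expectation per
    formula (used by the study simulator for group/solvent effects);
    the replicate-level draw multiplies it by a lognormal factor.
    """
    if not library:
        raise ValueError("library must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    mzs: list[float] = []
    intens: list[float] = []

    for f in library:
        mass = monoisotopic_mass(f)
        ion = mass - PROTON_MASS
        if expected_intensity is not None:
            base = float(expected_intensity[f])
            inten = base * float(np.exp(rng.normal(0.0, 0.25)))
            rng.normal()  # keep the draw count per formula constant
        else:
            inten = model.intensity_median * float(
                np.exp(rng.normal(0.0, model.intensity_sigma)))
            rng.normal()
        err = rng.normal(0.0, model.mass_error_ppm_sd * 1e-6)
        emitted = ion * (1.0 + err)
        rows.append((sample_id, replicate_id, "signal", hill_string(f), ion, emitted, inten))
        mzs.append(emitted)
        intens.append(inten)
        if model.isotopologues:
            iso_ion = ion + C13_C12_DELTA
            iso_err = rng.normal(0.0, model.mass_error_ppm_sd * 1e-6)
            iso_emitted = iso_ion * (1.0 + iso_err)
            iso_inten = f.c * C13_ABUNDANCE_RATIO * inten
            rows.append((sample_id, replicate_id, "isotopologue", hill_string(f),
                         iso_ion, iso_emitted, iso_inten))
            mzs.append(iso_emitted)
            intens.append(iso_inten)

    n_noise = int(rng.poisson(model.noise_mean_count))
    lo, hi = model.mz_window
    log_f, log_c = np.log(model.noise_floor_factor), np.log(model.noise_ceiling_factor)
    placed = 0
    while placed < n_noise:
        mz = float(rng.uniform(lo, hi))
        if any(abs(mz - m) <= 2e-6 for m in mzs):
            continue  # redraw: centroids closer than 1e-6 Da are unresolvable
        inten = model.noise_level * float(np.exp(rng.uniform(log_f, log_c)))
        rows.append((sample_id, replicate_id, "noise", "", mz, mz, inten))
        mzs.append(mz)
        intens.append(inten)
        placed += 1

    spectrum = Spectrum(np.array(mzs), np.array(intens), sample_id=sample_id,
                        replicate_id=replicate_id, noise_level=model.noise_level)
    frame = pd.DataFrame(rows, columns=["sample_id", "replicate_id", "kind", "formula",
                                        "true_mz", "emitted_mz", "intensity"])
    return spectrum, TruthLedger(frame, params={"model": model.__dict__})


@dataclass(frozen=True)
class StudyDesign:
    """Groups x solvents x replicates factorial design."""

    groups: tuple[str, ...] = ("A", "B")
    solvents: tuple[str, ...] = SOLVENTS
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per extract")
        if len(self.solvents) < 1:
            raise ValueError("need at least 1 solvent")

    def sample_id(self, group: str, solvent: str) -> str:
        return f"{group}_{solvent}"


@dataclass(frozen=True)
class EffectModel:
    """Group/solvent effect structure and the metadata linear model.

    Each group's formula pool is the shared pool plus a group-exclusive
    pool (``exclusive_fraction`` of the library per group).  Group "A"
    exclusives are drawn nitrogen-enriched (CHON-dominated) and all
    other groups' exclusives CHO-dominated, mirroring the distinct
    heteroatomic chemistries of a red and a brown alga.  Solvents
    modulate expected intensities by a lognormal factor of spread
    ``solvent_sigma``.  Metadata vectors follow
    ``value = base + effect * 1[group != first] + N(0, noise_sd)``.
    """

    exclusive_fraction: float = 0.2
    solvent_sigma: float = 0.5
    metadata_base: Mapping[str, float] = field(
        default_factory=lambda: {"phenolics_mg_g": 5.0, "antioxidant_umol_te_g": 10.0})
    metadata_effect: Mapping[str, float] = field(
        default_factory=lambda: {"phenolics_mg_g": 10.0, "antioxidant_umol_te_g": 20.0})
    metadata_noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"phenolics_mg_g": 1.0, "antioxidant_umol_te_g": 2.0})


@dataclass
class StudyData:
    spectra: list[Spectrum]
    metadata: pd.DataFrame          # index: sample_id; columns: metadata vectors + group/solvent
    ledger: TruthLedger
    replicate_map: dict[str, list[str]]
    library: list[MolecularFormula]
    pools: dict[str, set[MolecularFormula]]   # group -> formula pool (incl. shared)


def simulate_study(
    design: StudyDesign = StudyDesign(),
    n_formulas: int = 500,
    effect: EffectModel = EffectModel(),
    model: SpectrumModel = SpectrumModel(),
    seed: int = 0,
    library_config: LibraryConfig = LibraryConfig(),
) -> StudyData:
    """Simulate a full groups x solvents x replicates study.

    Returns spectra (one per replicate measurement), a per-extract
    metadata table correlated with group identity, and the pooled truth
    ledger.  Fully deterministic given ``seed``: child generators are
    spawned from one SeedSequence in a fixed order.
    """
    n_groups = len(design.groups)
    n_excl = int(round(effect.exclusive_fraction * n_formulas))
    n_shared = n_formulas - n_groups * n_excl
    if n_shared < 1 or (n_excl < 1 and effect.exclusive_fraction > 0):
        raise ValueError("degenerate design: pools would be empty")

    ss = np.random.SeedSequence(seed)
    # fixed spawn order: shared lib, per-group libs, intensities, spectra, metadata
    children = ss.spawn(3 + n_groups + n_groups * len(design.solvents) * design.n_replicates)
    rng_shared = np.random.default_rng(children[0])
    shared = generate_formula_library(n_shared, rng_shared, library_config)
    taken = list(shared)
    pools: dict[str, set[MolecularFormula]] = {}
    excl: dict[str, list[MolecularFormula]] = {}
    for gi, group in enumerate(design.groups):
        rng_g = np.random.default_rng(children[1 + gi])
        if gi == 0:    # nitrogen-enriched chemistry
            cfg = replace(library_config, hetero_weights=(0.10, 0.30, 0.30, 0.20, 0.10))
        else:          # CHO-dominated chemistry
            cfg = replace(library_config, hetero_weights=(0.85, 0.09, 0.04, 0.02, 0.00))
        lib_g = generate_formula_library(len(taken) + n_excl, rng_g, cfg,
                                         include_formulas=taken)
        new = lib_g[len(taken):]
        excl[group] = new
        taken.extend(new)
    for group in design.groups:
        pools[group] = set(shared) | set(excl[group])

    # expected intensities: per (group, formula) base, per solvent multiplier
    rng_int = np.random.default_rng(children[1 + n_groups])
    expected: dict[tuple[str, str], dict[MolecularFormula, float]] = {}
    for group in design.groups:
        pool = sorted(pools[group], key=hill_string)
        base = {f: model.intensity_median * float(np.exp(rng_int.normal(0.0, model.intensity_sigma)))
                for f in pool}
        for solvent in design.solvents:
            mult = {f: float(np.exp(rng_int.normal(0.0, effect.solvent_sigma))) for f in pool}
            expected[(group, solvent)] = {f: base[f] * mult[f] for f in pool}

    spectra: list[Spectrum] = []
    ledgers: list[pd.DataFrame] = []
    replicate_map: dict[str, list[str]] = {}
    ci = 2 + n_groups
    for group in design.groups:
        for solvent in design.solvents:
            sid = design.sample_id(group, solvent)
            pool = sorted(pools[group], key=hill_string)
            replicate_map[sid] = []
            for r in range(design.n_replicates):
                rid = f"r{r + 1}"
                rng_s = np.random.default_rng(children[ci])
                ci += 1
                sp, led = simulate_spectrum(
                    pool, rng_s, model, sample_id=sid, replicate_id=rid,
                    expected_intensity=expected[(group, solvent)])
                spectra.append(sp)
                ledgers.append(led.frame)
                replicate_map[sid].append(rid)

    rng_meta = np.random.default_rng(children[ci])
    meta_rows = []
    for group in design.groups:
        for solvent in design.solvents:
            row: dict[str, object] = {"sample_id": design.sample_id(group, solvent),
                                      "group": group, "solvent": solvent}
            for name, base_v in effect.metadata_base.items():
                eff = effect.metadata_effect.get(name, 0.0)
                sd = effect.metadata_noise_sd.get(name, 0.0)
                val = base_v + (eff if group != design.groups[0] else 0.0)
                row[name] = val + float(rng_meta.normal(0.0, sd)) if sd > 0 else val
            meta_rows.append(row)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    ledger = TruthLedger(pd.concat(ledgers, ignore_index=True), seed=seed,
                         params={"design": design.__dict__, "model": model.__dict__,
                                 "effect": {k: (dict(v) if isinstance(v, Mapping) else v)
                                            for k, v in effect.__dict__.items()}})
    return StudyData(spectra=spectra, metadata=metadata, ledger=ledger,
                     replicate_map=replicate_map, library=taken, pools=pools)
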