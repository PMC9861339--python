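"""End-to-end workflow: peak lists -> assignments -> profiles -> ordination.

Glue that chains the processing modules in the canonical order (noise
filter, alignment, duplicate consensus, formula attribution, profile
normalization, Bray-Curtis / PCoA / vector fitting) with one config
object, so the CLI, the examples and the test harness all run the
identical code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assignment import AssignmentConfig, AssignmentSet, assign_peaks
from .diversity import DissimilarityMatrix, Ordination, VectorFit, bray_curtis, fit_vectors, pcoa
from .formulas import MolecularFormula, parse_formula
from .profiles import SampleProfile, build_profile
from .spectra import AlignedPeakTable, Spectrum, align_spectra, duplicate_consensus, mdl_filter, remove_masses

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "replicate_profiles"]


@dataclass(frozen=True)
class PipelineConfig:
    mdl_factor: float = 2.5
    align_tol_ppm: float = 0.5
    assignment: AssignmentConfig = AssignmentConfig()
    exclusion_masses: tuple[float, ...] = ()
    replicate_level_ordination: bool = True
    k_axes: int = 2
    n_perm: int = 10_000
    seed: int = 0


@dataclass
class PipelineResult:
    aligned: AlignedPeakTable
    consensus: AlignedPeakTable
    assignments: AssignmentSet
    profiles: list[SampleProfile]
    ordination_profiles: list[SampleProfile]
    dissimilarity: DissimilarityMatrix
    ordination: Ordination
    vector_fit: VectorFit | None

    @property
    def n_formulas_identified(self) -> int:
        """Distinct formulas assigned across all samples (after consensus)."""
        return self.assignments.n_assigned


def replicate_profiles(
    aset: AssignmentSet,
    aligned: AlignedPeakTable,
    metadata: pd.DataFrame | None = None,
) -> list[SampleProfile]:
    """Replicate-level profiles restricted to consensus-retained features.

    The consensus rule decides which (feature, sample) pairs are real;
    the replicate-level intensities of exactly those features then give
    one profile per measurement, so technical replicates enter the
    ordination as separate points.
    """
    cons = aset.table
    cons_index: dict[float, int] = {}
    idx = np.searchsorted(aligned.mz, cons.mz)
    profiles = []
    sample_cols = {sid: j for j, (sid, _) in enumerate(cons.columns)}
    for j_col, (sid, rid) in enumerate(aligned.columns):
        inten_col = aligned.intensities[:, j_col]
        retained = cons.intensities[:, sample_cols[sid]] > 0
        intensities: dict[MolecularFormula, float] = {}
        for i_cons, i_full in enumerate(idx):
            if not retained[i_cons]:
                continue
            fstr = aset.frame["formula"].iloc[i_cons]
            if not isinstance(fstr, str):
                continue
            v = float(inten_col[i_full])
            if v > 0:
                intensities[parse_formula(fstr)] = v
        if not intensities:
            continue
        meta = {}
        if metadata is not None and sid in metadata.index:
            meta = {k: float(v) for k, v in metadata.loc[sid].items()
                    if isinstance(v, (int, float, np.floating, np.integer))}
        profiles.append(SampleProfile(f"{sid}/{rid}", intensities, meta))
    return profiles


def run_pipeline(
    spectra: Sequence[Spectrum],
    replicate_map: Mapping[str, Sequence[str]] | None = None,
    metadata: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full workflow on a set of replicate measurements.

    ``metadata`` (rows: sample ids; numeric columns) feeds the
    permutation vector fitting; when absent the vector-fit step is
    skipped.
    """
    filtered = [mdl_filter(s, config.mdl_factor) for s in spectra]
    if config.exclusion_masses:
        filtered = [remove_masses(s, config.exclusion_masses, config.align_tol_ppm)
                    for s in filtered]
    aligned = align_spectra(filtered, config.align_tol_ppm)
    consensus = duplicate_consensus(aligned, replicate_map)
    aset = assign_peaks(consensus, config.assignment)

    profiles = []
    for sid in consensus.samples:
        meta = {}
        if metadata is not None and sid in metadata.index:
            meta = {k: float(v) for k, v in metadata.loc[sid].items()
                    if isinstance(v, (int, float, np.floating, np.integer))}
        profiles.append(build_profile(aset, sid, meta))

    if config.replicate_level_ordination:
        ord_profiles = replicate_profiles(aset, aligned, metadata)
    else:
        ord_profiles = profiles
    d = bray_curtis(ord_profiles)
    o = pcoa(d)

    vf = None
    if metadata is not None:
        numeric = metadata.select_dtypes(include=[np.number])
        if len(numeric.columns):
            rows = {}
            for name in numeric.columns:
                per_sample = numeric[name]
                rows[name] = [float(per_sample[pid.split("/")[0]]) for pid in o.ids]
            k = min(config.k_axes, o.n_axes)
            vf = fit_vectors(o, rows, k_axes=k, n_perm=config.n_perm, seed=config.seed)
    return PipelineResult(aligned=aligned, consensus=consensus, assignments=aset,
                          profiles=profiles, ordination_profiles=ord_profiles,
                          dissimilarity=d, ordination=o, vector_fit=vf)
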