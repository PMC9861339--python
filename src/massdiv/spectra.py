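"""Peak-list I/O, noise filtering, mass alignment and replicate consensus.

A :class:`Spectrum` holds the centroided peak list of one measurement of
one extract (negative-mode, singly charged ions assumed throughout).
Spectra from all measurements are mass-aligned into an
:class:`AlignedPeakTable`; the duplicate-consensus rule then keeps a
feature for a sample only when it was detected in every replicate
measurement of that sample, which is the main guard against spurious
peaks surviving the noise filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "Spectrum",
    "AlignedPeakTable",
    "PeakListError",
    "read_peaklist",
    "write_peaklist",
    "estimate_noise_level",
    "mdl_filter",
    "remove_masses",
    "align_spectra",
    "duplicate_consensus",
    "DEFAULT_MZ_WINDOW",
]

logger = logging.getLogger(__name__)

#: Default acquisition window in Da (m/z of singly charged ions).
DEFAULT_MZ_WINDOW: tuple[float, float] = (100.0, 1000.0)


class PeakListError(ValueError):
    """Raised for unreadable or empty peak lists."""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One centroided measurement: sorted m/z and intensity arrays.

    ``sample_id`` names the extract; ``replicate_id`` distinguishes the
    duplicate measurements of that extract.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    replicate_id: str = ""
    noise_level: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise PeakListError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity <= 0):
            raise PeakListError("intensities must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 1e-6):
            raise PeakListError("duplicate m/z values (< 1e-6 Da apart) within one spectrum")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.replicate_id)


def read_peaklist(
    path: str | Path,
    *,
    sample_id: str = "",
    replicate_id: str = "",
    delimiter: str | None = None,
    noise_level: float | None = None,
    max_bad_fraction: float = 0.5,
) -> Spectrum:
    """Read a two-column (mz, intensity) delimited text file or an mzML file.

    The delimiter is sniffed from the first line unless given; a header
    row is detected and skipped.  Rows with non-positive intensity are
    dropped with a logged count.  mzML input (``.mzml`` suffix) is read
    through :mod:`pyteomics` and must contain centroided peaks; spectra
    flagged as multiply charged are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return _read_mzml(path, sample_id=sample_id, replicate_id=replicate_id,
                          noise_level=noise_level)
    try:
        text = path.read_text()
    except OSError as exc:
        raise PeakListError(f"cannot read {path}: {exc}") from exc
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PeakListError(f"empty peak list: {path}")
    if delimiter is None:
        first = lines[0]
        for cand in ("\t", ",", ";", " "):
            if cand in first:
                delimiter = cand
                break
        else:
            raise PeakListError(f"cannot detect delimiter in {path}")
    rows: list[tuple[float, float]] = []
    bad = 0
    nonpos = 0
    for i, ln in enumerate(lines):
        parts = [p for p in ln.split(delimiter) if p != ""]
        if len(parts) < 2:
            bad += 1
            continue
        try:
            mz, inten = float(parts[0]), float(parts[1])
        except ValueError:
            if i == 0:
                continue  # header row
            bad += 1
            continue
        if inten <= 0:
            nonpos += 1
            continue
        rows.append((mz, inten))
    if nonpos:
        warnings.warn(f"{path}: dropped {nonpos} rows with non-positive intensity", stacklevel=2)
    if bad > max_bad_fraction * len(lines):
        raise PeakListError(f"{path}: {bad}/{len(lines)} unparseable rows")
    if not rows:
        raise PeakListError(f"{path}: no usable peaks")
    arr = np.array(rows, dtype=float)
    return Spectrum(arr[:, 0], arr[:, 1], sample_id=sample_id,
                    replicate_id=replicate_id, noise_level=noise_level)


def _read_mzml(path: Path, *, sample_id: str, replicate_id: str,
               noise_level: float | None) -> Spectrum:
    from pyteomics import mzml as _mzml  # optional dependency

    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    with _mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("centroid spectrum") is None and "profile spectrum" in entry:
                raise PeakListError(f"{path}: profile-mode spectra are not supported")
            mzs.append(np.asarray(entry["m/z array"], dtype=float))
            intens.append(np.asarray(entry["intensity array"], dtype=float))
    if not mzs:
        raise PeakListError(f"empty mzML file: {path}")
    mz = np.concatenate(mzs)
    inten = np.concatenate(intens)
    keep = inten > 0
    return Spectrum(mz[keep], inten[keep], sample_id=sample_id,
                    replicate_id=replicate_id, noise_level=noise_level)


def write_peaklist(s: Spectrum, path: str | Path, *, delimiter: str = ",") -> None:
    pd.DataFrame({"mz": s.mz, "intensity": s.intensity}).to_csv(
        path, sep=delimiter, index=False, float_format="%.8f")


def estimate_noise_level(s: Spectrum, *, decile: float = 0.1) -> float:
    """Median intensity of the lowest-intensity decile of peaks.

    A stand-in for instrument-supplied noise floors; with a realistic
    excess of low-intensity noise peaks the lowest decile is dominated
    by noise, so its median tracks the noise floor.
    """
    if len(s) == 0:
        raise PeakListError("cannot estimate noise of an empty spectrum")
    k = max(1, int(np.ceil(decile * len(s))))
    lowest = np.partition(s.intensity, k - 1)[:k]
    return float(np.median(lowest))


def mdl_filter(s: Spectrum, mdl_factor: float = 2.5) -> Spectrum:
    """Drop peaks below ``mdl_factor`` times the spectrum noise level.

    The method-detection-limit rule: a peak is kept iff its intensity is
    at least ``mdl_factor * noise_level``.  Idempotent by construction.
    If ``noise_level`` is unset it is estimated with
    :func:`estimate_noise_level`.
    """
    if mdl_factor < 0:
        raise ValueError("mdl_factor must be non-negative")
    noise = s.noise_level if s.noise_level is not None else estimate_noise_level(s)
    keep = s.intensity >= mdl_factor * noise
    if not np.any(keep):
        warnings.warn(f"spectrum {s.key}: all peaks below MDL threshold", stacklevel=2)
    logger.debug("mdl_filter %s: kept %d/%d peaks", s.key, int(keep.sum()), len(s))
    return Spectrum(s.mz[keep], s.intensity[keep], sample_id=s.sample_id,
                    replicate_id=s.replicate_id, noise_level=noise)


def remove_masses(s: Spectrum, exclusion: Iterable[float], tol_ppm: float = 0.5) -> Spectrum:
    """Remove peaks matching a user-supplied contaminant mass list (ppm window)."""
    excl = np.sort(np.asarray(list(exclusion), dtype=float))
    if excl.size == 0:
        return s
    idx = np.searchsorted(excl, s.mz)
    keep = np.ones(len(s), dtype=bool)
    for side in (np.clip(idx - 1, 0, excl.size - 1), np.clip(idx, 0, excl.size - 1)):
        keep &= np.abs(s.mz - excl[side]) > tol_ppm * 1e-6 * s.mz
    logger.debug("remove_masses %s: removed %d peaks", s.key, int((~keep).sum()))
    return Spectrum(s.mz[keep], s.intensity[keep], sample_id=s.sample_id,
                    replicate_id=s.replicate_id, noise_level=s.noise_level)


@dataclass
class AlignedPeakTable:
    """Cross-measurement feature matrix after mass alignment.

    ``mz`` holds ascending consensus masses; ``intensities`` is a
    features x columns matrix (0 marks absence); ``columns`` lists the
    (sample_id, replicate_id) key of each column.  After
    :func:`duplicate_consensus` the replicate part of each key is
    ``None`` and columns are per sample.
    """

    mz: np.ndarray
    intensities: np.ndarray
    columns: list[tuple[str, str | None]]
    consensus: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.mz.size, len(self.columns)):
            raise ValueError("intensity matrix shape does not match mz/columns")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensities = self.intensities[order]

    @property
    def n_features(self) -> int:
        return int(self.mz.size)

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.columns:
            seen.setdefault(sid, None)
        return list(seen)

    def replicate_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, rid in self.columns:
            out.setdefault(sid, []).append(rid)  # type: ignore[arg-type]
        return out

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{sid}" if rid is None else f"{sid}/{rid}" for sid, rid in self.columns]
        df = pd.DataFrame(self.intensities, columns=cols)
        df.insert(0, "consensus_mz", self.mz)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def align_spectra(spectra: Sequence[Spectrum], tol_ppm: float = 0.5) -> AlignedPeakTable:
    """Single-linkage mass alignment of peaks across spectra.

    Peaks from all spectra are pooled and sorted; a gap larger than
    ``tol_ppm`` (relative to the left mass) starts a new feature.  The
    consensus mass of a feature is the intensity-weighted mean of its
    member masses.  When one spectrum contributes several peaks to a
    feature, the most intense wins (logged).
    """
    if not spectra:
        raise ValueError("no spectra to align")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    keys = [s.key for s in spectra]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (sample_id, replicate_id) keys among spectra")
    mz = np.concatenate([s.mz for s in spectra])
    inten = np.concatenate([s.intensity for s in spectra])
    col = np.concatenate([np.full(len(s), i, dtype=int) for i, s in enumerate(spectra)])
    order = np.argsort(mz, kind="stable")
    mz, inten, col = mz[order], inten[order], col[order]

    # chain rule: gap > tol relative to the left member starts a feature
    if mz.size == 0:
        raise ValueError("all spectra are empty")
    new_feature = np.empty(mz.size, dtype=bool)
    new_feature[0] = True
    new_feature[1:] = np.diff(mz) > tol_ppm * 1e-6 * mz[:-1]
    feat = np.cumsum(new_feature) - 1
    n_feat = int(feat[-1]) + 1

    matrix = np.zeros((n_feat, len(spectra)), dtype=float)
    collisions = 0
    # most-intense-wins within (feature, spectrum)
    for f_id, c_id, iv in zip(feat, col, inten):
        if matrix[f_id, c_id] > 0:
            collisions += 1
            if iv <= matrix[f_id, c_id]:
                continue
        matrix[f_id, c_id] = iv
    if collisions:
        logger.info("align_spectra: %d within-spectrum collisions resolved by intensity", collisions)

    wsum = np.bincount(feat, weights=mz * inten, minlength=n_feat)
    wtot = np.bincount(feat, weights=inten, minlength=n_feat)
    consensus_mz = wsum / wtot
    return AlignedPeakTable(consensus_mz, matrix, [(s.sample_id, s.replicate_id) for s in spectra])


def duplicate_consensus(
    t: AlignedPeakTable,
    replicate_map: Mapping[str, Sequence[str]] | None = None,
    *,
    allow_single_replicate: bool = False,
) -> AlignedPeakTable:
    """Keep, per sample, only features detected in every replicate.

    Sample-level intensity is the mean over that sample's replicates.
    Features detected in no sample after the rule are dropped from the
    table entirely.
    """
    if t.consensus:
        return t
    rmap = dict(replicate_map) if replicate_map is not None else t.replicate_map()
    col_index = {key: i for i, key in enumerate(t.columns)}
    samples = list(rmap)
    out = np.zeros((t.n_features, len(samples)), dtype=float)
    for j, sid in enumerate(samples):
        reps = list(rmap[sid])
        if len(reps) < 2 and not allow_single_replicate:
            raise ValueError(f"sample {sid!r} has fewer than 2 replicates; "
                             "pass allow_single_replicate=True to keep it")
        try:
            idx = [col_index[(sid, rid)] for rid in reps]
        except KeyError as exc:
            raise ValueError(f"replicate map entry missing from table: {exc}") from exc
        sub = t.intensities[:, idx]
        present = np.all(sub > 0, axis=1)
        out[present, j] = sub[present].mean(axis=1)
    row_keep = np.any(out > 0, axis=1)
    dropped = int((~row_keep).sum())
    if dropped:
        logger.info("duplicate_consensus: dropped %d features absent from every replicate pair",
                    dropped)
    return AlignedPeakTable(t.mz[row_keep], out[row_keep],
                            [(sid, None) for sid in samples], consensus=True)
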