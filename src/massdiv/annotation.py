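"""Formula-to-isomer annotation with bioactivity summaries.

Exact-mass spectrometry cannot distinguish structural isomers, so the
last step of the workflow maps each assigned molecular formula to the
most common isomers reported for it, with their molecule types,
bioactivities and literature references.  Two backends exist:

* an offline fixture database packaged with the distribution (curated
  formula -> ranked isomer records); this is the default and the only
  backend exercised by the test suite;
* optional live REST queries against PubChem (PUG-REST ``fastformula``
  search) and MetaboLights, enabled only by an explicit ``online``
  flag.  The HTTP transport is injectable so the live code paths are
  fully testable offline with recorded responses.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Callable, Iterable, Sequence

from pydantic import BaseModel, Field, ValidationError, field_validator

from .formulas import MolecularFormula, hill_string, parse_formula

__all__ = [
    "IsomerRecord",
    "AnnotationReport",
    "IsomerDB",
    "AnnotationError",
    "OfflineError",
    "BackendUnavailableError",
    "MalformedResponseError",
    "load_fixture_db",
    "default_fixture_path",
    "annotate_formula",
    "rank_isomers",
    "query_live",
]

_FIXTURE_NAME = "isomer_db.json"


class AnnotationError(Exception):
    """Base class for annotation failures."""


class OfflineError(AnnotationError):
    """A live backend was requested without the explicit online flag."""


class BackendUnavailableError(AnnotationError):
    """The live backend failed (network error or non-200 status)."""


class MalformedResponseError(AnnotationError):
    """The live backend returned an unparseable payload."""


@dataclass(frozen=True)
class IsomerRecord:
    formula: MolecularFormula
    name: str
    molecule_type: str = ""
    bioactivities: tuple[str, ...] = ()
    references: tuple[str, ...] = ()
    rank: int = 1
    backend: str = "fixture"
    annotation_count: int | None = None
    identifier: str | None = None


@dataclass(frozen=True)
class AnnotationReport:
    query: MolecularFormula
    records: tuple[IsomerRecord, ...]
    backend: str
    retrieved_at: str | None = None   # None for the timeless offline fixture

    @property
    def top_isomer(self) -> str | None:
        return self.records[0].name if self.records else None

    def to_dict(self) -> dict:
        return {
            "formula": hill_string(self.query),
            "backend": self.backend,
            "retrieved_at": self.retrieved_at,
            "isomers": [
                {
                    "rank": r.rank,
                    "name": r.name,
                    "molecule_type": r.molecule_type,
                    "bioactivities": list(r.bioactivities),
                    "references": list(r.references),
                }
                for r in self.records
            ],
        }

    def to_markdown(self) -> str:
        lines = [f"# Isomer report for {hill_string(self.query)}",
                 f"*backend: {self.backend}*", ""]
        if not self.records:
            lines.append("No isomer records found.")
        for r in self.records:
            lines.append(f"## {r.rank}. {r.name}" + (f" ({r.molecule_type})" if r.molecule_type else ""))
            for b in r.bioactivities:
                lines.append(f"- {b}")
            if r.references:
                lines.append(f"- References: {', '.join(r.references)}")
            lines.append("")
        return "\n".join(lines)


# ---------------------------------------------------------------- fixture DB

class _SourceModel(BaseModel):
    species_context: str
    solvent_contexts: list[str] = Field(default_factory=list)


class _IsomerModel(BaseModel):
    name: str
    molecule_type: str = ""
    bioactivities: list[str] = Field(default_factory=list)
    references: list[str] = Field(default_factory=list)

    @field_validator("name")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("isomer name must be non-empty")
        return v


class _EntryModel(BaseModel):
    formula: str
    sources: list[_SourceModel] = Field(default_factory=list)
    isomers: list[_IsomerModel]


@dataclass
class IsomerDB:
    """In-memory isomer index keyed by canonical Hill formula string."""

    entries: dict[str, list[IsomerRecord]]
    sources: dict[str, list[dict]] = field(default_factory=dict)
    path: str | None = None

    def __contains__(self, key: str | MolecularFormula) -> bool:
        return self._key(key) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def _key(key: str | MolecularFormula) -> str:
        if isinstance(key, MolecularFormula):
            return hill_string(key)
        return hill_string(parse_formula(key))

    def get(self, key: str | MolecularFormula) -> list[IsomerRecord]:
        return list(self.entries.get(self._key(key), []))

    @property
    def formulas(self) -> list[str]:
        return sorted(self.entries)


def default_fixture_path() -> Path:
    return Path(__file__).parent / "data" / _FIXTURE_NAME


def load_fixture_db(path: str | Path | None = None) -> IsomerDB:
    """Load and validate a fixture isomer database (JSON list of entries).

    Raises :class:`AnnotationError` with the offending record location
    on schema violations or duplicate (formula, name) pairs.  An empty
    list yields an empty database (with a warning).
    """
    import warnings

    path = Path(path) if path is not None else default_fixture_path()
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationError(f"cannot load fixture DB {path}: {exc}") from exc
    if isinstance(raw, dict) and not raw:
        raw = []
    if not isinstance(raw, list):
        raise AnnotationError(f"fixture DB {path}: top level must be a list of entries")
    entries: dict[str, list[IsomerRecord]] = {}
    sources: dict[str, list[dict]] = {}
    for i, item in enumerate(raw):
        try:
            entry = _EntryModel.model_validate(item)
            f = parse_formula(entry.formula)
        except (ValidationError, ValueError) as exc:
            raise AnnotationError(f"fixture DB {path}: invalid entry #{i}: {exc}") from exc
        key = hill_string(f)
        if key in entries:
            raise AnnotationError(f"fixture DB {path}: duplicate formula {key} at entry #{i}")
        recs = []
        seen_names: set[str] = set()
        for rank, iso in enumerate(entry.isomers, start=1):
            if iso.name in seen_names:
                raise AnnotationError(
                    f"fixture DB {path}: duplicate (formula, name) pair ({key}, {iso.name!r})")
            seen_names.add(iso.name)
            recs.append(IsomerRecord(
                formula=f, name=iso.name, molecule_type=iso.molecule_type,
                bioactivities=tuple(iso.bioactivities),
                references=tuple(iso.references), rank=rank, backend="fixture"))
        entries[key] = recs
        sources[key] = [s.model_dump() for s in entry.sources]
    if not entries:
        warnings.warn(f"fixture DB {path} is empty", stacklevel=2)
    return IsomerDB(entries=entries, sources=sources, path=str(path))


def annotate_formula(f: MolecularFormula, db: IsomerDB) -> AnnotationReport:
    """Offline annotation: ranked fixture records for a formula.

    Pure given a fixed database; an absent formula yields an empty
    report rather than an error.
    """
    return AnnotationReport(query=f, records=tuple(db.get(f)), backend="fixture",
                            retrieved_at=None)


def rank_isomers(records: Sequence[IsomerRecord], policy: str = "fixture") -> list[IsomerRecord]:
    """Order isomer records for reporting.

    ``fixture`` preserves the curated rank order; ``live`` sorts by
    descending annotation/literature count with ties broken by
    ascending database identifier (stable).
    """
    if not records:
        return []
    formulas = {hill_string(r.formula) for r in records}
    if len(formulas) > 1:
        raise ValueError(f"records span several formulas: {sorted(formulas)}")
    if policy == "fixture":
        ordered = sorted(records, key=lambda r: r.rank)
    elif policy == "live":
        ordered = sorted(records, key=lambda r: (-(r.annotation_count or 0),
                                                 r.identifier or ""))
    else:
        raise ValueError(f"unknown ranking policy {policy!r}")
    return [IsomerRecord(formula=r.formula, name=r.name, molecule_type=r.molecule_type,
                         bioactivities=r.bioactivities, references=r.references,
                         rank=i + 1, backend=r.backend,
                         annotation_count=r.annotation_count, identifier=r.identifier)
            for i, r in enumerate(ordered)]


# ---------------------------------------------------------------- live REST

Transport = Callable[[str], tuple[int, bytes]]

PUBCHEM_URL = ("https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/fastformula/"
               "{formula}/property/Title/JSON?MaxRecords={max_records}")
METABOLIGHTS_URL = ("https://www.ebi.ac.uk/metabolights/ws/compounds/search/"
                    "{formula}")


def _urllib_transport(url: str) -> tuple[int, bytes]:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover - network
            return resp.status, resp.read()
    except urllib.error.HTTPError as exc:  # pragma: no cover - network
        return exc.code, exc.read() or b""
    except urllib.error.URLError as exc:  # pragma: no cover - network
        raise BackendUnavailableError(f"network failure for {url}: {exc}") from exc


def query_live(
    f: MolecularFormula,
    backend: str = "pubchem",
    *,
    online: bool = False,
    max_records: int = 25,
    transport: Transport | None = None,
) -> list[IsomerRecord]:
    """Query a public compound database for isomers of a formula.

    Requires ``online=True`` (an explicit opt-in) unless a recorded
    ``transport`` is injected.  Network failures and non-200 statuses
    raise :class:`BackendUnavailableError`; unparseable payloads raise
    :class:`MalformedResponseError` with an excerpt — an empty result
    list is only ever a genuine empty result.
    """
    if backend not in ("pubchem", "metabolights"):
        raise ValueError(f"unknown backend {backend!r}")
    if transport is None:
        if not online:
            raise OfflineError("live queries require online=True (offline mode is the default)")
        transport = _urllib_transport
    url = (PUBCHEM_URL if backend == "pubchem" else METABOLIGHTS_URL).format(
        formula=hill_string(f), max_records=max_records)
    status, payload = transport(url)
    if status != 200:
        raise BackendUnavailableError(f"{backend} returned HTTP {status} for {url}")
    try:
        doc = json.loads(payload.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise MalformedResponseError(
            f"{backend} payload unparseable: {payload[:120]!r}") from exc
    try:
        if backend == "pubchem":
            records = _parse_pubchem(f, doc)
        else:
            records = _parse_metabolights(f, doc)
    except (KeyError, TypeError, AttributeError) as exc:
        raise MalformedResponseError(
            f"{backend} payload missing expected fields: {str(doc)[:120]!r}") from exc
    return rank_isomers(records[:max_records], policy="live")


def _parse_pubchem(f: MolecularFormula, doc: dict) -> list[IsomerRecord]:
    props = doc["PropertyTable"]["Properties"]
    out = []
    for p in props:
        out.append(IsomerRecord(
            formula=f, name=str(p["Title"]), backend="pubchem",
            identifier=str(p["CID"]),
            annotation_count=int(p["AnnotationCount"]) if "AnnotationCount" in p else None,
            references=(f"https://pubchem.ncbi.nlm.nih.gov/compound/{p['CID']}",)))
    return out


def _parse_metabolights(f: MolecularFormula, doc: dict) -> list[IsomerRecord]:
    content = doc["content"]
    out = []
    for item in content:
        out.append(IsomerRecord(
            formula=f, name=str(item["name"]), backend="metabolights",
            identifier=str(item.get("id", "")),
            references=(f"https://www.ebi.ac.uk/metabolights/{item.get('id', '')}",)))
    return out
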