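"""Isomer annotation: fixture DB integrity, reports, live-backend replay."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from massdiv.annotation import (
    AnnotationError,
    BackendUnavailableError,
    IsomerRecord,
    MalformedResponseError,
    OfflineError,
    annotate_formula,
    load_fixture_db,
    query_live,
    rank_isomers,
)
from massdiv.formulas import MolecularFormula, parse_formula

FIXDIR = Path(__file__).parent / "fixtures"

# every published isomer-table row: formula -> top isomer(s) in printed order
PUBLISHED_TOP_ISOMERS = {
    # red-alga extract table
    "C18H34O5": ["Pinellic acid", "9,10,13-TriHOME"],
    "C18H32O16": ["Maltotriose", "Dextran"],
    "C10H18N2O3": ["Dethiobiotin"],
    "C8H12N2O2": ["Pyridoxamine"],
    "C7H6O5": ["Gallic acid"],
    "C6H13N3O3": ["Citrulline"],
    "C22H28O11": ["Prim-O-glucosylcimifugin", "4'-O-Glucosyl-5-O-methylvisamminol"],
    "C23H30O11": ["Yadanzioside D"],
    "C6H8O6": ["Ascorbic acid(Vitamin C)"],
    # brown-alga extract table
    "C10H8O5": ["Fraxetin"],
    "C20H34O5": ["Prostaglandin F2alpha", "Alprostadil"],
    "C18H28O3": ["12-Oxo-phytodienoic acid"],
    "C20H34O6": ["Thromboxane B2", "6-Keto-prostaglandin F1alpha"],
    "C20H24O8": ["Vernodalol"],
    "C17H22O4": ["1-Dehydro-[6]-gingerdione"],
    "C14H16O5": ["1'-Acetoxyeugenol acetate"],
    "C12H14O2": ["Precocene I"],
    "C12H14O3": ["Acetyleugenol"],
    "C24H34O10": ["3'-Hydroxy-T2 Toxin"],
    "C19H28O6": ["Tirotundin"],
    "C19H24O3": ["2-Methoxyestrone"],
    "C15H18O4": ["Helenalin", "Parthenin"],
    "C15H16O3": ["Osthole", "Batatasin III"],
    "C15H18O3": ["Santonin", "Irofulven", "Xanthatin"],
    "C17H20O7": ["Dihydroscandenolide", "Yomogiartemin"],
    "C23H34O7": ["Nargenicin A1"],
    "C18H24O5": ["Zearalanone, beta-,alpha-Zearalenol"],
    # shared-polyphenol table
    "C6H6O3": ["Maltol", "Pyrogallol"],
    "C8H8O2": ["Phenylacetic acid"],
    "C6H6O4": ["Kolic acid"],
    "C10H10O4": ["Ferulic acid"],
    "C11H10O4": ["Scoparone"],
    "C12H12O4": ["Hispolon", "Eugenitin"],
    "C14H12O3": ["Resveratrol"],
    "C14H14O4": ["Marmesin"],
}


class TestFixtureDB:
    def test_covers_every_published_row_in_order(self):
        db = load_fixture_db()
        for formula, names in PUBLISHED_TOP_ISOMERS.items():
            recs = db.get(formula)
            assert recs, f"{formula} missing from fixture DB"
            assert [r.name for r in recs] == names
            assert [r.rank for r in recs] == list(range(1, len(names) + 1))

    def test_missing_name_reported_with_location(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text(json.dumps([{"formula": "C6H8O6", "isomers": [{"name": ""}]}]))
        with pytest.raises(AnnotationError, match="entry #0"):
            load_fixture_db(bad)

    def test_duplicate_name_rejected(self, tmp_path):
        bad = tmp_path / "dup.json"
        bad.write_text(json.dumps([{
            "formula": "C6H8O6",
            "isomers": [{"name": "X"}, {"name": "X"}],
        }]))
        with pytest.raises(AnnotationError, match="duplicate"):
            load_fixture_db(bad)

    def test_empty_db_warns(self, tmp_path):
        empty = tmp_path / "empty.json"
        empty.write_text("[]")
        with pytest.warns(UserWarning, match="empty"):
            db = load_fixture_db(empty)
        assert len(db) == 0


class TestAnnotate:
    def test_known_formula_report(self):
        db = load_fixture_db()
        rep = annotate_formula(parse_formula("C20H24O8"), db)
        assert rep.top_isomer == "Vernodalol"
        assert rep.records[0].molecule_type == "Sesquiterpene lactone"

    def test_absent_formula_empty_report(self):
        db = load_fixture_db()
        rep = annotate_formula(MolecularFormula(99, 2, o=1), db)
        assert rep.records == ()
        assert rep.top_isomer is None

    def test_pure_given_fixed_db(self):
        db = load_fixture_db()
        f = parse_formula("C10H8O5")
        assert annotate_formula(f, db) == annotate_formula(f, db)

    def test_markdown_report_mentions_references(self):
        db = load_fixture_db()
        text = annotate_formula(parse_formula("C14H12O3"), db).to_markdown()
        assert "Resveratrol" in text and "B86" in text


class TestRankIsomers:
    def test_fixture_policy_preserves_order(self):
        db = load_fixture_db()
        recs = db.get("C18H32O16")
        assert [r.name for r in rank_isomers(recs, "fixture")] == ["Maltotriose", "Dextran"]

    def test_live_policy_sorts_by_count_then_id(self):
        f = parse_formula("C6H8O6")
        recs = [
            IsomerRecord(formula=f, name="minor", annotation_count=12, identifier="9"),
            IsomerRecord(formula=f, name="major", annotation_count=40, identifier="5"),
            IsomerRecord(formula=f, name="tied", annotation_count=40, identifier="3"),
        ]
        assert [r.name for r in rank_isomers(recs, "live")] == ["tied", "major", "minor"]

    def test_single_record(self):
        db = load_fixture_db()
        recs = db.get("C7H6O5")
        assert rank_isomers(recs) == recs

    def test_mixed_formula_input_rejected(self):
        recs = [IsomerRecord(formula=parse_formula("C6H8O6"), name="a"),
                IsomerRecord(formula=parse_formula("C7H6O5"), name="b")]
        with pytest.raises(ValueError, match="several formulas"):
            rank_isomers(recs)


class TestLiveReplay:
    """Live backend code paths exercised offline via recorded responses."""

    def test_pubchem_recorded_success(self):
        payload = (FIXDIR / "pubchem_C6H8O6.json").read_bytes()
        recs = query_live(parse_formula("C6H8O6"), "pubchem",
                          transport=lambda url: (200, payload))
        assert any("scorbic" in r.name for r in recs)
        assert all(r.backend == "pubchem" for r in recs)

    def test_metabolights_recorded_success(self):
        payload = (FIXDIR / "metabolights_C6H8O6.json").read_bytes()
        recs = query_live(parse_formula("C6H8O6"), "metabolights",
                          transport=lambda url: (200, payload))
        assert any("ascorbic" in r.name for r in recs)

    def test_offline_by_default(self):
        with pytest.raises(OfflineError):
            query_live(parse_formula("C6H8O6"), "pubchem")

    def test_http_500_is_typed_error(self):
        with pytest.raises(BackendUnavailableError, match="HTTP 500"):
            query_live(parse_formula("C6H8O6"), "pubchem",
                       transport=lambda url: (500, b"server error"))

    def test_malformed_payload_is_typed_error(self):
        with pytest.raises(MalformedResponseError):
            query_live(parse_formula("C6H8O6"), "pubchem",
                       transport=lambda url: (200, b"<html>not json</html>"))

    def test_valid_json_missing_fields_is_typed_error(self):
        with pytest.raises(MalformedResponseError):
            query_live(parse_formula("C6H8O6"), "pubchem",
                       transport=lambda url: (200, b'{"unexpected": 1}'))
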