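"""Formula-to-isomer annotation from the packaged fixture database.

Exact-mass MS cannot tell isomers apart, so each formula maps to a
ranked list of plausible structures with bioactivities and references.
The offline fixture is the default; live PubChem/MetaboLights queries
require an explicit online flag (shown here with a canned transport).
"""

import json
from pathlib import Path

from massdiv import annotate_formula, load_fixture_db, parse_formula, query_live

db = load_fixture_db()
print(f"fixture database: {len(db)} formulas")

for text in ("C6H8O6", "C18H32O16", "C15H18O3"):
    rep = annotate_formula(parse_formula(text), db)
    names = ", ".join(f"{r.rank}. {r.name}" for r in rep.records)
    print(f"{text:>10} -> {names}")

# the live code path, replayed from a recorded PubChem response:
recorded = Path(__file__).parent.parent / "tests" / "fixtures" / "pubchem_C6H8O6.json"
records = query_live(parse_formula("C6H8O6"), "pubchem",
                     transport=lambda url: (200, recorded.read_bytes()))
print("PubChem replay:", [r.name for r in records])
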