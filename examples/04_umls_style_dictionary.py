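"""Read a UMLS-style KB from pipe-delimited MRCONSO/MRSTY files.

MRCONSO.RRF carries one synonym string per row (CUI in field 1, language in
field 2, string in field 15); MRSTY.RRF carries semantic types (type name in
field 4).  The readers keep one language, lowercase strings, collapse
duplicates, and join multiple semantic types in first-seen order.
"""

import tempfile
from pathlib import Path

from protolink import build_synonym_index
from protolink.kb import entities_from_umls, read_mrconso, read_mrsty

MRCONSO = """\
C0004057|ENG|P|L0004057|PF|S0016718|Y|A0062237||M0001335|D001241|MSH|MH|D001241|Aspirin|0|N||
C0004057|ENG|S|L0004058|PF|S0016719|Y|A0062238||M0001335|D001241|MSH|EN|D001241|Acetylsalicylic Acid|0|N||
C0004057|FRE|P|L0162299|PF|S0226654|Y|A0063241||M0001335|D001241|MSHFRE|MH|D001241|Aspirine|3|N||
C0027051|ENG|P|L0027051|PF|S0064491|Y|A0086385||M0014340|D009203|MSH|MH|D009203|Myocardial Infarction|0|N||
C0027051|ENG|S|L0379543|PF|S0469877|Y|A0446091||M0014340|D009203|MSH|EN|D009203|Heart Attack|0|N||
"""

MRSTY = """\
C0004057|T109|A1.4.1.2.1|Organic Chemical|AT17575038|256|
C0004057|T121|A1.4.1.1.1|Pharmacologic Substance|AT17634323|256|
C0027051|T047|B2.2.1.2.1|Disease or Syndrome|AT17683839|3840|
"""

with tempfile.TemporaryDirectory() as tmp:
    conso_path = Path(tmp) / "MRCONSO.RRF"
    sty_path = Path(tmp) / "MRSTY.RRF"
    conso_path.write_text(MRCONSO)
    sty_path.write_text(MRSTY)

    pairs = read_mrconso(conso_path, language_filter="ENG")
    types = read_mrsty(sty_path)
    entities = entities_from_umls(pairs, types)

index = build_synonym_index(entities)
print(f"{len(pairs)} English (CUI, synonym) pairs -> {len(entities)} entities")
for e in sorted(entities, key=lambda e: e.entity_id):
    print(f"  {e.entity_id}: type={e.semantic_type!r} synonyms={e.synonyms}")
print(f"dictionary keys: {index.synonyms}")
# Note the French row was filtered out and C0004057 carries both of its
# semantic types joined in first-seen order, ready for the entity template.
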