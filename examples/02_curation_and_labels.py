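"""Activity labeling and curation rules on a handful of raw records.

Measurements are pooled per compound-target pair and labeled active
(any value <= 10 uM), inactive (all values >= 100 uM) or gray-zone;
compounds outside 5-80 heavy atoms or from unsupported assays are filtered.
"""

from revscreen.data import (ActivityRecord, BioactivitySet, CompoundRecord,
                            classify_activity, filter_compounds,
                            standardize_structure)

print("standardization:")
for raw in ("CC(=O)[O-].[Na+]", "CCO.O", "c1ccccc1"):
    print(f"  {raw!r:28} -> {standardize_structure(raw)!r}")

print("\nlabels from measurement sets (values in uM):")
for values in ([5.0], [150.0], [50.0], [500.0, 2.0]):
    records = [ActivityRecord("c", "T", "Ki", v) for v in values]
    print(f"  {values!r:16} -> {classify_activity(records)}")

compounds = {
    "ok": CompoundRecord("ok", "CCCCCO", 6),
    "tiny": CompoundRecord("tiny", "CCCC", 4),
}
records = [ActivityRecord("ok", "T1", "Ki", 1.0),
           ActivityRecord("tiny", "T1", "Ki", 1.0),
           ActivityRecord("ok", "T2", "Ki", 0.5, species="dog")]
filtered, removed = filter_compounds(BioactivitySet.from_records(compounds, records))
print(f"\nfilter removed per criterion: {removed}")
print(f"surviving records: {len(filtered.records)} "
      "(the 4-heavy-atom compound and the non-rodent assay are dropped)")
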