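"""Scan the reference panel: motifs, regions, substitution profile, predictions.

The synthetic panel mirrors the documented family structure: the basic
subunit (His-11, four Cys including the inter-subunit 77/109 pair, three
degenerate mannose-binding windows), the acidic subunit (26 of 114 mature
positions changed, Tyr-11, receptor set intact), and the lectin-like type
(three intact windows, no dimer cysteines). The prediction table derives the
dimerization / lectin / taste flags from exactly those states.
"""

from curculigo import (
    ReferencePanel,
    derive_regions,
    functional_prediction,
    reference_panel,
    scan_mbs_motifs,
    substitution_profile,
)
from curculigo.neoculin import predictions_table, profile_heatmap_table

records = reference_panel()
panel = ReferencePanel.from_records(records)

print("mannose-binding-site windows (QxDxNxVxY consensus):")
for rid, record in records.items():
    hits = [(h.start, h.conserved_matches, "intact" if h.intact else "degenerate")
            for h in scan_mbs_motifs(record)]
    print(f"  {rid}: {hits}")

partition = derive_regions(panel.nbs)
print("\nnine-region partition of the basic subunit (start-end):")
print("  " + ", ".join(f"{r.name} {r.start}-{r.end}" for r in partition.regions if r.length))

profiles = [
    substitution_profile(records[rid], panel.nbs, panel.nas, partition, panel.c9931)
    for rid in ("NAS", "C9931")
]
print("\nper-region substitution rates (%) against the basic subunit:")
print(profile_heatmap_table(profiles).to_string())
print(
    f"\nacidic vs basic subunit overall: {profiles[0].overall_substitutions} of "
    f"{profiles[0].overall_length} mature residues ({profiles[0].overall_rate:.0f}%)"
)

preds = [functional_prediction(rec, panel) for rec in records.values()]
print("\nfunctional predictions (flag(count) per column):")
print(predictions_table(preds).to_string(index=False))
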