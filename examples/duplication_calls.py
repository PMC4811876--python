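"""Tandem and segmental duplication calls on the curated grapevine table.

Tandem arrays chain same-subfamily loci within 250 kb on one chromosome;
segmental calls need a paralogous-segment map, so this example builds a
small illustrative map around the GRASV1 loci on chromosomes 1, 14 and 17.
"""

from grasfam import grapevine_gras_table, segmental_pairs, tandem_arrays
from grasfam.family_model import ParalogousSegmentMap, subfamily_from_short_name

table = grapevine_gras_table()
labels = {
    l.locus_id: subfamily_from_short_name(l.short_name)
    for l in table
    if subfamily_from_short_name(l.short_name)
}

print("tandem arrays (250 kb chain rule):")
for call in tandem_arrays(table, labels):
    print(f"  {call.evidence}: {len(call.members)} members")


def around(locus_id, pad=10_000):
    locus = table.get(locus_id)
    return (locus.chromosome, locus.span[0] - pad, locus.span[1] + pad)


# illustrative-only map: the three paralogous GRASV1 regions
seg_map = ParalogousSegmentMap(pairs=[
    (around("Vitvi01g01509"), around("Vitvi14g01510")),
    (around("Vitvi01g01509"), around("Vitvi17g01040")),
    (around("Vitvi14g01510"), around("Vitvi17g01040")),
])
print("segmental calls in the illustrative GRASV1 map:")
for call in segmental_pairs(table, labels, seg_map):
    print(f"  {call.members[0]} ~ {call.members[1]}")
# The LISCL clusters on chr6 and chr13 dominate the tandem calls; the GRASV1
# trio sits in paralogous regions from ancestral polyploidization.
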