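"""Codon indels and COI secondary structure.

Plants a one-codon insertion at alignment site 37 in three species from
two families and a one-codon deletion at site 36 in another species —
the hotspot configuration reported for marine bivalves — then detects
the events by translation-guided alignment and maps them onto the COI
membrane topology.
"""

from barcodekit import (
    PlantedIndel,
    SequenceRecord,
    SimConfig,
    codon_align,
    detect_indels,
    hotspot_summary,
    map_to_structure,
    pseudogene_screen,
    simulate_dataset,
)
from barcodekit.indels import events_to_frame

ds = simulate_dataset(
    SimConfig(
        n_species=10,
        seed=9,
        planted_indels=(
            PlantedIndel(37, 1, "insertion", 1),  # Family01
            PlantedIndel(37, 1, "insertion", 5),  # Family02
            PlantedIndel(37, 3, "insertion", 8),  # Family03, three codons
            PlantedIndel(36, 1, "deletion", 3),
        ),
    )
)
reference = SequenceRecord("REF", ds.manifest.ancestor_seq)
aln = codon_align(ds.records, reference)
events = map_to_structure(detect_indels(aln, ds.meta))

print(events_to_frame(events).to_string(index=False))
print()
print(hotspot_summary(events).to_string(index=False))
# All events are codon multiples (no frame shift), so none of the
# carriers is flagged as a putative pseudogene; site 37 is a hotspot
# shared across families in the first external loop.
print("\npseudogene flags:", pseudogene_screen(events, aln) or "none")
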