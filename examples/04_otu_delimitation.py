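"""OTU delimitation: 2% threshold clustering vs barcode-gap discovery.

Clusters a synthetic library with both delimiters and compares the
partitions with each other and with the true species assignment. At a
648-bp barcode the 2% threshold corresponds to 13 base-pair differences.
"""

from barcodekit import (
    Partition,
    SimConfig,
    abgd_partition,
    distance_matrix,
    pairdiff_threshold,
    partition_congruence,
    simulate_dataset,
    threshold_cluster,
)

print(f"2% of a 648-bp barcode = {pairdiff_threshold(0.02, 648)} bp differences\n")

ds = simulate_dataset(SimConfig(n_species=15, seed=11))
m = distance_matrix(ds.records)

p_thr = threshold_cluster(m, threshold=0.02)
abgd = abgd_partition(m)  # log-spaced priors from 0.0006 to 0.17
print(abgd.to_frame().to_string(index=False))

truth = Partition({s: hash(sp) for s, sp in ds.manifest.species_of.items()}, "truth")
for name, part in [("threshold 2%", p_thr), ("barcode-gap discovery", abgd.selected)]:
    rep = partition_congruence(part, truth)
    print(f"\n{name}: {part.n_otus} OTUs ({part.n_singletons} singletons), "
          f"agreement with truth = {rep.agreement:.3f}")
# Both delimiters recover the 15 true species exactly (agreement 1.0):
# intraspecific distances stay far below the gap, interspecific far above.
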