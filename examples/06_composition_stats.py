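"""Nucleotide composition and the statistical battery.

Computes per-species GC content, tests base-frequency homogeneity among
species within a class, regresses intraspecific divergence on sample
size, and correlates genus-level GC content with nearest-neighbour
distance — the full set of dataset-level statistics a barcode survey
reports.
"""

from barcodekit import (
    SimConfig,
    distance_matrix,
    genus_summaries,
    simulate_dataset,
    species_summaries,
)
from barcodekit.compstats import (
    composition_homogeneity,
    composition_table,
    divergence_vs_n_regression,
    gc_nn_correlation,
    species_composition,
    success_rate,
)

ds = simulate_dataset(SimConfig(n_species=20, seed=19))
m = distance_matrix(ds.records)
summaries = species_summaries(m, ds.meta)

comp = composition_table(ds.records, ds.meta, rank="species")
print(f"mean GC across {len(comp)} species: {comp.gc_pct.mean():.1f}%")

chi = composition_homogeneity(species_composition(ds.records, ds.meta))
print(f"composition homogeneity: chi2={chi.statistic:.1f} df={chi.df:.0f} p={chi.p_value:.3g}")

reg = divergence_vs_n_regression(summaries, response="mean_intra")
print(f"divergence ~ n: slope={reg.effect['slope']:.4f} "
      f"R2={reg.effect['r_squared']:.3f} p={reg.p_value:.2f}")
# Under the generator there is no true effect of sample size, so the
# regression should be flat and insignificant.

gc_by_species = dict(zip(comp.species, comp.gc_pct))
genera = genus_summaries(summaries, ds.meta, gc_by_species)
try:
    corr = gc_nn_correlation(genera, seed=1)
    print(f"GC vs NN across {int(corr.effect['n_genera'])} genera: "
          f"r={corr.statistic:.2f} p={corr.p_value:.2f}")
except ValueError as exc:
    print(f"GC vs NN correlation not computable here: {exc}")

rate, _ = success_rate(1214, 2352)
print(f"\nsequencing success for 1214 of 2352 specimens: {rate}%")
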