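"""Batch-score a small pathway collection and screen by skewness.

Builds one cohort, defines three overlapping pathways over its genes,
scores all of them, and ranks pathways by the skewness of their score
distributions — right-skew flags pathways where a few individuals are
strongly aberrant against a quiet background.
"""

from padma import (PathwayDefinition, SimConfig, generate_multiomic,
                   rank_by_skewness, run_collection)

ds = generate_multiomic(SimConfig(seed=3))
genes = list(ds.pathway.genes)
drivers = sorted(ds.truth.driver_genes)
pathways = [
    PathwayDefinition("PW_ALL", "all genes", tuple(genes)),
    PathwayDefinition("PW_DRIVERS", "driver genes only", tuple(drivers)),
    PathwayDefinition("PW_QUIET", "non-driver genes",
                      tuple(g for g in genes if g not in drivers)[:4]),
]

table, results, log = run_collection(pathways, ds.omics, ds.mti)
print(table.summary.round(3).to_string(index=False))

top = rank_by_skewness(table, top_fraction=0.5)
print("\ntop pathways by score skewness (heavy right tail = spiked signal):")
print(top.round(3).to_string(index=False))
print("\nPW_DRIVERS concentrates the spiked effect, so its score "
      "distribution is the most right-skewed; PW_QUIET shows none.")
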