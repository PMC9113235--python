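"""Linkage-disequilibrium decay from unphased dosages.

r^2 here is the squared Pearson correlation between per-site dosage vectors
(composite LD), binned by pair distance. The simulator draws sites
independently, so the curve is flat at the background level expected from a
finite sample (E[r^2] ~ 1/n for unlinked loci) — on real data the short-range
bins would start high and decay toward this background.
"""

from islandscan import SimulationConfig, ld_r2_decay, simulate_split_populations

cfg = SimulationConfig(n_populations=1, samples_per_pop=25,
                       contig_length=500_000, seed=11)
geno, sites, _ = simulate_split_populations(cfg)
curve = ld_r2_decay(geno, sites, cfg.population_map().samples("pop1"),
                    max_dist=100_000, n_bins=10)
frame = curve.to_frame().dropna()
print(f"{geno.n_sites} SNPs, {int(frame['n_pairs'].sum())} pairs <= 100 kb")
print(frame.to_string(index=False,
                      formatters={"mean_r2": "{:.4f}".format}))
print(f"\nbackground expectation for unlinked loci, dosage correlation over "
      f"n = {geno.n_samples} individuals: ~1/n = {1 / geno.n_samples:.3f}")
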