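"""Plant selective sweeps (diversity loss in one population) and recover them
with the joint top-5% FST x log2(theta-pi ratio) outlier criterion.

Sweeps erase variation in the target population: its pi collapses inside the
swept windows, so log2(pi_ref/pi_target) blows up while FST rises. A window
must sit in BOTH top-5% tails to be called, which suppresses false positives
from either statistic alone.
"""

from islandscan import (SimulationConfig, scan, simulate_split_populations,
                        sweep_outliers)

sweeps = [("chr1", 200_000, 240_000, "pop2", 1.0),
          ("chr1", 640_000, 680_000, "pop2", 1.0)]
cfg = SimulationConfig(n_populations=2, samples_per_pop=10,
                       contig_length=1_000_000, sweep_intervals=sweeps, seed=3)
geno, sites, truth = simulate_split_populations(cfg)
records = scan(geno, sites, cfg.population_map(), [("pop1", "pop2")],
               contig_lengths={"chr1": cfg.contig_length})

result = sweep_outliers(records, target="pop2", fst_q=0.05, ratio_q=0.05)
print(f"orientation: {result.orientation}")
print(f"cutoffs: FST >= {result.fst_cutoff:.3f}, "
      f"log2 ratio >= {result.ratio_cutoff:.3f}")
print(f"{len(result.windows)} joint outlier windows:")
print(result.windows[["contig", "start", "end", "fst_weighted", "pi_a",
                      "pi_b", "pi_ratio_log2"]].to_string(index=False))

hit = sum(any(w[0] == t[0] and w[1] < t[2] and t[1] < w[2]
              for w in result.window_set) for t in truth.sweep_windows)
print(f"\nplanted sweeps overlapped by an outlier window: "
      f"{hit}/{len(truth.sweep_windows)}")
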