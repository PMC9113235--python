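"""Synthetic resequencing data with the structure a divergence scan assumes.

The generator produces dosage genotypes for 1-3 populations that diverged by
drift from a common ancestral gene pool, with optional symmetric migration,
planted high-divergence windows ("islands"), planted low-diversity sweep
windows, and an optional binary trait driven by one causal SNP.

Engine: per-site forward allele-frequency diffusion. Ancestral standing
variation is drawn from the neutral frequency spectrum (density proportional
to 1/x), which reproduces Watterson's expectation E[S] = 4*Ne*mu*L*a_n for a
sample of n allele copies; each daughter population's frequencies then drift
by binomial resampling (time-compressed into at most ``max_drift_steps``
diffusion-equivalent steps) with infinite-sites mutation input, and dosages
are finally drawn per individual as Binomial(ploidy, p). Islands are planted
as divergent directional frequency shifts, sweeps as removal of minor-allele
copies from the sampled genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, ConfigurationError, GenotypeMatrix, PopulationMap, make_site_table

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_split_populations",
    "plant_sweep",
    "simulate_trait",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the split-population simulation.

    ``split_times`` are in generations before present, oldest first; split i
    separates population ``n_populations - 1 - i`` from the remaining group.
    ``generation_time`` (years) is carried as metadata only. Interval tuples
    are ``(contig, start, end, populations, intensity)`` with 0-based
    half-open coordinates; ``causal_snp`` is ``(contig, pos_1based, effect)``.
    """

    n_populations: int = 2
    samples_per_pop: int = 20
    ploidy_per_pop: list | None = None
    effective_size: int | list = 10_000
    split_times: list | None = None
    migration_rate: float = 0.0
    mutation_rate: float = 5.4e-9
    generation_time: float = 6.0
    n_contigs: int = 1
    contig_length: int = 1_000_000
    island_intervals: list = field(default_factory=list)
    sweep_intervals: list = field(default_factory=list)
    causal_snp: tuple | None = None
    seed: int = 0
    pop_names: list | None = None
    mean_depth: float = 7.7
    max_drift_steps: int = 64

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ConfigurationError("n_populations must be >= 1")
        if self.samples_per_pop < 1:
            raise ConfigurationError("samples_per_pop must be >= 1")
        if self.ploidy_per_pop is None:
            self.ploidy_per_pop = [2] * self.n_populations
        if len(self.ploidy_per_pop) != self.n_populations:
            raise ConfigurationError("ploidy_per_pop needs one entry per population")
        if any(p < 1 for p in self.ploidy_per_pop):
            raise ConfigurationError("ploidy_per_pop entries must be >= 1")
        if np.isscalar(self.effective_size):
            self.effective_size = [int(self.effective_size)] * self.n_populations
        if len(self.effective_size) != self.n_populations:
            raise ConfigurationError("effective_size needs one entry per population")
        if any(ne <= 0 for ne in self.effective_size):
            raise ConfigurationError("effective_size must be strictly positive")
        if self.split_times is None:
            self.split_times = [2000 * i for i in range(self.n_populations - 1, 0, -1)]
        if len(self.split_times) != self.n_populations - 1:
            raise ConfigurationError("split_times needs n_populations - 1 entries")
        if any(t < 0 for t in self.split_times):
            raise ConfigurationError("split_times must be non-negative")
        if sorted(self.split_times, reverse=True) != list(self.split_times):
            raise ConfigurationError("split_times must be ordered oldest first")
        if not (0.0 <= self.migration_rate <= 1.0):
            raise ConfigurationError("migration_rate must lie in [0, 1]")
        if self.mutation_rate <= 0:
            raise ConfigurationError("mutation_rate must be strictly positive")
        if self.generation_time <= 0:
            raise ConfigurationError("generation_time must be strictly positive")
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ConfigurationError("n_contigs and contig_length must be >= 1")
        if self.pop_names is None:
            self.pop_names = [f"pop{i + 1}" for i in range(self.n_populations)]
        if len(self.pop_names) != self.n_populations:
            raise ConfigurationError("pop_names needs one entry per population")
        contigs = set(self.contig_names())
        for label, ivs in (("island_intervals", self.island_intervals),
                           ("sweep_intervals", self.sweep_intervals)):
            for iv in ivs:
                contig, start, end = iv[0], int(iv[1]), int(iv[2])
                if contig not in contigs:
                    raise ConfigurationError(f"{label}: unknown contig {contig!r}")
                if not (0 <= start < end <= self.contig_length):
                    raise ConfigurationError(f"{label}: interval out of contig bounds")
        if self.causal_snp is not None:
            contig, pos = self.causal_snp[0], int(self.causal_snp[1])
            if contig not in contigs:
                raise ConfigurationError("causal_snp: unknown contig")
            if not (1 <= pos <= self.contig_length):
                raise ConfigurationError("causal_snp: position out of contig bounds")

    def contig_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]

    def population_map(self) -> PopulationMap:
        assign = {}
        for k, name in enumerate(self.pop_names):
            for j in range(self.samples_per_pop):
                assign[f"{name}_s{j + 1:02d}"] = name
        return PopulationMap(assign)


@dataclass
class SimTruth:
    """Planted intervals (0-based half-open, sorted) and the causal SNP."""

    island_windows: list = field(default_factory=list)
    sweep_windows: list = field(default_factory=list)
    causal_snp: tuple | None = None

    def __post_init__(self) -> None:
        self.island_windows = sorted(
            (c, int(s), int(e)) for c, s, e in self.island_windows)
        self.sweep_windows = sorted(
            (c, int(s), int(e)) for c, s, e in self.sweep_windows)
        for c, s, e in self.island_windows + self.sweep_windows:
            if s < 0 or s >= e:
                raise ValueError("truth intervals must be non-negative half-open")


def _drift_epoch(rng, freqs, group_sizes, duration, cfg):
    """Binomial drift of per-group frequencies for ``duration`` generations.

    ``freqs`` is (n_groups, S); the (possibly widened) array is returned. New
    mutations arising during the epoch enter at frequency 1/(2Ne) at a random
    step. Time is compressed into at most cfg.max_drift_steps steps; a step
    of c generations uses a binomial denominator of round(2*Ne/c), which
    preserves the per-generation diffusion variance p(1-p)/(2Ne).
    """
    if duration <= 0:
        return freqs
    n_steps = int(min(duration, cfg.max_drift_steps))
    c = duration / n_steps
    n_groups = freqs.shape[0]
    denom = [max(2, round(2 * ne / c)) for ne in group_sizes]
    # New-mutation influx per chunk step. The equilibrium frequency spectrum
    # of a Wright-Fisher chain is f(x) = 2I/x with I the per-step influx,
    # independent of the chain size, so matching the target 4*Ne*mu*L/x
    # requires I = 2*Ne*mu*L per step with entry frequency 1/denominator
    # (the time-compressed chain cannot represent rarer classes).
    theta_step = [2 * ne * cfg.mutation_rate * cfg.contig_length
                  for ne in group_sizes]
    n_new = [rng.poisson(th * n_steps) for th in theta_step]
    total_new = int(sum(n_new))
    new_freqs = np.zeros((n_groups, total_new))
    birth_step = np.empty(total_new, dtype=np.int64)
    birth_group = np.empty(total_new, dtype=np.int64)
    off = 0
    for g, k in enumerate(n_new):
        birth_step[off:off + k] = rng.integers(0, n_steps, size=k)
        birth_group[off:off + k] = g
        off += k
    freqs = np.concatenate([freqs, new_freqs], axis=1)
    base = freqs.shape[1] - total_new
    m_step = min(1.0, cfg.migration_rate * c)
    for step in range(n_steps):
        born = np.nonzero(birth_step == step)[0]
        for idx in born:
            g = birth_group[idx]
            freqs[g, base + idx] = 1.0 / denom[g]
        for g in range(n_groups):
            freqs[g] = rng.binomial(denom[g], freqs[g]) / denom[g]
        if m_step > 0 and n_groups > 1:
            pool = freqs.mean(axis=0)
            freqs += m_step * (pool[None, :] - freqs)
    return freqs


def _simulate_contig(rng, cfg: SimulationConfig, contig: str):
    """Per-population allele frequencies and positions for one contig."""
    n_pops = cfg.n_populations
    ne_anc = int(round(float(np.mean(cfg.effective_size))))
    theta_l = 4 * ne_anc * cfg.mutation_rate * cfg.contig_length
    lo = 1.0 / (2 * ne_anc)
    log_span = math.log((1 - lo) / lo)
    n_standing = rng.poisson(theta_l * log_span)
    p_anc = lo * np.exp(rng.random(n_standing) * log_span)

    # groups of populations that still share a gene pool; oldest split first
    freqs = p_anc[None, :].copy()
    group_members = [list(range(n_pops))]
    group_sizes = [ne_anc]
    boundaries = list(cfg.split_times) + [0]
    t_prev = boundaries[0] if boundaries else 0
    for i, t in enumerate(boundaries):
        if i > 0:
            freqs = _drift_epoch(rng, freqs, group_sizes, t_prev - t, cfg)
            t_prev = t
        if i < len(cfg.split_times):
            # split the highest-index population off the first (root) group
            donor = 0
            leaving = max(group_members[donor])
            group_members[donor] = [p for p in group_members[donor] if p != leaving]
            group_members.append([leaving])
            freqs = np.concatenate([freqs, freqs[donor:donor + 1].copy()], axis=0)
            group_sizes = [
                ne_anc if len(m) > 1 else cfg.effective_size[m[0]]
                for m in group_members
            ]
    # expand groups to per-population rows
    pop_freqs = np.empty((n_pops, freqs.shape[1]))
    for g, members in enumerate(group_members):
        for p in members:
            pop_freqs[p] = freqs[g]

    # unique 1-based positions, randomly paired with sites, then co-sorted
    n_sites = min(pop_freqs.shape[1], cfg.contig_length)
    pop_freqs = pop_freqs[:, :n_sites]
    pos = rng.choice(cfg.contig_length, size=n_sites, replace=False) + 1
    order = np.argsort(pos)
    pos = pos[order]
    pop_freqs = pop_freqs[:, order]

    # plant islands: divergent directional shifts inside the interval
    pop_index = {name: k for k, name in enumerate(cfg.pop_names)}
    for iv in cfg.island_intervals:
        c, start, end, targets, intensity = iv
        if c != contig:
            continue
        if not 0 < intensity <= 1:
            raise ConfigurationError("island intensity must lie in (0, 1]")
        tidx = [pop_index[t] for t in targets]
        # shift only sites already polymorphic in the target populations, so
        # the island changes divergence rather than SNP density
        pooled = pop_freqs[tidx].mean(axis=0)
        in_iv = ((pos - 1 >= start) & (pos - 1 < end)
                 & (pooled > 0) & (pooled < 1))
        up = tidx[0]
        pop_freqs[up, in_iv] += intensity * (1 - pop_freqs[up, in_iv])
        for down in tidx[1:]:
            pop_freqs[down, in_iv] *= (1 - intensity)

    # force a site at the causal position with intermediate frequency
    if cfg.causal_snp is not None and cfg.causal_snp[0] == contig:
        cpos = int(cfg.causal_snp[1])
        if cpos not in set(pos.tolist()):
            insert_at = int(np.searchsorted(pos, cpos))
            pos = np.insert(pos, insert_at, cpos)
            pop_freqs = np.insert(pop_freqs, insert_at, 0.5, axis=1)
        else:
            pop_freqs[:, pos == cpos] = 0.5
    return pop_freqs, pos


def simulate_split_populations(config: SimulationConfig):
    """Simulate genotypes, site metadata and truth annotations.

    Returns
    -------
    (GenotypeMatrix, SiteTable, SimTruth)
        Dosage genotypes for all samples, per-site records with synthetic
        depth/MQ fields, and the planted-truth annotations.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    contig_seeds = root.spawn(cfg.n_contigs + 1)
    rng_global = np.random.default_rng(contig_seeds[-1])

    popmap = cfg.population_map()
    sample_ids = list(popmap.assignments)
    ploidy = np.array([
        cfg.ploidy_per_pop[cfg.pop_names.index(popmap.assignments[s])]
        for s in sample_ids
    ])
    pop_of_sample = np.array([
        cfg.pop_names.index(popmap.assignments[s]) for s in sample_ids
    ])

    all_dos, all_contig, all_pos = [], [], []
    for ci, contig in enumerate(cfg.contig_names()):
        rng = np.random.default_rng(contig_seeds[ci])
        pop_freqs, pos = _simulate_contig(rng, cfg, contig)
        n_sites = pos.size
        dos = np.empty((len(sample_ids), n_sites), dtype=np.int16)
        for si in range(len(sample_ids)):
            p = pop_freqs[pop_of_sample[si]]
            dos[si] = rng.binomial(int(ploidy[si]), p)
        # keep sites segregating in the pooled sample (protect the causal site)
        tot = dos.sum(axis=0)
        seg = (tot > 0) & (tot < int(ploidy.sum()))
        if cfg.causal_snp is not None and cfg.causal_snp[0] == contig:
            seg |= pos == int(cfg.causal_snp[1])
        all_dos.append(dos[:, seg])
        all_pos.append(pos[seg])
        all_contig.extend([contig] * int(seg.sum()))

    dosages = np.concatenate(all_dos, axis=1)
    pos = np.concatenate(all_pos)
    n_sites = pos.size
    ref_idx = rng_global.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng_global.integers(1, 4, size=n_sites)) % 4
    depth = rng_global.poisson(cfg.mean_depth, size=n_sites).astype(float)
    mq = np.full(n_sites, 60.0)
    noisy = rng_global.random(n_sites) < 0.02
    mq[noisy] = rng_global.uniform(10, 59, size=int(noisy.sum()))

    sites = make_site_table(all_contig, pos, _BASES[ref_idx], _BASES[alt_idx],
                            depth, mq)
    geno = GenotypeMatrix(dosages, sample_ids, ploidy)

    for iv in cfg.sweep_intervals:
        c, start, end, target, intensity = iv
        geno = plant_sweep(geno, sites, (c, start, end), popmap, target, intensity)

    truth = SimTruth(
        island_windows=[(c, s, e) for c, s, e, *_ in cfg.island_intervals],
        sweep_windows=[(c, s, e) for c, s, e, *_ in cfg.sweep_intervals],
        causal_snp=(cfg.causal_snp[0], int(cfg.causal_snp[1]))
        if cfg.causal_snp is not None else None,
    )
    return geno, sites, truth


def plant_sweep(geno: GenotypeMatrix, sites: pd.DataFrame, interval, popmap: PopulationMap,
                target_pop: str, intensity: float) -> GenotypeMatrix:
    """Reduce diversity in ``target_pop`` inside ``interval`` (0-based half-open).

    For every site in the interval, a fraction ``intensity`` of the target
    population's minor-allele copies (rounded up) is converted to the major
    allele, mimicking hitchhiking loss of variation; intensity 1 makes the
    population monomorphic there. Deterministic: copies are removed from the
    highest-dosage carriers first, in sample order. Other populations and
    sites outside the interval are untouched.
    """
    contig, start, end = interval
    if start >= end:
        raise ValueError("empty interval: start must be < end")
    if not 0 < intensity <= 1:
        raise ValueError("intensity must lie in (0, 1]")
    rows = geno.sample_indices(popmap.samples(target_pop))
    out = geno.copy()
    pos0 = sites["pos"].to_numpy() - 1
    idx = np.nonzero((sites["contig"].to_numpy() == contig)
                     & (pos0 >= start) & (pos0 < end))[0]
    ploidy = geno.ploidy[rows]
    for j in idx:
        d = out.dosages[rows, j].astype(np.int64)
        obs = d != MISSING
        if not obs.any():
            continue
        alt = int(d[obs].sum())
        total = int(ploidy[obs].sum())
        minor_is_alt = alt <= total - alt
        n_minor = min(alt, total - alt)
        if n_minor == 0:
            continue
        k = math.ceil(intensity * n_minor)
        minor_copies = np.where(obs, d if minor_is_alt else ploidy - d, 0)
        order = np.argsort(-minor_copies, kind="stable")
        for s in order:
            if k == 0:
                break
            take = int(min(minor_copies[s], k))
            if take == 0:
                break
            d[s] += -take if minor_is_alt else take
            k -= take
        out.dosages[rows, j] = np.where(obs, d, MISSING).astype(np.int16)
    return out


def simulate_trait(geno: GenotypeMatrix, sites: pd.DataFrame, causal_snp,
                   penetrance: str = "dominant", noise: float = 0.0,
                   popmap: PopulationMap | None = None,
                   case_populations=None, seed: int = 0) -> pd.DataFrame:
    """Binary (0/1) phenotype per sample.

    penetrance modes:
      - "dominant": phenotype 1 iff causal dosage > 0, each value flipped
        with probability ``noise``;
      - "coin": fair-coin null, ignores the causal SNP;
      - "population": phenotype 1 for samples whose population label is in
        ``case_populations`` (fully structure-confounded trait).
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    if penetrance == "coin":
        y = rng.integers(0, 2, size=n)
    elif penetrance == "population":
        if popmap is None or case_populations is None:
            raise ValueError("population mode needs popmap and case_populations")
        cases = set(case_populations)
        y = np.array([1 if popmap.assignments[s] in cases else 0
                      for s in geno.sample_ids])
    elif penetrance == "dominant":
        if causal_snp is None:
            raise ValueError("dominant mode needs a causal SNP")
        contig, cpos = causal_snp[0], int(causal_snp[1])
        hit = np.nonzero((sites["contig"].to_numpy() == contig)
                         & (sites["pos"].to_numpy() == cpos))[0]
        if hit.size == 0:
            raise ValueError(f"causal SNP {contig}:{cpos} absent from site table")
        d = geno.dosages[:, hit[0]]
        y = (d > 0).astype(np.int64)
        y[d == MISSING] = 0
        if noise > 0:
            flip = rng.random(n) < noise
            y = np.where(flip, 1 - y, y)
    else:
        raise ValueError(f"unknown penetrance model {penetrance!r}")
    return pd.DataFrame({"sample_id": geno.sample_ids, "value": y.astype(np.int64)})


def write_dataset(geno: GenotypeMatrix, sites: pd.DataFrame, truth: SimTruth,
                  phenotypes: pd.DataFrame | None, popmap: PopulationMap,
                  out_dir, contig_lengths: dict | None = None) -> dict:
    """Write VCF + population map + phenotype TSV + truth BED files.

    Returns a dict of the emitted paths. The VCF round-trips through
    :func:`islandscan.vcfio.read_vcf` to identical dosages.
    """
    from pathlib import Path

    from .vcfio import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / "simulated.vcf", "popmap": out / "popmap.tsv",
             "islands_bed": out / "truth_islands.bed",
             "sweeps_bed": out / "truth_sweeps.bed"}
    write_vcf(paths["vcf"], geno, sites, contig_lengths=contig_lengths)
    popmap.to_tsv(paths["popmap"])
    for key, windows in (("islands_bed", truth.island_windows),
                         ("sweeps_bed", truth.sweep_windows)):
        with open(paths[key], "w") as fh:
            for c, s, e in windows:
                fh.write(f"{c}\t{s}\t{e}\n")
    if phenotypes is not None:
        paths["phenotype"] = out / "phenotype.tsv"
        phenotypes.to_csv(paths["phenotype"], sep="\t", index=False)
    if truth.causal_snp is not None:
        paths["causal"] = out / "truth_causal.tsv"
        with open(paths["causal"], "w") as fh:
            fh.write(f"{truth.causal_snp[0]}\t{truth.causal_snp[1]}\n")
    return {k: str(v) for k, v in paths.items()}
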