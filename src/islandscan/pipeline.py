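"""Config-driven orchestration: simulate -> filter -> windows -> islands /
sweeps / randomization -> GWAS, with a reproducible run manifest.

A single YAML config (one block per stage) drives the run; defaults are the
standard scan parameters (40-kb windows / 20-kb step, Z-FST >= 2, top-5%
quantiles, depth 2-50 / MQ 20 / MAF 0.05 / missingness 0.1 filters). All
randomness flows from one seed through named sub-streams. Deterministic
stages are checksum-stable across reruns with the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ConfigurationError, PopulationMap
from .gwas import kinship_simple_matching, mlm_assoc, pc_covariates
from .islands import (add_zfst, call_islands, island_background_randomization,
                      sweep_outliers)
from .simulate import SimulationConfig, SimTruth, simulate_split_populations, \
    simulate_trait, write_dataset
from .vcfio import FilterThresholds, filter_sites, read_vcf, write_vcf
from .winstats import scan

log = logging.getLogger("islandscan")

ALL_STAGES = ["simulate", "filter", "windows", "islands", "sweeps",
              "randtest", "gwas"]

_TOP_KEYS = {"seed", "out_dir", "stages", "simulation", "input", "filters",
             "windows", "comparisons", "islands", "sweeps", "randomization",
             "gwas"}
_BLOCK_KEYS = {
    "input": {"vcf", "popmap", "phenotype"},
    "filters": {"min_depth", "max_depth", "min_mq", "min_maf", "max_missing"},
    "windows": {"size", "step", "min_snps"},
    "islands": {"z_threshold", "mode", "merge"},
    "sweeps": {"fst_q", "ratio_q", "target"},
    "randomization": {"stat", "n_perm", "alternative"},
    "gwas": {"pcs", "phenotype", "causal_snp", "trait_noise"},
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "islandscan_run"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    simulation: dict | None = None
    input: dict | None = None
    filters: dict = field(default_factory=dict)
    windows: dict = field(default_factory=lambda: {"size": 40_000, "step": 20_000,
                                                   "min_snps": 10})
    comparisons: list = field(default_factory=list)
    islands: dict = field(default_factory=lambda: {"z_threshold": 2.0,
                                                   "mode": "standard",
                                                   "merge": False})
    sweeps: dict = field(default_factory=lambda: {"fst_q": 0.05, "ratio_q": 0.05,
                                                  "target": None})
    randomization: dict = field(default_factory=lambda: {"stat": "dxy",
                                                         "n_perm": 1000,
                                                         "alternative": "two-sided"})
    gwas: dict = field(default_factory=lambda: {"pcs": 3, "phenotype": None,
                                                "trait_noise": 0.05})


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stages_run: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def validate_config(source) -> RunConfig:
    """Load and validate a YAML config (path, mapping, or YAML string).

    Unknown keys are rejected by name; every listed comparison population
    must exist; defaults fill every omitted block.
    """
    if isinstance(source, dict):
        raw = dict(source)
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config must be a mapping")
    problems = [f"unknown key {k!r}" for k in raw if k not in _TOP_KEYS]
    for block, allowed in _BLOCK_KEYS.items():
        for k in (raw.get(block) or {}):
            if k not in allowed:
                problems.append(f"unknown key {block}.{k!r}")
    if problems:
        raise ConfigurationError("; ".join(problems))
    cfg = RunConfig()
    for k, v in raw.items():
        if isinstance(getattr(cfg, k, None), dict) and isinstance(v, dict):
            getattr(cfg, k).update(v)
        else:
            setattr(cfg, k, v)
    unknown_stage = [s for s in cfg.stages if s not in ALL_STAGES]
    if unknown_stage:
        raise ConfigurationError(f"unknown stages: {unknown_stage}")
    if cfg.simulation is None and cfg.input is None:
        cfg.simulation = {}
    # resolve population labels for comparison validation
    if cfg.simulation is not None:
        sim = SimulationConfig(seed=cfg.seed, **cfg.simulation)
        pops = list(sim.pop_names)
        if not cfg.comparisons and sim.n_populations >= 2:
            cfg.comparisons = [[pops[0], pops[1]]]
    else:
        if "popmap" not in (cfg.input or {}):
            raise ConfigurationError("input.popmap is required without simulation")
        pops = PopulationMap.from_tsv(cfg.input["popmap"]).populations
    for pair in cfg.comparisons:
        for p in pair:
            if p not in pops:
                raise ConfigurationError(
                    f"comparison names unknown population {p!r}")
    if cfg.sweeps.get("target") is None and cfg.comparisons:
        cfg.sweeps["target"] = cfg.comparisons[0][1]
    if cfg.sweeps.get("target") is not None and cfg.sweeps["target"] not in pops:
        raise ConfigurationError(
            f"sweep target names unknown population {cfg.sweeps['target']!r}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, provenance: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# islandscan {__version__}: {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in dependency order.

    Every stage's outputs are written before dependents start; a failing
    stage raises :class:`PipelineError` naming it, with earlier outputs
    retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__,
                           seed=config.seed)
    stages = [s for s in ALL_STAGES if s in config.stages]
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    trait_seed = int(seeds[1].generate_state(1)[0] % (2 ** 31))
    perm_seed = int(seeds[2].generate_state(1)[0] % (2 ** 31))

    state: dict = {}

    def _run(stage, fn):
        t0 = time.time()
        log.info("stage=%s start params=%s", stage,
                 getattr(config, stage, None) or {})
        try:
            outputs = fn() or {}
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        for name, path in outputs.items():
            manifest.checksums[f"{stage}:{name}"] = _sha256(Path(path))
        manifest.stages_run.append(stage)
        manifest.timestamps[stage] = time.time() - t0
        log.info("stage=%s done wall=%.2fs", stage, manifest.timestamps[stage])

    def stage_simulate():
        sim_cfg = SimulationConfig(seed=config.seed, **(config.simulation or {}))
        geno, sites, truth = simulate_split_populations(sim_cfg)
        popmap = sim_cfg.population_map()
        pheno = None
        if sim_cfg.causal_snp is not None:
            pheno = simulate_trait(geno, sites, sim_cfg.causal_snp,
                                   penetrance="dominant",
                                   noise=config.gwas.get("trait_noise", 0.05),
                                   seed=trait_seed)
        contig_lengths = {c: sim_cfg.contig_length for c in sim_cfg.contig_names()}
        paths = write_dataset(geno, sites, truth, pheno, popmap, out / "data",
                              contig_lengths=contig_lengths)
        state.update(geno=geno, sites=sites, truth=truth, popmap=popmap,
                     pheno=pheno, contig_lengths=contig_lengths)
        return paths

    def stage_load():
        geno, sites = read_vcf(config.input["vcf"])
        popmap = PopulationMap.from_tsv(config.input["popmap"])
        popmap.check_covers(geno.sample_ids)
        pheno = None
        if config.input.get("phenotype"):
            pheno = pd.read_csv(config.input["phenotype"], sep="\t")
        state.update(geno=geno, sites=sites, truth=SimTruth(), popmap=popmap,
                     pheno=pheno, contig_lengths=None)
        return {}

    def stage_filter():
        thr = FilterThresholds(**config.filters) if config.filters \
            else FilterThresholds()
        geno, sites, report = filter_sites(state["geno"], state["sites"], thr)
        state.update(geno=geno, sites=sites)
        report.to_tsv(out / "filter_report.tsv")
        write_vcf(out / "filtered.vcf", geno, sites,
                  contig_lengths=state.get("contig_lengths"))
        for rule, n in report.removed.items():
            log.info("filter rule=%s removed=%d", rule, n)
        return {"report": out / "filter_report.tsv", "vcf": out / "filtered.vcf"}

    def stage_windows():
        comparisons = [tuple(c) for c in config.comparisons]
        if not comparisons:
            raise ValueError("no population comparisons configured")
        records = scan(state["geno"], state["sites"], state["popmap"],
                       comparisons, contig_lengths=state.get("contig_lengths"),
                       **{k: config.windows[k] for k in ("size", "step", "min_snps")
                          if k in config.windows})
        state["records"] = records
        _write_tsv(records, out / "window_stats.tsv",
                   f"windowed statistics, comparisons={comparisons}")
        return {"stats": out / "window_stats.tsv"}

    def stage_islands():
        records = add_zfst(state["records"], mode=config.islands["mode"])
        callsets = call_islands(records,
                                z_threshold=config.islands["z_threshold"],
                                mode=config.islands["mode"],
                                merge=config.islands.get("merge", False))
        state["records"] = records
        state["callsets"] = callsets
        outputs = {}
        for cs in callsets:
            tag = cs.comparison.replace(":", "_")
            tsv = out / f"islands_{tag}.tsv"
            _write_tsv(cs.windows, tsv,
                       f"islands zfst>={cs.threshold} comparison={cs.comparison}")
            bed = out / f"islands_{tag}.bed"
            with open(bed, "w") as fh:
                for c, s, e in sorted(cs.window_set):
                    fh.write(f"{c}\t{s}\t{e}\n")
            outputs[f"tsv:{tag}"] = tsv
            outputs[f"bed:{tag}"] = bed
        return outputs

    def stage_sweeps():
        outputs = {}
        state["sweepsets"] = []
        for comparison, grp in state["records"].groupby("comparison", sort=False):
            target = config.sweeps["target"]
            if target not in (grp["pop_a"].iat[0], grp["pop_b"].iat[0]):
                continue
            ss = sweep_outliers(grp, target, fst_q=config.sweeps["fst_q"],
                                ratio_q=config.sweeps["ratio_q"])
            state["sweepsets"].append(ss)
            tag = str(comparison).replace(":", "_")
            tsv = out / f"sweeps_{tag}.tsv"
            _write_tsv(ss.windows, tsv,
                       f"sweep outliers fst_q={config.sweeps['fst_q']} "
                       f"ratio_q={config.sweeps['ratio_q']} "
                       f"orientation={ss.orientation}")
            outputs[f"tsv:{tag}"] = tsv
        return outputs

    def stage_randtest():
        rows = []
        for cs in state.get("callsets", []):
            if not cs.window_set:
                continue
            grp = state["records"][state["records"]["comparison"] == cs.comparison]
            res = island_background_randomization(
                grp, cs, stat=config.randomization["stat"],
                n_perm=config.randomization["n_perm"], seed=perm_seed,
                alternative=config.randomization["alternative"])
            rows.append({"comparison": cs.comparison,
                         "stat": config.randomization["stat"],
                         "observed_diff": res.observed_diff,
                         "p_value": res.p_value, "direction": res.direction,
                         "method": res.method, "n": res.n_permutations,
                         "anova_p": res.anova_p})
        df = pd.DataFrame(rows)
        _write_tsv(df, out / "randomization.tsv", "island vs background tests")
        return {"tsv": out / "randomization.tsv"}

    def stage_gwas():
        pheno = state.get("pheno")
        if pheno is None and config.gwas.get("phenotype"):
            pheno = pd.read_csv(config.gwas["phenotype"], sep="\t")
        if pheno is None:
            raise ValueError("no phenotype available for GWAS")
        geno, sites = state["geno"], state["sites"]
        K = kinship_simple_matching(geno)
        S = pc_covariates(geno, k=config.gwas.get("pcs", 3))
        assoc = mlm_assoc(geno, pheno, K=K, S=S, sites=sites)
        log.info("gwas lambda_gc=%.3f sigma_g2=%.4g sigma_e2=%.4g",
                 assoc.attrs["lambda_gc"], assoc.attrs["sigma_g2"],
                 assoc.attrs["sigma_e2"])
        n_ok = int((assoc["status"] == "ok").sum())
        bonferroni = 0.05 / max(n_ok, 1)
        assoc["significant"] = assoc["p"] < bonferroni
        _write_tsv(assoc, out / "assoc.tsv",
                   f"MLM GWAS, lambda={assoc.attrs['lambda_gc']:.3f}, "
                   f"bonferroni={bonferroni:.3g}")
        state["assoc"] = assoc
        return {"tsv": out / "assoc.tsv"}

    if "simulate" in stages:
        _run("simulate", stage_simulate)
    else:
        _run("load", stage_load)
    runners = {"filter": stage_filter, "windows": stage_windows,
               "islands": stage_islands, "sweeps": stage_sweeps,
               "randtest": stage_randtest, "gwas": stage_gwas}
    deps = {"islands": "windows", "sweeps": "windows", "randtest": "islands"}
    for stage in ["filter", "windows", "islands", "sweeps", "randtest", "gwas"]:
        if stage not in stages:
            continue
        need = deps.get(stage)
        if need and need not in manifest.stages_run:
            raise PipelineError(f"stage {stage!r} requires stage {need!r}")
        _run(stage, runners[stage])

    manifest.save(out / "manifest.json")
    return manifest
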