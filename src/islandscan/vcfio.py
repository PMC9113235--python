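"""VCF input/output, SNP filtering, and allele-frequency summaries.

Reading goes through pysam's VCF parser; genotypes are collapsed to
alternate-allele dosages with ploidy inferred per sample from GT arity.
Filtering applies the standard resequencing thresholds (depth window, RMS
mapping quality, pooled minor-allele frequency, per-site missingness) in a
fixed, auditable order so every removed site is attributed to exactly one
rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .core import MISSING, GenotypeMatrix, PopulationMap, make_site_table

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "filter_sites",
    "allele_frequencies",
]

#: order in which a site failing several rules is attributed to one of them
RULE_ORDER = ["multiallelic", "depth_low", "depth_high", "mq", "missingness", "maf"]


@dataclass
class FilterThresholds:
    """SNP retention thresholds; ``None`` disables the corresponding rule.

    Defaults are the standard resequencing filter set: coverage depth in
    [2, 50], RMS mapping quality >= 20, pooled MAF >= 0.05, missingness <= 0.1.
    """

    min_depth: float | None = 2
    max_depth: float | None = 50
    min_mq: float | None = 20
    min_maf: float | None = 0.05
    max_missing: float | None = 0.1

    @classmethod
    def disabled(cls) -> "FilterThresholds":
        return cls(None, None, None, None, None)


@dataclass
class FilterReport:
    n_input: int = 0
    n_output: int = 0
    removed: dict = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def __post_init__(self) -> None:
        for r in RULE_ORDER:
            self.removed.setdefault(r, 0)

    def check(self) -> None:
        if self.n_input - self.n_output != sum(self.removed.values()):
            raise AssertionError("filter report does not balance")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("rule\tremoved\n")
            fh.write(f"input\t{self.n_input}\n")
            for r in RULE_ORDER:
                fh.write(f"{r}\t{self.removed[r]}\n")
            fh.write(f"output\t{self.n_output}\n")


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF into (GenotypeMatrix, SiteTable).

    Multiallelic records (more than one ALT) are dropped; the count is stored
    in ``sites.attrs["n_multiallelic_dropped"]`` so downstream filter reports
    can account for them. Missing genotypes stay missing. Ploidy is inferred
    from GT arity and must be constant within a sample.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.header.samples)
    n = len(sample_ids)
    ploidy = np.zeros(n, dtype=np.int64)
    rows: list = []
    dosage_cols: list = []
    n_multi = 0
    for rec_i, rec in enumerate(vcf):
        alts = rec.alts or ()
        if len(alts) != 1:
            n_multi += 1
            continue
        col = np.empty(n, dtype=np.int16)
        for si, sid in enumerate(sample_ids):
            gt = rec.samples[sid].get("GT", None)
            if gt is None or all(a is None for a in gt):
                col[si] = MISSING
                continue
            if any(a is None for a in gt):
                col[si] = MISSING
            else:
                col[si] = sum(1 for a in gt if a == 1)
            arity = len(gt)
            if ploidy[si] == 0:
                ploidy[si] = arity
            elif ploidy[si] != arity:
                raise ValueError(
                    f"inconsistent ploidy for sample {sid} at record "
                    f"{rec.chrom}:{rec.pos} (line ~{rec_i + 1} of body)")
        info = rec.info
        rows.append((rec.chrom, rec.pos, rec.ref, alts[0],
                     float(info.get("DP", np.nan)),
                     float(info.get("MQ", np.nan))))
        dosage_cols.append(col)
    vcf.close()
    ploidy[ploidy == 0] = 2  # samples missing everywhere default to diploid
    if rows:
        contig, pos, ref, alt, depth, mq = zip(*rows)
        dosages = np.stack(dosage_cols, axis=1)
    else:
        contig = pos = ref = alt = depth = mq = []
        dosages = np.zeros((n, 0), dtype=np.int16)
    sites = make_site_table(contig, pos, ref, alt, depth, mq)
    sites.attrs["n_multiallelic_dropped"] = n_multi
    return GenotypeMatrix(dosages, sample_ids, ploidy), sites


def write_vcf(path, geno: GenotypeMatrix, sites: pd.DataFrame,
              contig_lengths: dict | None = None) -> None:
    """Emit a minimal VCF v4.2 with GT (correct ploidy), INFO/DP and INFO/MQ."""
    if geno.n_sites != len(sites):
        raise ValueError("genotype matrix and site table disagree on site count")
    if contig_lengths is None:
        contig_lengths = (sites.groupby("contig", sort=False, observed=True)["pos"]
                          .max().to_dict())
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=islandscan\n")
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={int(ln)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        contigs = sites["contig"].to_numpy()
        pos = sites["pos"].to_numpy()
        ref = sites["ref"].to_numpy()
        alt = sites["alt"].to_numpy()
        depth = sites["depth"].to_numpy()
        mq = sites["mq"].to_numpy()
        for j in range(len(sites)):
            gts = []
            for si in range(geno.n_samples):
                d = int(geno.dosages[si, j])
                p = int(geno.ploidy[si])
                if d == MISSING:
                    gts.append("/".join(["."] * p))
                else:
                    gts.append("/".join(["0"] * (p - d) + ["1"] * d))
            dp = "." if np.isnan(depth[j]) else str(int(round(depth[j])))
            mqs = "." if np.isnan(mq[j]) else f"{mq[j]:g}"
            fh.write(f"{contigs[j]}\t{int(pos[j])}\t.\t{ref[j]}\t{alt[j]}\t.\t"
                     f"PASS\tDP={dp};MQ={mqs}\tGT\t" + "\t".join(gts) + "\n")


def filter_sites(geno: GenotypeMatrix, sites: pd.DataFrame,
                 thresholds: FilterThresholds | None = None):
    """Apply the SNP retention rules; return (geno, sites, FilterReport).

    Rules are checked in :data:`RULE_ORDER`; a site failing several is
    counted at its first failing rule. MAF is computed from pooled non-missing
    allele counts across all samples; missingness is the fraction of samples
    with a missing genotype.
    """
    thr = thresholds if thresholds is not None else FilterThresholds()
    n_in = len(sites)
    report = FilterReport(n_input=n_in + int(sites.attrs.get("n_multiallelic_dropped", 0)))
    report.removed["multiallelic"] = int(sites.attrs.get("n_multiallelic_dropped", 0))

    depth = sites["depth"].to_numpy()
    mq = sites["mq"].to_numpy()
    obs = geno.dosages != MISSING
    n_alleles = (obs * geno.ploidy[:, None]).sum(axis=0)
    alt_count = np.where(obs, geno.dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt_count / np.maximum(n_alleles, 1), np.nan)
    maf = np.minimum(freq, 1 - freq)
    missingness = 1.0 - obs.sum(axis=0) / geno.n_samples

    alive = np.ones(n_in, dtype=bool)

    def _kill(rule: str, fails: np.ndarray) -> None:
        newly = alive & fails
        report.removed[rule] += int(newly.sum())
        alive[newly] = False

    if thr.min_depth is not None:
        _kill("depth_low", depth < thr.min_depth)
    if thr.max_depth is not None:
        _kill("depth_high", depth > thr.max_depth)
    if thr.min_mq is not None:
        _kill("mq", mq < thr.min_mq)
    if thr.max_missing is not None:
        _kill("missingness", missingness > thr.max_missing)
    if thr.min_maf is not None:
        _kill("maf", np.isnan(maf) | (maf < thr.min_maf))

    out_sites = sites.loc[alive].reset_index(drop=True)
    out_sites.attrs["n_multiallelic_dropped"] = 0
    out_geno = geno.take_sites(alive)
    report.n_output = int(alive.sum())
    report.check()
    return out_geno, out_sites, report


def allele_frequencies(geno: GenotypeMatrix, pop, popmap: PopulationMap | None = None):
    """Per-site alternate-allele frequency and allele count for a sample subset.

    ``pop`` is a population label (then ``popmap`` is required) or an iterable
    of sample ids. Frequency = sum(dosages) / sum(ploidy) over non-missing
    samples; ``n`` is the non-missing allele count. Sites where the whole
    subset is missing get frequency NaN and n = 0.
    """
    if isinstance(pop, str):
        if popmap is None:
            raise ValueError("a population label requires a popmap")
        samples = popmap.samples(pop)
    else:
        samples = list(pop)
    if not samples:
        raise ValueError("empty sample subset")
    rows = geno.sample_indices(samples)
    d = geno.dosages[rows]
    obs = d != MISSING
    n = (obs * geno.ploidy[rows, None]).sum(axis=0)
    ac = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, ac / np.maximum(n, 1), np.nan)
    return freq.astype(float), n.astype(np.int64)
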