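"""Sliding-window population-genetic statistics.

Implements the per-window quantities of a genome divergence scan:

* nucleotide diversity pi (per bp, unbiased n/(n-1) estimator),
* Weir & Cockerham (1984) FST, window-aggregated as a ratio of sums of the
  per-site variance components a / (a + b + c),
* Tajima's (1989) D from window-level S and absolute pi,
* absolute divergence DXY per bp,
* linkage-disequilibrium decay as binned squared dosage correlation r^2
  (composite / Rogers-Huff form, safe on unphased genotypes).

Windows are 0-based half-open intervals; the default tiling is 40-kb windows
with a 20-kb step. All estimators are allele-frequency based and work on
mixed-ploidy cohorts; the full 1984 heterozygosity-aware FST components are
used when both populations are entirely diploid, otherwise an allele-count
(haploid-copies) variant with no within-individual component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "Window",
    "LDDecayCurve",
    "make_windows",
    "nucleotide_diversity",
    "weir_cockerham_fst",
    "tajimas_d",
    "dxy",
    "ld_r2_decay",
    "scan",
]


@dataclass(frozen=True)
class Window:
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("window must satisfy 0 <= start < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LDDecayCurve:
    bin_mid: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance_bp": self.bin_mid,
                             "mean_r2": self.mean_r2,
                             "n_pairs": self.n_pairs})


def make_windows(contig_lengths: dict, size: int = 40_000, step: int = 20_000,
                 trailing: str = "step") -> list[Window]:
    """Tile contigs with sliding windows.

    Full-size windows start at 0, step, 2*step, ... while they fit. A contig
    shorter than ``size`` yields the single window [0, L). With
    ``trailing="step"`` an uncovered tail of at least ``step`` bp gets one
    truncated trailing window; "never" suppresses it; "always" always emits it.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    if not 0 < step <= size:
        raise ValueError("step must satisfy 0 < step <= size")
    if trailing not in ("step", "never", "always"):
        raise ValueError("trailing must be 'step', 'never' or 'always'")
    windows: list[Window] = []
    for contig, length in contig_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for contig {contig!r}")
        if length < size:
            windows.append(Window(contig, 0, length))
            continue
        s = 0
        last_end = 0
        while s + size <= length:
            windows.append(Window(contig, s, s + size))
            last_end = s + size
            s += step
        if last_end < length:
            tail = length - s
            if trailing == "always" or (trailing == "step" and tail >= step):
                windows.append(Window(contig, s, length))
    return windows


# ---------------------------------------------------------------------------
# per-site summaries


def _pop_site_summaries(geno: GenotypeMatrix, samples) -> dict:
    """Per-site allele counts for one population subset.

    Returns arrays over all sites: ``n`` non-missing allele copies, ``p``
    alternate-allele frequency (NaN where n = 0), ``n_ind`` non-missing
    individuals, ``het`` observed heterozygote frequency (diploids; NaN
    otherwise), and the flag ``all_diploid``.
    """
    rows = geno.sample_indices(samples)
    d = geno.dosages[rows]
    ploidy = geno.ploidy[rows]
    obs = d != MISSING
    n = (obs * ploidy[:, None]).sum(axis=0)
    ac = np.where(obs, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac / np.maximum(n, 1), np.nan)
    n_ind = obs.sum(axis=0)
    all_diploid = bool((ploidy == 2).all())
    if all_diploid:
        n_het = ((d == 1) & obs).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            het = np.where(n_ind > 0, n_het / np.maximum(n_ind, 1), np.nan)
    else:
        het = np.full(geno.n_sites, np.nan)
    return {"n": n, "p": p, "n_ind": n_ind, "het": het, "all_diploid": all_diploid}


def _window_site_index(sites: pd.DataFrame, window: Window) -> np.ndarray:
    pos0 = sites["pos"].to_numpy() - 1
    mask = ((sites["contig"].to_numpy() == window.contig)
            & (pos0 >= window.start) & (pos0 < window.end))
    return np.nonzero(mask)[0]


def _resolve(geno, pop, popmap):
    if isinstance(pop, str):
        if popmap is None:
            raise ValueError("a population label requires a popmap")
        return popmap.samples(pop)
    samples = list(pop)
    if not samples:
        raise ValueError("empty population subset")
    return samples


# ---------------------------------------------------------------------------
# nucleotide diversity


def _pi_sum(n: np.ndarray, p: np.ndarray) -> float:
    """Sum over sites of the unbiased per-site heterozygosity n/(n-1)*2p(1-p)."""
    ok = n >= 2
    n = n[ok].astype(float)
    p = p[ok]
    return float(np.sum(n / (n - 1.0) * 2.0 * p * (1.0 - p)))


def nucleotide_diversity(geno: GenotypeMatrix, sites: pd.DataFrame, pop,
                         window: Window, popmap: PopulationMap | None = None) -> float:
    """Per-bp nucleotide diversity (theta-pi) of ``pop`` in ``window``.

    pi = sum_sites [n/(n-1)] * 2*p*(1-p) / L with n the non-missing allele
    count at each site and L the window length in bp.
    """
    samples = _resolve(geno, pop, popmap)
    summ = _pop_site_summaries(geno, samples)
    idx = _window_site_index(sites, window)
    return _pi_sum(summ["n"][idx], summ["p"][idx]) / window.length


# ---------------------------------------------------------------------------
# Weir & Cockerham FST


def _wc_components(nA_ind, pA, hA, nB_ind, pB, hB, diploid: bool):
    """Per-site Weir & Cockerham (1984) variance components for two populations.

    With genotypic (diploid) data the full a/b/c decomposition with the
    observed heterozygote frequency is used; otherwise ``nA_ind``/``nB_ind``
    are allele-copy counts and the haploid mean-squares form (c = 0) applies.
    Sites unusable (monomorphic across both populations, or missing data in
    either) are masked out.
    """
    r = 2.0
    nA = nA_ind.astype(float)
    nB = nB_ind.astype(float)
    usable = (nA >= (2 if diploid else 2)) & (nB >= (2 if diploid else 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (nA + nB) / r
        pbar = np.where(nbar > 0, (nA * pA + nB * pB) / (r * nbar), np.nan)
    usable &= np.isfinite(pbar) & (pbar > 0) & (pbar < 1)
    n_c = np.where(usable,
                   (r * nbar - (nA ** 2 + nB ** 2) / np.maximum(r * nbar, 1e-300))
                   / (r - 1),
                   np.nan)
    s2 = np.where(usable,
                  (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2)
                  / ((r - 1) * np.maximum(nbar, 1e-300)),
                  np.nan)
    if diploid:
        hbar = np.where(usable, (nA * hA + nB * hB) / np.maximum(r * nbar, 1e-300),
                        np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            a = (nbar / n_c) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                / (nbar - 1.0))
            b = (nbar / (nbar - 1.0)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r
                - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
            c = hbar / 2.0
        usable &= nbar > 1
    else:
        # haploid allele-copy mean squares: a = (MSP - MSG)/n_c, b = MSG, c = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            msp = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / (r - 1)
            msg = (nA * pA * (1 - pA) + nB * pB * (1 - pB)) / (nA + nB - r)
            a = (msp - msg) / n_c
            b = msg
            c = np.zeros_like(a)
        usable &= (nA + nB) > r
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c, usable


def weir_cockerham_fst(geno: GenotypeMatrix, sites: pd.DataFrame, popA, popB,
                       window: Window, popmap: PopulationMap | None = None):
    """Window FST between two populations.

    Returns ``(fst_weighted, per_site)`` where the window estimate is the
    ratio of sums sum(a) / sum(a+b+c) over usable sites and ``per_site`` is a
    DataFrame of the per-site components and ratios. With no usable site the
    window value is NaN.
    """
    sA = _resolve(geno, popA, popmap)
    sB = _resolve(geno, popB, popmap)
    mA = _pop_site_summaries(geno, sA)
    mB = _pop_site_summaries(geno, sB)
    idx = _window_site_index(sites, window)
    diploid = mA["all_diploid"] and mB["all_diploid"]
    if diploid:
        nA, nB = mA["n_ind"][idx], mB["n_ind"][idx]
    else:
        nA, nB = mA["n"][idx], mB["n"][idx]
    a, b, c, usable = _wc_components(nA, mA["p"][idx], mA["het"][idx],
                                     nB, mB["p"][idx], mB["het"][idx], diploid)
    per_site = pd.DataFrame({
        "site_index": idx, "a": a, "b": b, "c": c,
        "fst": np.where(usable, a / np.where(usable, a + b + c, np.nan), np.nan),
    })
    if not usable.any():
        return float("nan"), per_site
    denom = np.nansum(a + b + c)
    fst = float(np.nansum(a) / denom) if denom != 0 else float("nan")
    return fst, per_site


# ---------------------------------------------------------------------------
# Tajima's D


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants for a sample of n allele copies."""
    if n < 2:
        raise ValueError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(geno: GenotypeMatrix, sites: pd.DataFrame, pop, window: Window,
              popmap: PopulationMap | None = None) -> float:
    """Tajima's D for ``pop`` in ``window``; NaN when undefined.

    Uses window-level S (sites segregating within the population) and the
    absolute (not per-bp) unbiased pi. The allele-sample size n for the
    normalizing constants is the minimum per-site non-missing allele count
    across segregating sites, a conservative choice under missingness.
    Undefined (NaN) when S = 0 or fewer than 4 allele copies are available.
    """
    samples = _resolve(geno, pop, popmap)
    summ = _pop_site_summaries(geno, samples)
    idx = _window_site_index(sites, window)
    return _tajd_from(summ["n"][idx], summ["p"][idx])


def _tajd_from(n: np.ndarray, p: np.ndarray) -> float:
    seg = (n >= 2) & np.isfinite(p) & (p > 0) & (p < 1)
    s = int(seg.sum())
    if s == 0:
        return float("nan")
    n_used = int(n[seg].min())
    if n_used < 4:
        return float("nan")
    pi_abs = _pi_sum(n[seg], p[seg])
    k = tajima_constants(n_used)
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    if var <= 0:
        return float("nan")
    return float((pi_abs - s / k["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# DXY


def dxy(geno: GenotypeMatrix, sites: pd.DataFrame, popA, popB, window: Window,
        popmap: PopulationMap | None = None) -> float:
    """Absolute divergence per bp between two populations in ``window``.

    DXY = sum_sites [pA*(1-pB) + pB*(1-pA)] / L with point-estimate allele
    frequencies and L the window length. Sites lacking data in either
    population are skipped; a window whose every site lacks data in one
    population is NaN. A window with no sites at all is 0 (no divergence
    observable, all monomorphic).
    """
    sA = _resolve(geno, popA, popmap)
    sB = _resolve(geno, popB, popmap)
    mA = _pop_site_summaries(geno, sA)
    mB = _pop_site_summaries(geno, sB)
    idx = _window_site_index(sites, window)
    return _dxy_from(mA["p"][idx], mB["p"][idx], window.length)


def _dxy_from(pA: np.ndarray, pB: np.ndarray, length: int) -> float:
    if pA.size == 0:
        return 0.0
    ok = np.isfinite(pA) & np.isfinite(pB)
    if not ok.any():
        return float("nan")
    pA, pB = pA[ok], pB[ok]
    return float(np.sum(pA * (1 - pB) + pB * (1 - pA)) / length)


# ---------------------------------------------------------------------------
# LD decay


def ld_r2_decay(geno: GenotypeMatrix, sites: pd.DataFrame, pop,
                max_dist: int = 500_000, n_bins: int = 50,
                popmap: PopulationMap | None = None) -> LDDecayCurve:
    """Mean squared dosage-correlation r^2 binned by pair distance.

    r^2 is the squared Pearson correlation between the dosage vectors of two
    sites (composite LD; valid on unphased data). Pairs span sites on the
    same contig at distance <= ``max_dist``; monomorphic (zero-variance)
    sites contribute no pairs. Missing dosages are mean-imputed per site.
    """
    samples = _resolve(geno, pop, popmap)
    rows = geno.sample_indices(samples)
    d = geno.dosages[rows].astype(float)
    d[geno.dosages[rows] == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    nan_mask = np.isnan(d)
    if nan_mask.any():
        d[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    poly = sd > 0
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    contigs = sites["contig"].to_numpy()
    pos = sites["pos"].to_numpy()
    for contig in pd.unique(contigs):
        sel = np.nonzero((contigs == contig) & poly)[0]
        if sel.size < 2:
            continue
        z = d[:, sel] / sd[sel]
        cpos = pos[sel]
        n = z.shape[0]
        for i in range(sel.size - 1):
            j_hi = int(np.searchsorted(cpos, cpos[i] + max_dist, side="right"))
            if j_hi <= i + 1:
                continue
            r = z[:, i] @ z[:, i + 1:j_hi] / n
            dist = cpos[i + 1:j_hi] - cpos[i]
            b = np.minimum(np.digitize(dist, edges) - 1, n_bins - 1)
            np.add.at(sums, b, r ** 2)
            np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return LDDecayCurve(mids, mean_r2, counts)


# ---------------------------------------------------------------------------
# full scan


def scan(geno: GenotypeMatrix, sites: pd.DataFrame, popmap: PopulationMap,
         comparisons, contig_lengths: dict | None = None, size: int = 40_000,
         step: int = 20_000, min_snps: int = 10) -> pd.DataFrame:
    """One record per window per population comparison.

    Columns: contig, start, end, comparison, pop_a, pop_b, n_snps, pi_a,
    pi_b, fst_weighted, fst_mean, dxy, tajd_a, tajd_b, low_snp. Windows with
    fewer than ``min_snps`` SNPs are flagged (not removed). ``zfst`` is added
    by the island-calling stage.
    """
    for a, b in comparisons:
        popmap.samples(a), popmap.samples(b)
    if contig_lengths is None:
        contig_lengths = (sites.groupby("contig", sort=False, observed=True)["pos"]
                          .max().to_dict())
    windows = make_windows(contig_lengths, size=size, step=step)
    pops = sorted({p for pair in comparisons for p in pair})
    summ = {p: _pop_site_summaries(geno, popmap.samples(p)) for p in pops}

    contigs_arr = sites["contig"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1
    records = []
    for w in windows:
        on_contig = contigs_arr == w.contig
        cpos = pos0[on_contig]
        base = np.nonzero(on_contig)[0]
        lo, hi = np.searchsorted(cpos, [w.start, w.end])
        idx = base[lo:hi]
        for a, b in comparisons:
            sa, sb = summ[a], summ[b]
            diploid = sa["all_diploid"] and sb["all_diploid"]
            if diploid:
                nA, nB = sa["n_ind"][idx], sb["n_ind"][idx]
            else:
                nA, nB = sa["n"][idx], sb["n"][idx]
            ca, cb, cc, usable = _wc_components(
                nA, sa["p"][idx], sa["het"][idx],
                nB, sb["p"][idx], sb["het"][idx], diploid)
            denom = np.nansum(ca + cb + cc)
            fst_w = float(np.nansum(ca) / denom) if usable.any() and denom != 0 else np.nan
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios = ca / (ca + cb + cc)
            fst_m = float(np.nanmean(ratios)) if usable.any() else np.nan
            records.append({
                "contig": w.contig, "start": w.start, "end": w.end,
                "comparison": f"{a}:{b}", "pop_a": a, "pop_b": b,
                "n_snps": int(idx.size),
                "pi_a": _pi_sum(sa["n"][idx], sa["p"][idx]) / w.length,
                "pi_b": _pi_sum(sb["n"][idx], sb["p"][idx]) / w.length,
                "fst_weighted": fst_w, "fst_mean": fst_m,
                "dxy": _dxy_from(sa["p"][idx], sb["p"][idx], w.length),
                "tajd_a": _tajd_from(sa["n"][idx], sa["p"][idx]),
                "tajd_b": _tajd_from(sb["n"][idx], sb["p"][idx]),
                "low_snp": bool(idx.size < min_snps),
            })
    return pd.DataFrame.from_records(records)
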