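"""Divergence-outlier machinery on windowed scan tables.

Z-FST standardization, genomic-island calling (Z-FST >= 2, roughly the top
5% tail), intersection of island calls across population comparisons, joint
top-quantile FST x log2(theta-pi ratio) selective-sweep outliers, and
island-vs-background randomization and rank-sum tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "IslandCallSet",
    "SweepRegionSet",
    "RandomizationResult",
    "zfst",
    "add_zfst",
    "call_islands",
    "intersect_islands",
    "sweep_outliers",
    "island_background_randomization",
    "compare_island_stats",
]

WINDOW_KEY = ["contig", "start", "end"]


def _window_tuples(records: pd.DataFrame) -> list:
    return list(map(tuple, records[WINDOW_KEY].itertuples(index=False, name=None)))


@dataclass
class IslandCallSet:
    comparison: str
    windows: pd.DataFrame          # called island windows with fst and zfst
    threshold: float
    mean_fst: float
    sd_fst: float
    tiling: frozenset = field(default_factory=frozenset)  # all scanned windows

    @property
    def window_set(self) -> set:
        return set(_window_tuples(self.windows))


@dataclass
class SweepRegionSet:
    comparison: str
    windows: pd.DataFrame
    fst_cutoff: float
    ratio_cutoff: float
    orientation: str

    @property
    def window_set(self) -> set:
        return set(_window_tuples(self.windows))


@dataclass
class RandomizationResult:
    observed_diff: float
    p_value: float
    n_permutations: int
    direction: str                 # "elevated" or "reduced" in islands
    method: str                    # "exhaustive" or "sampled"
    anova_p: float = float("nan")  # plain one-way F-test alongside


def zfst(values, mode: str = "standard") -> np.ndarray:
    """Standardize window FST values.

    ``mode="standard"``: z = (x - mean) / sd, the conventional Z-score under
    which z >= 2 approximates a top-5% tail. ``mode="printed"`` evaluates the
    alternative (x * mean) / sd form for fidelity experiments. NaNs propagate;
    mean/sd are computed over finite entries only.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("zfst needs at least two finite FST values")
    mean = float(x[finite].mean())
    sd = float(x[finite].std(ddof=0))
    if sd <= max(abs(mean), 1e-30) * 1e-12:
        raise ValueError("zfst undefined: FST values are all equal (sd = 0)")
    if mode == "standard":
        z = (x - mean) / sd
    elif mode == "printed":
        z = (x * mean) / sd
    else:
        raise ValueError(f"unknown zfst mode {mode!r}")
    return np.where(finite, z, np.nan)


def add_zfst(records: pd.DataFrame, fst_col: str = "fst_weighted",
             mode: str = "standard") -> pd.DataFrame:
    """Return a copy of the scan table with a per-comparison ``zfst`` column."""
    out = records.copy()
    out["zfst"] = np.nan
    for _, grp in out.groupby("comparison", sort=False):
        out.loc[grp.index, "zfst"] = zfst(grp[fst_col].to_numpy(), mode=mode)
    return out


def call_islands(records: pd.DataFrame, z_threshold: float = 2.0,
                 fst_col: str = "fst_weighted", mode: str = "standard",
                 merge: bool = False) -> list[IslandCallSet]:
    """Call genomic islands of divergence per comparison.

    A window is an island when its Z-FST (standardized against the
    genome-wide mean and sd of windowed FST for that comparison) reaches
    ``z_threshold``. With ``merge=True`` overlapping or book-ended called
    windows are merged into intervals (window bookkeeping columns are then
    dropped).
    """
    callsets = []
    for comparison, grp in records.groupby("comparison", sort=False):
        x = grp[fst_col].to_numpy(dtype=float)
        finite = np.isfinite(x)
        z = zfst(x, mode=mode)
        called = grp.loc[np.isfinite(z) & (z >= z_threshold)].copy()
        called["zfst"] = z[np.isfinite(z) & (z >= z_threshold)]
        if merge and len(called):
            called = _merge_intervals(called)
        callsets.append(IslandCallSet(
            comparison=str(comparison), windows=called.reset_index(drop=True),
            threshold=float(z_threshold),
            mean_fst=float(x[finite].mean()), sd_fst=float(x[finite].std(ddof=0)),
            tiling=frozenset(_window_tuples(grp)),
        ))
    return callsets


def _merge_intervals(called: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for contig, grp in called.sort_values(WINDOW_KEY).groupby("contig", sort=False):
        cur = None
        for _, r in grp.iterrows():
            if cur is None or r["start"] > cur[2]:
                if cur is not None:
                    rows.append(cur)
                cur = [contig, int(r["start"]), int(r["end"])]
            else:
                cur[2] = max(cur[2], int(r["end"]))
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=WINDOW_KEY)


def intersect_islands(callsets) -> list:
    """Windows called as islands in every callset (exact window identity)."""
    callsets = list(callsets)
    if not callsets:
        return []
    tiling = callsets[0].tiling
    for cs in callsets[1:]:
        if cs.tiling != tiling:
            raise ValueError("callsets come from different window tilings")
    common = set.intersection(*(cs.window_set for cs in callsets))
    return sorted(common)


def pi_ratio_log2(records: pd.DataFrame, target: str) -> np.ndarray:
    """log2(pi_ref / pi_target); large values mean diversity loss in target.

    ``target`` names the population whose diversity reduction is scanned for
    (the putatively swept population); the other population of the comparison
    is the reference (numerator). Zero target diversity gives +inf (maximal
    loss); zero over zero gives NaN.
    """
    if (records["pop_a"] == target).all():
        num, den = records["pi_b"], records["pi_a"]
    elif (records["pop_b"] == target).all():
        num, den = records["pi_a"], records["pi_b"]
    else:
        raise ValueError(f"orientation target {target!r} is not a population "
                         "of every record's comparison")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(num.to_numpy() / den.to_numpy())


def sweep_outliers(records: pd.DataFrame, target: str, fst_q: float = 0.05,
                   ratio_q: float = 0.05,
                   fst_col: str = "fst_weighted") -> SweepRegionSet:
    """Joint top-quantile FST x log2(theta-pi ratio) sweep outliers.

    A window is an outlier when its FST lies in the top ``fst_q`` fraction
    AND its log2 pi-ratio (oriented so large values mean diversity loss in
    ``target``) lies in the top ``ratio_q`` fraction. Cutoffs are empirical
    quantiles over finite values; ties at a cutoff are included; +inf ratios
    (target pi = 0) always exceed the ratio cutoff.
    """
    comparisons = records["comparison"].unique()
    if len(comparisons) != 1:
        raise ValueError("sweep_outliers expects records of a single comparison")
    ratio = pi_ratio_log2(records, target)
    fst = records[fst_col].to_numpy(dtype=float)
    if fst_q <= 0 or ratio_q <= 0:
        empty = records.iloc[0:0].copy()
        return SweepRegionSet(str(comparisons[0]), empty, float("inf"),
                              float("inf"), f"log2(pi_ref/pi_{target})")
    fin_f = np.isfinite(fst)
    fin_r = np.isfinite(ratio)
    if not fin_f.any() or not (fin_r | np.isposinf(ratio)).any():
        raise ValueError("no finite FST or ratio values to rank")
    fst_cut = float(np.quantile(fst[fin_f], 1 - fst_q))
    ratio_cut = float(np.quantile(ratio[fin_r], 1 - ratio_q)) if fin_r.any() else np.inf
    keep = (np.where(fin_f, fst, -np.inf) >= fst_cut) \
        & ((np.where(fin_r, ratio, -np.inf) >= ratio_cut) | np.isposinf(ratio))
    out = records.loc[keep].copy()
    out["pi_ratio_log2"] = ratio[keep]
    return SweepRegionSet(str(comparisons[0]), out.reset_index(drop=True),
                          fst_cut, ratio_cut, f"log2(pi_ref/pi_{target})")


def island_background_randomization(records: pd.DataFrame, islands,
                                    stat: str = "dxy", n_perm: int = 1000,
                                    seed: int = 0,
                                    alternative: str = "two-sided",
                                    exhaustive_limit: int = 100_000
                                    ) -> RandomizationResult:
    """Permutation test of mean(stat in islands) - mean(stat in background).

    Island/background labels are shuffled over windows (island count
    preserved). When the number of distinct labelings is at most
    ``exhaustive_limit`` the null is enumerated exactly and p is the exact
    tail fraction; otherwise ``n_perm`` random relabelings are drawn and the
    add-one correction p = (1 + hits) / (1 + n_perm) is used. ``alternative``
    compares permuted differences to the observed one by absolute value
    ("two-sided") or signed ("greater"/"less"). A one-way ANOVA F-test
    p-value for the same grouping is reported alongside.
    """
    if isinstance(islands, IslandCallSet):
        islands = islands.window_set
    islands = set(islands)
    keys = _window_tuples(records)
    values = records[stat].to_numpy(dtype=float)
    is_island = np.array([k in islands for k in keys])
    finite = np.isfinite(values)
    values, is_island = values[finite], is_island[finite]
    k = int(is_island.sum())
    n = values.size
    if k == 0 or k == n:
        raise ValueError("need at least one island and one background window "
                         "with a finite statistic")
    total = values.sum()

    def diff_from_island_sum(s_isl):
        return s_isl / k - (total - s_isl) / (n - k)

    observed = diff_from_island_sum(values[is_island].sum())

    def tail_hits(diffs: np.ndarray) -> int:
        if alternative == "two-sided":
            return int(np.sum(np.abs(diffs) >= abs(observed) - 1e-12))
        if alternative == "greater":
            return int(np.sum(diffs >= observed - 1e-12))
        if alternative == "less":
            return int(np.sum(diffs <= observed + 1e-12))
        raise ValueError(f"unknown alternative {alternative!r}")

    n_arrangements = math.comb(n, k)
    if n_arrangements <= exhaustive_limit:
        sums = np.fromiter((values[list(c)].sum()
                            for c in combinations(range(n), k)),
                           dtype=float, count=n_arrangements)
        diffs = diff_from_island_sum(sums)
        p = tail_hits(diffs) / n_arrangements
        method, n_used = "exhaustive", n_arrangements
    else:
        rng = np.random.default_rng(seed)
        perm_sums = np.empty(n_perm)
        for i in range(n_perm):
            perm_sums[i] = values[rng.choice(n, size=k, replace=False)].sum()
        diffs = diff_from_island_sum(perm_sums)
        p = (1 + tail_hits(diffs)) / (1 + n_perm)
        method, n_used = "sampled", n_perm
    anova_p = float(sps.f_oneway(values[is_island], values[~is_island]).pvalue) \
        if k >= 2 and n - k >= 2 else float("nan")
    return RandomizationResult(
        observed_diff=float(observed), p_value=float(p), n_permutations=n_used,
        direction="elevated" if observed > 0 else "reduced",
        method=method, anova_p=anova_p)


def compare_island_stats(records: pd.DataFrame, islands,
                         stats=("pi_a", "pi_b", "dxy", "n_snps",
                                "tajd_a", "tajd_b")) -> pd.DataFrame:
    """Island vs background summary with two-sided rank-sum p-values.

    One row per statistic: island mean/median, background mean/median, and
    the Mann-Whitney U test p-value comparing the two sets of windows.
    """
    if isinstance(islands, IslandCallSet):
        islands = islands.window_set
    islands = set(islands)
    keys = _window_tuples(records)
    is_island = np.array([k in islands for k in keys])
    rows = []
    for stat in stats:
        v = records[stat].to_numpy(dtype=float)
        fin = np.isfinite(v)
        isl = v[fin & is_island]
        bg = v[fin & ~is_island]
        if isl.size and bg.size:
            p = float(sps.mannwhitneyu(isl, bg, alternative="two-sided").pvalue)
        else:
            p = float("nan")
        rows.append({
            "stat": stat, "n_island": isl.size, "n_background": bg.size,
            "island_mean": float(isl.mean()) if isl.size else np.nan,
            "island_median": float(np.median(isl)) if isl.size else np.nan,
            "background_mean": float(bg.mean()) if bg.size else np.nan,
            "background_median": float(np.median(bg)) if bg.size else np.nan,
            "ranksum_p": p,
        })
    return pd.DataFrame(rows)
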