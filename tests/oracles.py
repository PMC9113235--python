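"""Independent brute-force implementations used as test oracles.

Everything here is coded directly from first principles (pairwise-difference
counts, the Weir & Cockerham 1984 component formulas, Tajima 1989 constants,
explicit pair loops) and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def pi_pairwise(dosages: np.ndarray, ploidy: np.ndarray, length: int) -> float:
    """Per-bp pi as the average fraction of differing allele-copy pairs."""
    total = 0.0
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        obs = col != MISSING
        n = int(ploidy[obs].sum())
        if n < 2:
            continue
        ac = int(col[obs].sum())
        pairs = n * (n - 1) / 2
        total += ac * (n - ac) / pairs
    return total / length


def wc_fst_site_diploid(dosA: np.ndarray, dosB: np.ndarray):
    """Weir & Cockerham (1984) a, b, c for one biallelic site, two diploid pops.

    Direct transcription of the two-allele, r-population formulas with r = 2,
    using observed genotype (heterozygote) frequencies.
    """
    r = 2
    ns = []
    ps = []
    hs = []
    for dos in (dosA, dosB):
        dos = dos[dos != MISSING]
        n_i = len(dos)
        p_i = dos.sum() / (2 * n_i)
        h_i = np.sum(dos == 1) / n_i
        ns.append(n_i)
        ps.append(p_i)
        hs.append(h_i)
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n ** 2 for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def wc_fst_window_diploid(dosA: np.ndarray, dosB: np.ndarray) -> float:
    """Ratio-of-sums window FST over usable (polymorphic-overall) sites."""
    num = den = 0.0
    for j in range(dosA.shape[1]):
        colA, colB = dosA[:, j], dosB[:, j]
        oa, ob = colA != MISSING, colB != MISSING
        if oa.sum() < 2 or ob.sum() < 2:
            continue
        pool = np.concatenate([colA[oa], colB[ob]])
        tot = pool.sum()
        if tot == 0 or tot == 2 * len(pool):
            continue
        a, b, c = wc_fst_site_diploid(colA, colB)
        num += a
        den += a + b + c
    return num / den if den else float("nan")


def tajimas_d_oracle(dosages: np.ndarray, ploidy: np.ndarray) -> float:
    """Tajima (1989) D with constants recomputed here from the harmonic sums."""
    seg_p = []
    ns = []
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        obs = col != MISSING
        n = int(ploidy[obs].sum())
        if n < 2:
            continue
        ac = int(col[obs].sum())
        if 0 < ac < n:
            seg_p.append((n, ac))
            ns.append(n)
    s = len(seg_p)
    if s == 0:
        return float("nan")
    n = min(ns)
    if n < 4:
        return float("nan")
    pi_abs = sum(2 * (ac / nn) * (1 - ac / nn) * nn / (nn - 1) for nn, ac in seg_p)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi_abs - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def dxy_oracle(dosA, ploidyA, dosB, ploidyB, length: int) -> float:
    """Per-bp between-population divergence by an explicit per-site loop."""
    total = 0.0
    any_site = dosA.shape[1] > 0
    used = 0
    for j in range(dosA.shape[1]):
        colA, colB = dosA[:, j], dosB[:, j]
        oa, ob = colA != MISSING, colB != MISSING
        nA, nB = int(ploidyA[oa].sum()), int(ploidyB[ob].sum())
        if nA == 0 or nB == 0:
            continue
        pA = colA[oa].sum() / nA
        pB = colB[ob].sum() / nB
        total += pA * (1 - pB) + pB * (1 - pA)
        used += 1
    if any_site and used == 0:
        return float("nan")
    return total / length


def r2_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, from the definition."""
    x = x.astype(float)
    y = y.astype(float)
    cx = x - x.mean()
    cy = y - y.mean()
    return float((cx @ cy) ** 2 / ((cx @ cx) * (cy @ cy)))


def kinship_loop(dosages: np.ndarray, ploidy: np.ndarray) -> np.ndarray:
    """Simple-matching kinship by an explicit pairwise double loop."""
    n = dosages.shape[0]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            scores = []
            for s in range(dosages.shape[1]):
                di, dj = dosages[i, s], dosages[j, s]
                if di == MISSING or dj == MISSING:
                    continue
                scores.append(1 - abs(di / ploidy[i] - dj / ploidy[j]))
            K[i, j] = sum(scores) / len(scores)
    return K


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x vs y by counting pairs (ties count one half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def sieve_filter(depth, mq, maf, missingness, thresholds) -> np.ndarray:
    """Rule-by-rule retention mask, coded independently of the package."""
    keep = np.ones(len(depth), dtype=bool)
    for i in range(len(depth)):
        if thresholds.get("min_depth") is not None and depth[i] < thresholds["min_depth"]:
            keep[i] = False
        elif thresholds.get("max_depth") is not None and depth[i] > thresholds["max_depth"]:
            keep[i] = False
        elif thresholds.get("min_mq") is not None and mq[i] < thresholds["min_mq"]:
            keep[i] = False
        elif thresholds.get("max_missing") is not None and missingness[i] > thresholds["max_missing"]:
            keep[i] = False
        elif thresholds.get("min_maf") is not None and (
                np.isnan(maf[i]) or maf[i] < thresholds["min_maf"]):
            keep[i] = False
    return keep


def ols_assoc(y: np.ndarray, covariates: np.ndarray, x: np.ndarray):
    """Per-SNP ordinary least squares with a t-test on the marker coefficient."""
    from scipy import stats as sps

    X = np.column_stack([covariates, x])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[-1, -1])
    t = beta[-1] / se
    pval = 2 * sps.t.sf(abs(t), n - p)
    return beta[-1], se, t, pval
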