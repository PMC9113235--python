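"""Mixed-linear-model association scan for a binary (0/1 coded) trait.

The model is y = X*alpha + S*beta + u + e with u ~ (0, sigma_g^2 K) and
e ~ (0, sigma_e^2 I): alpha the per-marker fixed effect, S an intercept plus
top principal components correcting population structure, and K a kinship
matrix of simple matching coefficients. Variance components are estimated
once on the null (no-marker) model by REML through a single eigendecomposition
of K (the EMMAX approximation); each SNP is then tested by generalized least
squares with a Wald t-test on the marker coefficient. The binary trait is
analyzed as quantitative, the standard LMM treatment of presence/absence
traits in GWAS of strongly structured cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .core import MISSING, GenotypeMatrix

__all__ = [
    "kinship_simple_matching",
    "pc_covariates",
    "mlm_assoc",
    "genomic_inflation",
]


def kinship_simple_matching(geno: GenotypeMatrix) -> np.ndarray:
    """Kinship matrix of ploidy-normalized simple matching coefficients.

    K_ij is the mean over sites non-missing in both samples of
    1 - |d_i/p_i - d_j/p_j|. For diploid pairs this reduces to the classic
    simple-matching scores 1 / 0.5 / 0 for identical / half-matching /
    opposite genotypes. Raises if some pair shares no genotyped site.
    """
    if geno.n_samples < 2 or geno.n_sites < 1:
        raise ValueError("kinship needs >= 2 samples and >= 1 site")
    x = geno.dosages.astype(float)
    x[geno.dosages == MISSING] = np.nan
    x /= geno.ploidy[:, None]
    n = geno.n_samples
    K = np.empty((n, n))
    for i in range(n):
        diff = np.abs(x - x[i][None, :])          # (n, sites) with NaNs
        shared = np.sum(~np.isnan(diff), axis=1)
        if (shared == 0).any():
            j = int(np.nonzero(shared == 0)[0][0])
            raise ValueError(
                f"samples {geno.sample_ids[i]!r} and {geno.sample_ids[j]!r} "
                "share no non-missing site")
        K[i] = 1.0 - np.nanmean(diff, axis=1)
    return 0.5 * (K + K.T)  # exact symmetry


def pc_covariates(geno: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Intercept plus the top ``k`` principal components of the dosage matrix.

    Dosages are mean-imputed per site and column-centered before the SVD.
    The sign of each PC is fixed by making its largest-magnitude site loading
    positive. ``k=0`` returns the intercept-only matrix.
    """
    n = geno.n_samples
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= n:
        raise ValueError("need more samples than requested components")
    cols = [np.ones((n, 1))]
    if k > 0:
        x = geno.dosages.astype(float)
        x[geno.dosages == MISSING] = np.nan
        mu = np.nanmean(x, axis=0)
        nan_mask = np.isnan(x)
        if nan_mask.any():
            x[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
        x -= x.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        if int(np.sum(s > s[0] * 1e-12)) < k:
            raise ValueError("dosage matrix is rank-deficient for requested PCs")
        scores = u[:, :k] * s[:k]
        for j in range(k):
            lead = np.argmax(np.abs(vt[j]))
            if vt[j, lead] < 0:
                scores[:, j] = -scores[:, j]
        cols.append(scores)
    out = np.hstack(cols)
    if np.linalg.matrix_rank(out) < out.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    return out


def _reml_delta(yr: np.ndarray, sr: np.ndarray, d: np.ndarray):
    """REML estimate of delta = sigma_e^2 / sigma_g^2 in the rotated model.

    ``yr``/``sr`` are the eigen-rotated response and null design; ``d`` the
    kinship eigenvalues. Returns (delta, sigma_g2, sigma_e2).
    """
    n, p = sr.shape
    logdet_ss = np.linalg.slogdet(sr.T @ sr)[1]

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        v = d + delta
        w = 1.0 / v
        a = sr.T @ (sr * w[:, None])
        coef = np.linalg.solve(a, sr.T @ (yr * w))
        r = yr - sr @ coef
        rss = float(np.sum(w * r * r))
        sg2 = rss / (n - p)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sg2) + np.sum(np.log(v))
                     + np.linalg.slogdet(a)[1] - logdet_ss + (n - p))
        return -ll

    grid = np.linspace(np.log(1e-5), np.log(1e5), 81)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(res.x))
    v = d + delta
    w = 1.0 / v
    a = sr.T @ (sr * w[:, None])
    coef = np.linalg.solve(a, sr.T @ (yr * w))
    r = yr - sr @ coef
    sg2 = float(np.sum(w * r * r)) / (n - p)
    return delta, sg2, sg2 * delta


def mlm_assoc(geno: GenotypeMatrix, phenotype, K: np.ndarray | None = None,
              S: np.ndarray | None = None, sites: pd.DataFrame | None = None,
              h2: float | None = None) -> pd.DataFrame:
    """Per-SNP mixed-model association tests.

    Parameters
    ----------
    phenotype
        Array aligned with ``geno.sample_ids``, or a DataFrame with
        ``sample_id`` and ``value`` columns.
    K
        Kinship matrix; identity when None (plain weighted regression).
    S
        Fixed-effect covariates including the intercept; intercept-only
        when None.
    h2
        Fix the heritability sigma_g^2/(sigma_g^2+sigma_e^2) instead of
        estimating it by REML; ``h2=0`` reduces every test to ordinary least
        squares exactly.

    Returns a DataFrame (beta, se, stat, p per tested SNP; monomorphic or
    collinear SNPs flagged with NaN) whose ``attrs`` carry the variance
    components and the genomic-inflation factor of the scan.
    """
    if isinstance(phenotype, pd.DataFrame):
        pheno = phenotype.set_index("sample_id")["value"]
        y = pheno.reindex(geno.sample_ids).to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError("phenotype missing for some samples")
    else:
        y = np.asarray(phenotype, dtype=float)
    n = geno.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length does not match samples")
    if K is None:
        K = np.eye(n)
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship matrix has wrong shape")
    if S is None:
        S = np.ones((n, 1))
    S = np.asarray(S, dtype=float)

    # stabilize: simple-matching matrices can be numerically indefinite
    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin < 0:
        K = K + (1e-6 - eigmin) * np.eye(n)
    d, u = np.linalg.eigh(K)
    d = np.clip(d, 0, None)
    yr = u.T @ y
    sr = u.T @ S

    if h2 is None:
        delta, sg2, se2 = _reml_delta(yr, sr, d)
    elif h2 <= 0:
        delta, sg2, se2 = np.inf, 0.0, float(np.var(y))
    else:
        delta = (1 - h2) / h2
        sg2 = se2 = np.nan
    w = np.ones(n) if not np.isfinite(delta) else 1.0 / (d + delta)

    x_all = geno.dosages.astype(float)
    miss = geno.dosages == MISSING
    rows = []
    sw = sr * w[:, None]
    for j in range(geno.n_sites):
        xj = x_all[:, j].copy()
        m = miss[:, j]
        if m.all():
            rows.append((np.nan, np.nan, np.nan, np.nan, "all_missing"))
            continue
        if m.any():
            xj[m] = xj[~m].mean()      # mean imputation, this SNP only
        if np.ptp(xj) == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, "monomorphic"))
            continue
        xr = u.T @ xj
        X = np.column_stack([sr, xr])
        Xw = np.column_stack([sw, xr * w])
        A = Xw.T @ X                   # X' W X
        rhs = Xw.T @ yr
        try:
            coef = np.linalg.solve(A, rhs)
            cov_unscaled = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            rows.append((np.nan, np.nan, np.nan, np.nan, "singular"))
            continue
        resid = yr - X @ coef
        dof = n - X.shape[1]
        sigma2 = float(np.sum(w * resid * resid)) / dof
        se = float(np.sqrt(sigma2 * cov_unscaled[-1, -1]))
        if not np.isfinite(se) or se <= 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, "singular"))
            continue
        beta = float(coef[-1])
        t = beta / se
        p = float(2 * sps.t.sf(abs(t), dof))
        rows.append((beta, se, t, max(p, np.finfo(float).tiny), "ok"))

    out = pd.DataFrame(rows, columns=["beta", "se", "stat", "p", "status"])
    if sites is not None:
        out.insert(0, "contig", sites["contig"].to_numpy())
        out.insert(1, "pos", sites["pos"].to_numpy())
    out.attrs["sigma_g2"] = sg2
    out.attrs["sigma_e2"] = se2
    out.attrs["delta"] = delta
    pvals = out["p"].to_numpy(dtype=float)
    fin = np.isfinite(pvals)
    out.attrs["lambda_gc"] = genomic_inflation(pvals[fin]) if fin.sum() >= 10 else np.nan
    return out


def genomic_inflation(pvalues) -> float:
    """Genomic-inflation factor lambda.

    p-values are converted to chi-square(1 df) statistics; lambda is their
    median over the chi-square(1) median 0.4549. Lambda near 1 indicates the
    structure correction is adequate.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 10:
        raise ValueError("genomic inflation needs at least 10 finite p-values")
    chi2 = sps.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / sps.chi2.isf(0.5, df=1))
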