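"""Per-phenotype genome scans.

Linear mixed model with identity-by-state (IBS) kinship in the
EMMAX/P3D style — variance components are estimated once on the null
model by REML through an eigendecomposition of K, then every SNP is
tested by generalised least squares in the rotated space — plus an
uncorrected per-SNP ordinary-least-squares scan, MAF filtering,
variance explained, and Box-Cox preparation of expression phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import ExpressionPhenotype, GenotypeMatrix

#: eigenvalue floor applied to K so H = h*K + (1-h)*I stays invertible
EIGEN_FLOOR = 1e-8

#: smallest p-value reported (underflow cap)
P_FLOOR = 1e-300


@dataclass
class AssocResult:
    """Per-SNP scan output plus null-model variance components."""

    table: pd.DataFrame  # snp_id, chrom, pos, maf, beta, pvalue
    sigma_g2: float
    sigma_e2: float
    model: str  # "lmm" | "lm"

    @property
    def neglog10p(self) -> np.ndarray:
        return -np.log10(self.table["pvalue"].to_numpy())


def ibs_kinship(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pairwise fraction of identical alleles between lines.

    Missing genotypes (coded -1) are excluded pairwise; a line pair
    with no jointly called SNP is an error.
    """
    G = genotypes.G
    if G.shape[0] < 2 or G.shape[1] < 1:
        raise ValueError("need >= 2 lines and >= 1 SNP")
    called = (G >= 0).astype(np.float64)
    Gf = np.where(G >= 0, G, 0).astype(np.float64)
    joint = called @ called.T
    if np.any(joint == 0):
        raise ValueError("a line pair shares no jointly called SNPs")
    # matches = joint - sum|gi-gj| over jointly-called SNPs (0/1 codes)
    cross = Gf @ Gf.T
    ones_i = (Gf * called) @ called.T
    ones_j = called @ (Gf * called).T
    mismatches = ones_i + ones_j - 2.0 * cross
    K = (joint - mismatches) / joint
    return K


def maf_filter(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with minor allele frequency strictly above threshold."""
    if not (0.0 < threshold < 0.5):
        raise ValueError("threshold must be in (0, 0.5)")
    keep = genotypes.maf() > threshold
    return genotypes.subset_snps(keep)


def _reml_loglik(h: float, lam: np.ndarray, ystar: np.ndarray, Xstar: np.ndarray) -> float:
    """Restricted log-likelihood profile in the heritability ratio
    h = sigma_g^2 / (sigma_g^2 + sigma_e^2), given eigenvalues of K."""
    n, q = Xstar.shape
    w = h * lam + (1.0 - h)
    Xw = Xstar / w[:, None]
    XtWX = Xstar.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    rss = float(r @ (r / w))
    sigma2 = rss / (n - q)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    return -0.5 * (
        (n - q) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xwx + (n - q)
    )


def _fit_null_reml(
    y: np.ndarray, K: np.ndarray, X: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Eigendecompose K, rotate, and maximise the REML profile over the
    variance ratio.  Returns (eigvecs U, eigvals lam, h, sigma_g2, sigma_e2)."""
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semi-definite")
    lam = np.clip(lam, EIGEN_FLOOR, None)
    ystar = U.T @ y
    Xstar = U.T @ X

    grid = np.linspace(0.0, 0.99, 34)
    lls = np.array([_reml_loglik(h, lam, ystar, Xstar) for h in grid])
    i = int(np.argmax(lls))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda h: -_reml_loglik(h, lam, ystar, Xstar),
        bounds=(lo, hi),
        method="bounded",
    )
    h = float(res.x)
    w = h * lam + (1.0 - h)
    Xw = Xstar / w[:, None]
    beta = np.linalg.solve(Xstar.T @ Xw, Xw.T @ ystar)
    r = ystar - Xstar @ beta
    sigma2 = float(r @ (r / w)) / (n - X.shape[1])
    return U, lam, h, h * sigma2, (1.0 - h) * sigma2


def _impute_mean(G: np.ndarray) -> np.ndarray:
    """Mean-impute missing genotype calls per SNP."""
    Gf = G.astype(np.float64)
    miss = G < 0
    if miss.any():
        with np.errstate(invalid="ignore"):
            col_mean = np.where(
                (~miss).sum(0) > 0,
                np.where(G >= 0, Gf, 0).sum(0) / np.maximum((~miss).sum(0), 1),
                0.0,
            )
        Gf = np.where(miss, col_mean[None, :], Gf)
    return Gf


def _gls_scan(
    y: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray | None,
    intercept: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised single-SNP regressions y ~ intercept + g, optionally
    in a whitened space (weights = residual variances per coordinate).
    ``intercept`` defaults to a ones column; a rotated space must pass
    its rotated intercept.  Returns (beta, two-sided t-test p) per SNP."""
    n, m = G.shape
    if weights is None:
        sw = np.ones(n)
    else:
        sw = 1.0 / np.sqrt(weights)
    ones = np.ones(n) if intercept is None else intercept
    yw = y * sw
    ones_w = ones * sw
    Gw = G * sw[:, None]

    # project out the (whitened) intercept
    denom_1 = float(ones_w @ ones_w)
    y_res = yw - ones_w * (ones_w @ yw / denom_1)
    G_res = Gw - ones_w[:, None] * (ones_w @ Gw / denom_1)

    gtg = np.einsum("ij,ij->j", G_res, G_res)
    gty = G_res.T @ y_res
    ok = gtg > 1e-12
    beta = np.full(m, np.nan)
    pval = np.ones(m)
    beta[ok] = gty[ok] / gtg[ok]
    rss = float(y_res @ y_res) - beta[ok] ** 2 * gtg[ok]
    df = n - 2
    rss = np.maximum(rss, 0.0)
    se2 = rss / df / gtg[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[ok] / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval[ok] = np.clip(p, P_FLOOR, 1.0)
    return beta, pval


def lmm_scan(
    phenotype: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    K: np.ndarray,
) -> AssocResult:
    """Mixed-model scan y = mu + x*beta + u + e with cov(u) = sigma_g^2 K.

    Variance components come from one REML fit of the null model
    (eigendecomposition of K); each SNP is then tested by GLS in the
    rotated space with those components fixed (P3D/EMMAX
    approximation), Wald two-sided p.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    if y.size != genotypes.n_lines or K.shape != (y.size, y.size):
        raise ValueError("phenotype, genotypes and K must share the line panel")
    U, lam, h, sg2, se2 = _fit_null_reml(y, K)
    w = h * lam + (1.0 - h)
    ystar = U.T @ y
    Gstar = U.T @ _impute_mean(genotypes.G)
    beta, pval = _gls_scan(ystar, Gstar, w, intercept=U.T @ np.ones_like(y))
    table = genotypes.snps[["snp_id", "chrom", "pos", "maf"]].copy()
    table["beta"] = beta
    table["pvalue"] = pval
    return AssocResult(table=table, sigma_g2=sg2, sigma_e2=se2, model="lmm")


def lm_scan(
    phenotype: np.ndarray | pd.Series, genotypes: GenotypeMatrix
) -> AssocResult:
    """Per-SNP ordinary least squares without structure correction,
    two-sided t-test on the slope."""
    y = np.asarray(phenotype, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype")
    beta, pval = _gls_scan(y, _impute_mean(genotypes.G), None)
    table = genotypes.snps[["snp_id", "chrom", "pos", "maf"]].copy()
    table["beta"] = beta
    table["pvalue"] = pval
    var_e = float(np.var(y, ddof=1))
    return AssocResult(table=table, sigma_g2=0.0, sigma_e2=var_e, model="lm")


def boxcox_transform(expr: ExpressionPhenotype) -> ExpressionPhenotype:
    """Box-Cox the expression phenotype toward normality.

    lambda is chosen on the grid [-2, 2] (step 0.01) maximising the
    profile log-likelihood; the transform is (y^l - 1)/l, log y at l=0.
    """
    y = expr.values.to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
    lls = np.array([stats.boxcox_llf(l, y) for l in grid])
    lam = float(grid[int(np.argmax(lls))])
    if lam == 0.0:
        t = np.log(y)
    else:
        t = (y**lam - 1.0) / lam
    return ExpressionPhenotype(
        values=expr.values,
        lambda_=lam,
        transformed=pd.Series(t, index=expr.values.index, name=expr.values.name),
    )


def variance_explained(snp: np.ndarray, phenotype: np.ndarray) -> float:
    """Squared Pearson correlation between a genotype column and a
    phenotype — the fraction of phenotypic variance the SNP explains."""
    g = np.asarray(snp, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.size != y.size:
        raise ValueError("vectors must be aligned")
    if np.ptp(g) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    r = np.corrcoef(g, y)[0, 1]
    return float(r**2)


def inflation_factor(pvalues: np.ndarray) -> float:
    """Genomic-control lambda: median observed 1-df chi-square over its
    null median (0.4549)."""
    chi = stats.chi2.isf(np.asarray(pvalues, dtype=float), df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
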