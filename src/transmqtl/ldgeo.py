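"""Inter-locus linkage disequilibrium and geographic clines.

D' between two haploid-coded SNPs, an empirical null built from SNPs
matched on allele frequency (excluding both focal chromosomes),
one-sided Fisher's exact depletion tests on the 2x2 haplotype table,
multi-locus genotype-combination frequencies against the random-mating
expectation, targeted-TE methylation averages, longitude regressions
with optional allele regression-out, and BLUP structure correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import _fit_null_reml
from .config import LON_RANGE
from .containers import GenotypeMatrix, LineMetadataTable, MethylationPhenotype


@dataclass
class LdPair:
    """Haplotype frequencies and LD summaries for one SNP pair."""

    n_AB: int  # both alternative
    n_Ab: int  # A alternative only
    n_aB: int
    n_ab: int
    p_A: float
    p_B: float
    D: float
    Dmax: float
    d_prime: float
    r2: float

    @property
    def n(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    def haplotype_table(self) -> np.ndarray:
        """2x2 table with the double-alternative (double-carrier)
        haplotype in the top-left cell."""
        return np.array([[self.n_AB, self.n_Ab], [self.n_aB, self.n_ab]])


def d_prime(snpA: np.ndarray, snpB: np.ndarray) -> LdPair:
    """Signed standardised LD, D' = D / Dmax.

    Haploid lines expose haplotypes directly: D = p_AB - p_A * p_B with
    A/B the alternative alleles.  Dmax is min(p_A(1-p_B), (1-p_A)p_B)
    for D > 0 and min(p_A p_B, (1-p_A)(1-p_B)) for D < 0; D = 0 maps to
    D' = 0.
    """
    a = np.asarray(snpA).astype(int)
    b = np.asarray(snpB).astype(int)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic SNP")
    n = a.size
    n_AB = int(np.sum((a == 1) & (b == 1)))
    n_Ab = int(np.sum((a == 1) & (b == 0)))
    n_aB = int(np.sum((a == 0) & (b == 1)))
    n_ab = n - n_AB - n_Ab - n_aB
    p_A, p_B = a.mean(), b.mean()
    D = n_AB / n - p_A * p_B
    if D > 0:
        Dmax = min(p_A * (1 - p_B), (1 - p_A) * p_B)
    elif D < 0:
        Dmax = min(p_A * p_B, (1 - p_A) * (1 - p_B))
    else:
        Dmax = 0.0
    dp = D / Dmax if Dmax > 0 else 0.0
    r = np.corrcoef(a, b)[0, 1]
    return LdPair(
        n_AB=n_AB, n_Ab=n_Ab, n_aB=n_aB, n_ab=n_ab,
        p_A=float(p_A), p_B=float(p_B),
        D=float(D), Dmax=float(Dmax), d_prime=float(dp), r2=float(r**2),
    )


def fisher_exact_1sided(table) -> float:
    """One-sided Fisher's exact test for depletion of the
    double-carrier (top-left) cell of a 2x2 haplotype table: the
    hypergeometric probability of the observed or a more extreme
    deficit."""
    t = np.asarray(table)
    if np.any(t < 0):
        raise ValueError("negative counts")
    _, p = stats.fisher_exact(t, alternative="less")
    return float(p)


@dataclass
class MatchedNullResult:
    """Matched-MAF empirical null for an observed inter-locus D'."""

    observed: LdPair
    null_d_prime: np.ndarray
    matched_snp_ids: list[str]
    p_empirical: float
    fisher_p_observed: float
    fisher_p_null: np.ndarray


def matched_maf_null(
    genotypes: GenotypeMatrix,
    target_snp: str | int,
    partner_snp: str | int,
    maf_tol: float = 0.005,
    min_matched: int = 50,
    alternative: str = "depletion",
) -> MatchedNullResult:
    """Is the observed target-partner D' extreme for SNPs of that
    frequency?

    Collects every SNP whose MAF matches the partner's within
    ``maf_tol`` on chromosomes other than both focal SNPs' chromosomes,
    computes D'(target, matched SNP) for each, and reports the
    one-sided empirical p of the observed D':
    (1 + #{null as or more extreme}) / (n_matched + 1).

    The direction is fixed a priori by ``alternative``: "depletion"
    (default; null D' <= observed counts as extreme, testing repulsion
    between the non-reference haplotypes) or "excess".  Fixing the
    side keeps the empirical p uniform under independence; choosing it
    from the observed sign would double-dip and concentrate null p
    below 0.5.  One-sided Fisher's exact depletion p-values accompany
    every pair.
    """
    ti, pi = genotypes.snp_index(target_snp), genotypes.snp_index(partner_snp)
    g_t = genotypes.column(ti)
    g_p = genotypes.column(pi)
    obs = d_prime(g_t, g_p)
    fisher_obs = fisher_exact_1sided(obs.haplotype_table())

    maf = genotypes.maf()
    partner_maf = maf[pi]
    chrom = genotypes.snps["chrom"].to_numpy()
    excluded = {chrom[ti], chrom[pi]}
    cand = np.flatnonzero(
        (np.abs(maf - partner_maf) <= maf_tol)
        & ~np.isin(chrom, list(excluded))
    )
    if cand.size < min_matched:
        raise ValueError(
            f"only {cand.size} matched SNPs (need >= {min_matched}); "
            "widen maf_tol"
        )
    null_dp = np.empty(cand.size)
    null_fp = np.empty(cand.size)
    for i, j in enumerate(cand):
        pair = d_prime(g_t, genotypes.column(int(j)))
        null_dp[i] = pair.d_prime
        null_fp[i] = fisher_exact_1sided(pair.haplotype_table())
    if alternative == "depletion":
        extreme = np.sum(null_dp <= obs.d_prime)
    elif alternative == "excess":
        extreme = np.sum(null_dp >= obs.d_prime)
    else:
        raise ValueError("alternative must be 'depletion' or 'excess'")
    p_emp = (1.0 + extreme) / (cand.size + 1.0)
    return MatchedNullResult(
        observed=obs,
        null_d_prime=null_dp,
        matched_snp_ids=list(genotypes.snps["snp_id"].iloc[cand]),
        p_empirical=float(p_emp),
        fisher_p_observed=fisher_obs,
        fisher_p_null=null_fp,
    )


def genotype_combination_frequencies(
    genotypes: GenotypeMatrix, snps: list
) -> pd.DataFrame:
    """Observed multi-locus genotype counts vs the random-mating
    (independence) expectation n * prod(per-locus allele frequencies);
    reports the observed/expected ratio per combination."""
    if len(snps) < 1:
        raise ValueError("need at least one SNP")
    cols = [genotypes.column(s) for s in snps]
    n = genotypes.n_lines
    freqs = [c.mean() for c in cols]
    combos = np.stack(cols, axis=1)
    rows = []
    for combo in np.ndindex(*([2] * len(snps))):
        obs = int(np.sum(np.all(combos == np.array(combo), axis=1)))
        expected = n * float(
            np.prod([f if a == 1 else 1 - f for a, f in zip(combo, freqs)])
        )
        rows.append(
            {
                "combination": "/".join(str(a) for a in combo),
                "observed": obs,
                "expected": expected,
                "ratio": obs / expected if expected > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def targeted_te_average(
    pheno: MethylationPhenotype,
    te_neglog10p: pd.Series,
    threshold_log10p: float = 6.0,
) -> tuple[pd.Series, list[str]]:
    """Per-line mean methylation over the TEs whose focal-SNP
    association reaches -log10 p >= threshold (the scan-defined
    targeted set).  Returns (per-line means, TE set)."""
    hits = te_neglog10p.index[te_neglog10p >= threshold_log10p]
    te_set = [t for t in pheno.values.columns if t in set(hits)]
    if not te_set:
        raise ValueError(
            f"no TE reaches -log10 p >= {threshold_log10p}; lower the "
            "threshold for small panels"
        )
    return pheno.values[te_set].mean(axis=1), te_set


@dataclass
class ClineResult:
    """Longitude regression of a per-line value."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    covariate: str  # "none" | "allele" | "blup"


def longitude_cline(
    values: pd.Series,
    metadata: LineMetadataTable,
    covariate_snp: np.ndarray | None = None,
    lon_range: tuple[float, float] = LON_RANGE,
    min_lines: int = 10,
) -> ClineResult:
    """OLS of a per-line value on longitude within the sampling window.

    With ``covariate_snp`` given, the value is first regressed on the
    genotype and the residuals are regressed on longitude — the
    "after regressing out the focal allele" design for testing whether
    a cline is allele-mediated.
    """
    meta = metadata.table.set_index("line_id")
    lon = meta.loc[values.index, "longitude"].to_numpy(dtype=float)
    ok = (lon >= lon_range[0]) & (lon <= lon_range[1]) & ~values.isna().to_numpy()
    if ok.sum() < min_lines:
        raise ValueError(f"only {int(ok.sum())} lines in the longitude window")
    y = values.to_numpy(dtype=float)[ok]
    x = lon[ok]
    covariate = "none"
    if covariate_snp is not None:
        g = np.asarray(covariate_snp, dtype=float)[ok]
        if np.ptp(g) > 0:
            slope_g = np.cov(g, y, ddof=0)[0, 1] / np.var(g)
            y = y - slope_g * (g - g.mean())
        covariate = "allele"
    res = stats.linregress(x, y)
    return ClineResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(ok.sum()),
        covariate=covariate,
    )


def blup_correct(values: pd.Series | np.ndarray, K: np.ndarray) -> np.ndarray:
    """Structure-correct a per-line value by subtracting its BLUP.

    Fits y = mu + u + e with cov(u) = sigma_g^2 K by REML, predicts
    u by BLUP, and returns y - mu - u_hat.  With sigma_g^2 estimated
    at 0 this reduces to plain centering.
    """
    y = np.asarray(values, dtype=float)
    U, lam, h, sg2, se2 = _fit_null_reml(y, K)
    # GLS intercept under the fitted covariance
    w = h * lam + (1.0 - h)
    ystar = U.T @ y
    ones_star = U.T @ np.ones_like(y)
    mu = float((ones_star / w) @ ystar / ((ones_star / w) @ ones_star))
    resid = y - mu
    # BLUP: u_hat = h*K (h*K + (1-h)I)^-1 (y - mu), in the eigenbasis
    shrink = h * lam / w
    u_hat = U @ (shrink * (U.T @ resid))
    out = resid - u_hat
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out
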