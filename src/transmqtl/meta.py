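"""Combining per-phenotype scans into genome-wide peaks.

Fisher's method pools the k per-phenotype p-values at each SNP into
X^2 = -2 * sum(ln p_i) ~ chi-square with 2k df.  The significance
threshold is calibrated by an a priori-gene enrichment FDR (the ratio
of background to candidate exceedance fractions over a descending
threshold grid), and correlated peaks are pruned greedily by r^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

P_CLAMP = 1e-300


@dataclass
class MetaResult:
    """Per-SNP Fisher combination across k component scans."""

    table: pd.DataFrame  # snp_id, chrom, pos, maf, x2, df, pvalue
    k: int

    @property
    def neglog10p(self) -> np.ndarray:
        return -np.log10(self.table["pvalue"].to_numpy())


def fisher_combine(pvalue_matrix, snps: pd.DataFrame | None = None) -> MetaResult:
    """Fisher's method per SNP over component scans.

    ``pvalue_matrix`` is (n_snps, k) with each column one scan's
    p-values in (0, 1].  Exact zeros are clamped to 1e-300 with a
    warning; p > 1 is an error.  Combined p is the upper-tail
    chi-square probability at X^2 with 2k degrees of freedom.
    """
    P = np.atleast_2d(np.asarray(pvalue_matrix, dtype=float))
    if P.shape[1] < 1:
        raise ValueError("need at least one component scan")
    if np.any(P > 1.0) or np.any(P < 0.0) or np.any(np.isnan(P)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(P == 0.0):
        nz = int((P == 0.0).sum())
        warnings.warn(f"{nz} zero p-value(s) clamped to {P_CLAMP:g}", stacklevel=2)
        P = np.where(P == 0.0, P_CLAMP, P)
    k = P.shape[1]
    x2 = -2.0 * np.log(P).sum(axis=1)
    combined = stats.chi2.sf(x2, df=2 * k)
    combined = np.clip(combined, P_CLAMP, 1.0)
    if snps is None:
        table = pd.DataFrame({"snp_id": np.arange(P.shape[0]).astype(str)})
    else:
        table = snps[[c for c in ("snp_id", "chrom", "pos", "maf") if c in snps]].copy()
    table["x2"] = x2
    table["df"] = 2 * k
    table["pvalue"] = combined
    return MetaResult(table=table, k=k)


def gene_level_significance(
    meta: MetaResult, genes: pd.DataFrame, window: int = 15_000, maf_min: float = 0.05
) -> pd.DataFrame:
    """Best combined p within gene span +/- window, per gene.

    Only SNPs with MAF strictly above ``maf_min`` contribute; the
    window is closed (a SNP exactly ``window`` bp from the span
    counts).  Genes with no in-window SNP get NaN and drop out of the
    FDR computation.
    """
    snps = meta.table
    if "maf" in snps:
        snps = snps[snps["maf"] > maf_min]
    rows = []
    for g in genes.itertuples(index=False):
        lo, hi = g.start - window, g.end + window
        sel = snps[(snps["chrom"] == g.chrom) & (snps["pos"] >= lo) & (snps["pos"] <= hi)]
        best = sel["pvalue"].min() if len(sel) else np.nan
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "best_p": best,
                "score": -np.log10(best) if best == best else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FdrCurve:
    """Threshold grid with estimated FDR at each candidate threshold."""

    thresholds: np.ndarray
    fdr: np.ndarray
    threshold: float | None  # smallest qualifying -log10 p, None if none

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fdr": self.fdr})


def enrichment_fdr(
    gene_sig: pd.DataFrame,
    a_priori_ids,
    target_fdr: float = 0.2,
    min_apriori_hits: int = 3,
) -> FdrCurve:
    """Calibrate a -log10 p threshold by candidate-gene enrichment.

    For each candidate threshold t (the descending grid of observed
    gene scores), FDR(t) = fraction of background genes scoring >= t
    divided by the fraction of a priori genes scoring >= t, capped at
    1.  The ratio is treated as undefined (infinite) while fewer than
    ``min_apriori_hits`` a priori genes exceed t — with a denominator
    resting on one or two genes the estimate is pure noise and a lucky
    candidate gene at the top of the grid would otherwise declare a
    threshold under a completely exchangeable null.  Returns the
    smallest t with FDR <= ``target_fdr`` (None when no threshold
    qualifies) together with the full curve.
    """
    df = gene_sig.dropna(subset=["score"])
    a_priori = set(a_priori_ids)
    is_ap = df["gene_id"].isin(a_priori).to_numpy()
    if is_ap.sum() == 0:
        raise ValueError("no a priori gene with a non-missing score")
    scores = df["score"].to_numpy()
    ap_scores = scores[is_ap]
    bg_scores = scores[~is_ap]
    if bg_scores.size == 0:
        raise ValueError("no background genes")

    grid = np.unique(scores)[::-1]  # descending
    frac_bg = np.array([(bg_scores >= t).mean() for t in grid])
    n_ap_hits = np.array([(ap_scores >= t).sum() for t in grid])
    frac_ap = n_ap_hits / ap_scores.size
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            n_ap_hits >= min_apriori_hits, frac_bg / frac_ap, np.inf
        )
    fdr = np.where(np.isfinite(fdr), np.minimum(fdr, 1.0), np.inf)
    qualifying = grid[fdr <= target_fdr]
    threshold = float(qualifying.min()) if qualifying.size else None
    return FdrCurve(thresholds=grid, fdr=fdr, threshold=threshold)


def ld_r2(snpA: np.ndarray, snpB: np.ndarray) -> float:
    """Squared correlation of haploid allele indicators."""
    a = np.asarray(snpA, dtype=float)
    b = np.asarray(snpB, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("monomorphic SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


@dataclass
class PeakList:
    """LD-pruned peaks: retained SNPs plus the neighbours each absorbed."""

    peaks: pd.DataFrame  # snp_id, chrom, pos, x2, pvalue
    absorbed: dict[str, list[str]] = field(default_factory=dict)


def ld_prune(
    candidates: pd.DataFrame, genotypes: GenotypeMatrix, r2_cut: float = 0.2
) -> PeakList:
    """Greedy pruning of correlated candidate peaks.

    Candidates are visited by descending X^2 (ties broken by genomic
    order); a SNP is retained iff its r^2 with every already retained
    SNP is <= ``r2_cut``, otherwise it is absorbed by the retained SNP
    it correlates with most.
    """
    cand = candidates.sort_values(
        ["x2", "chrom", "pos"], ascending=[False, True, True]
    ).reset_index(drop=True)
    cols = {sid: genotypes.column(sid).astype(float) for sid in cand["snp_id"]}
    kept: list[int] = []
    absorbed: dict[str, list[str]] = {}
    for i, sid in enumerate(cand["snp_id"]):
        worst_r2, absorber = 0.0, None
        for j in kept:
            kid = cand.at[j, "snp_id"]
            r2 = ld_r2(cols[sid], cols[kid])
            if r2 > worst_r2:
                worst_r2, absorber = r2, kid
        if worst_r2 > r2_cut:
            absorbed.setdefault(absorber, []).append(sid)
        else:
            kept.append(i)
            absorbed.setdefault(sid, [])
    peaks = cand.iloc[kept].reset_index(drop=True)
    return PeakList(peaks=peaks, absorbed=absorbed)
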