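"""Allelic effect profiles and their validation against knockouts.

Per-TE differential methylation levels (DML) for a natural allele are
compared to a knockout panel by Spearman rank correlation; the null
distribution of that correlation is built by recomputing the profile
at randomly drawn SNPs genome-wide (1,500 by default).  Joint-genotype
metaplots and Welch's t-tests quantify additivity of two loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    EffectProfile,
    ExpressionPhenotype,
    GenotypeMatrix,
    MethylationPhenotype,
    MethylCountTable,
    MutantPanel,
)
from .summaries import metaplot_profile

#: central-body bins used for the "center of TE" t-tests (of 60 total)
CENTER_BINS = (29, 30)


def dml_by_allele(
    pheno: MethylationPhenotype, genotypes: GenotypeMatrix, snp: str | int
) -> EffectProfile:
    """Per-TE mean methylation of alternative-allele carriers minus the
    reference group.  Negative DML = the alternative allele decreases
    methylation.  Both groups must hold >= 2 lines."""
    g = genotypes.column(snp)
    name = genotypes.snps.at[genotypes.snp_index(snp), "snp_id"]
    alt = g == 1
    ref = g == 0
    if alt.sum() < 2 or ref.sum() < 2:
        raise ValueError(f"allele group with <2 lines at SNP {name}")
    V = pheno.values.to_numpy(dtype=float)
    dml = np.nanmean(V[alt], axis=0) - np.nanmean(V[ref], axis=0)
    return EffectProfile(
        source=str(name),
        dml=pd.Series(dml, index=pheno.values.columns),
        n_ref=int(ref.sum()),
        n_alt=int(alt.sum()),
    )


def _dml_many_snps(V: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Vectorised alt-minus-ref group means for many SNPs at once.

    V is lines x TEs, G lines x SNPs (0/1); returns SNPs x TEs."""
    Gf = G.astype(np.float64)
    n_alt = Gf.sum(axis=0)
    n_ref = Gf.shape[0] - n_alt
    mean_alt = (Gf.T @ V) / n_alt[:, None]
    mean_ref = ((1.0 - Gf).T @ V) / n_ref[:, None]
    return mean_alt - mean_ref


def allele_mutant_correlation(
    allele: EffectProfile, panel: MutantPanel, min_shared: int = 10
) -> pd.Series:
    """Spearman correlation of the allele profile with every mutant in
    the panel over shared TEs, sorted by correlation (descending) for a
    correlation-matrix style display."""
    shared = allele.dml.index.intersection(panel.dml.columns)
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared TEs; need >= {min_shared}")
    a = allele.dml.loc[shared].to_numpy()
    out = {}
    for mut in panel.mutants:
        r, _ = stats.spearmanr(a, panel.dml.loc[mut, shared].to_numpy())
        out[mut] = float(r)
    return pd.Series(out, name=allele.source).sort_values(ascending=False)


@dataclass
class PermutationResult:
    """Permutation null for an observed allele-knockout correlation."""

    r_obs: float
    r_null: np.ndarray
    p_empirical: float
    n_perm: int


def permutation_null(
    pheno: MethylationPhenotype,
    genotypes: GenotypeMatrix,
    mutant_profile: pd.Series,
    snp: str | int,
    n_perm: int = 1500,
    seed: int = 0,
) -> PermutationResult:
    """Empirical significance of an allele-knockout correlation.

    Draws ``n_perm`` SNPs uniformly at random from the (MAF-filtered)
    genome, recomputes the per-TE allele DML profile at each, and
    correlates it with the knockout profile.  Two-sided empirical
    p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), never exactly 0.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} limits p-value resolution to {1/(n_perm+1):.3g}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    shared = pheno.values.columns.intersection(mutant_profile.index)
    V = pheno.values[shared].to_numpy(dtype=float)
    V = np.nan_to_num(V, nan=np.nanmean(V))
    prof = mutant_profile.loc[shared].to_numpy()

    obs = dml_by_allele(pheno, genotypes, snp)
    r_obs, _ = stats.spearmanr(obs.dml.loc[shared].to_numpy(), prof)

    # draw permutation SNPs (polymorphic, both groups >= 2 lines)
    n = genotypes.n_lines
    counts = genotypes.G.sum(axis=0)
    eligible = np.flatnonzero((counts >= 2) & (counts <= n - 2))
    picks = rng.choice(eligible, size=n_perm, replace=True)
    D = _dml_many_snps(V, genotypes.G[:, picks])

    # Spearman via Pearson on ranks, vectorised across permutations
    rank_prof = stats.rankdata(prof)
    rank_D = stats.rankdata(D, axis=1)
    rp = (rank_prof - rank_prof.mean()) / rank_prof.std()
    rd = rank_D - rank_D.mean(axis=1, keepdims=True)
    sd = rd.std(axis=1)
    r_null = (rd @ rp) / (sd * rp.size)
    r_null = np.where(sd > 0, r_null, 0.0)

    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (n_perm + 1.0)
    return PermutationResult(
        r_obs=float(r_obs), r_null=r_null, p_empirical=float(p), n_perm=n_perm
    )


@dataclass
class JointGenotypeResult:
    """Metaplots per two-locus genotype combination plus the Welch test
    on the central body bins between two designated combinations."""

    profiles: pd.DataFrame  # combination label x 60 bins
    group_sizes: dict[str, int]
    tested: tuple[str, str] | None
    t_stat: float | None
    p_value: float | None


def joint_genotype_profile(
    table: MethylCountTable,
    genotypes: GenotypeMatrix,
    snpA: str | int,
    snpB: str | int,
    te_set: list[str],
    test_pair: tuple[str, str] | None = None,
) -> JointGenotypeResult:
    """60-bin metaplots for each (up to four) joint genotype of two
    loci over a TE class, with a Welch t-test on per-line central-body
    levels between two combinations (default: double reference vs
    double carrier).  Empty combinations are dropped with a warning."""
    if not te_set:
        raise ValueError("TE class is empty")
    gA = genotypes.column(snpA)
    gB = genotypes.column(snpB)
    lines = np.asarray(table.line_ids)
    groups: dict[str, list[str]] = {}
    for a in (0, 1):
        for b in (0, 1):
            label = f"A{'alt' if a else 'ref'}/B{'alt' if b else 'ref'}"
            members = lines[(gA == a) & (gB == b)].tolist()
            if members:
                groups[label] = members
            else:
                warnings.warn(f"genotype combination {label} is empty; dropped",
                              stacklevel=2)
    profiles = metaplot_profile(table, te_set, groups)

    if test_pair is None:
        ordered = list(groups)
        test_pair = (ordered[0], ordered[-1]) if len(ordered) >= 2 else None
    t = p = None
    if test_pair is not None and all(g in groups for g in test_pair):
        te_idx = [table.te_ids.index(tid) for tid in te_set]
        per_line = []
        for label in test_pair:
            li = [table.line_ids.index(l) for l in groups[label]]
            mc = table.mc_bins[np.ix_(li, te_idx)][:, :, CENTER_BINS].sum(axis=(1, 2))
            tot = table.total_bins[np.ix_(li, te_idx)][:, :, CENTER_BINS].sum(axis=(1, 2))
            per_line.append(mc / np.maximum(tot, 1))
        if np.allclose(per_line[0].mean(), per_line[1].mean()) and (
            np.allclose(per_line[0].var(), 0) and np.allclose(per_line[1].var(), 0)
        ):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(per_line[0], per_line[1], equal_var=False)
            t, p = float(t), float(p)
    return JointGenotypeResult(
        profiles=profiles,
        group_sizes={k: len(v) for k, v in groups.items()},
        tested=test_pair,
        t_stat=t,
        p_value=p,
    )


def expression_by_allele(
    expr: ExpressionPhenotype, genotypes: GenotypeMatrix, snp: str | int
) -> dict:
    """Welch's unequal-variance two-sided t-test of expression between
    reference and alternative allele carriers."""
    g = genotypes.column(snp)
    vals = expr.values.to_numpy(dtype=float)
    x_ref, x_alt = vals[g == 0], vals[g == 1]
    if x_ref.size < 2 or x_alt.size < 2:
        raise ValueError("both allele groups need >= 2 lines")
    if np.ptp(x_ref) == 0 and np.ptp(x_alt) == 0:
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(x_alt, x_ref, equal_var=False)
    return {
        "t": float(t),
        "p": float(p),
        "mean_ref": float(x_ref.mean()),
        "mean_alt": float(x_alt.mean()),
    }
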