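"""Methylation counts -> analysis-ready phenotypes.

Weighted methylation levels, the common-TE filter, family averages,
rank transforms, pathway-target classification from knockout DML, 60-bin
metaplot profiles, and complete-linkage clustering of family profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import rankdata

from .containers import MethylationPhenotype, MethylCountTable, MutantPanel

logger = logging.getLogger(__name__)


def weighted_methylation(mc_counts, total_counts) -> float:
    """Weighted methylation level of a region: summed methylated reads
    over summed covered reads — never the mean of per-unit ratios.
    Returns NaN when the region has no coverage."""
    mc = np.asarray(mc_counts, dtype=float)
    tot = np.asarray(total_counts, dtype=float)
    if mc.shape != tot.shape:
        raise ValueError("count vectors differ in length")
    if np.any(mc < 0) or np.any(tot < 0):
        raise ValueError("negative counts")
    if np.any(mc > tot):
        raise ValueError("mc_count exceeds total_count")
    denom = tot.sum()
    if denom == 0:
        return float("nan")
    return float(mc.sum() / denom)


def levels_from_counts(table: MethylCountTable) -> MethylationPhenotype:
    """Per-line per-TE weighted methylation; zero-total cells become NaN."""
    tot = table.total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        lv = np.where(tot > 0, table.mc / np.where(tot > 0, tot, 1.0), np.nan)
    return MethylationPhenotype(
        values=pd.DataFrame(lv, index=table.line_ids, columns=table.te_ids)
    )


def common_te_filter(table: MethylCountTable, lines: list[str]) -> list[str]:
    """TEs with covered reads in every listed line, in annotation order."""
    if not lines:
        raise ValueError("empty line list")
    idx = [table.line_ids.index(l) for l in lines]
    ok = (table.total[idx, :] > 0).all(axis=0)
    return [t for t, keep in zip(table.te_ids, ok) if keep]


def family_average(
    pheno: MethylationPhenotype, family_map: dict[str, str] | pd.Series
) -> MethylationPhenotype:
    """Per-line unweighted mean over member TEs of each family.

    ``pheno`` must be restricted to common TEs; families losing all
    members are dropped with a logged warning.
    """
    fam = pd.Series(family_map)
    missing = [t for t in pheno.values.columns if t not in fam.index]
    if missing:
        raise KeyError(f"family_map missing TE(s): {missing[:5]}")
    fam = fam.loc[pheno.values.columns]
    out = pheno.values.T.groupby(fam.to_numpy()).mean().T
    dropped = set(fam.unique()) - set(out.columns)
    if dropped:
        logger.warning("families with no common member dropped: %s", sorted(dropped))
    units = pd.DataFrame({"family": out.columns}, index=out.columns)
    return MethylationPhenotype(values=out, units=units)


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n across non-missing entries; ties get average ranks;
    NaN stays NaN.  Invariant under monotone transforms of the input."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing values to rank")
    out = np.full(v.shape, np.nan)
    out[ok] = rankdata(v[ok], method="average")
    return out


def rank_transform_frame(values: pd.DataFrame, axis: int = 0) -> pd.DataFrame:
    """Column-wise (axis=0, across lines) or row-wise (axis=1, per line)
    average-tie ranks of a phenotype matrix."""
    ranked = values.rank(axis=axis, method="average")
    return ranked


@dataclass
class TargetClassification:
    """te_id -> {RdDM, CMT2, both, untargeted}; exhaustive and exclusive."""

    labels: pd.Series
    dml_threshold: float

    def te_of(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


def classify_targets(panel: MutantPanel, dml_threshold: float = 0.1) -> TargetClassification:
    """Classify TEs by which pathway knockout changes their methylation.

    A TE is RdDM-targeted when |DML| against the RdDM-pathway classifier
    knockout strictly exceeds the threshold and the CMT2 one does not;
    symmetrically for CMT2; "both" when both exceed; "untargeted"
    otherwise (strict inequalities, so DML exactly at the threshold does
    not count).
    """
    for mut in (panel.rddm_classifier, panel.cmt2_classifier):
        if mut not in panel.dml.index:
            raise KeyError(f"designated classifier mutant {mut!r} absent from panel")
    rddm = panel.dml.loc[panel.rddm_classifier].abs() > dml_threshold
    cmt2 = panel.dml.loc[panel.cmt2_classifier].abs() > dml_threshold
    labels = np.select(
        [rddm & cmt2, rddm, cmt2],
        ["both", "RdDM", "CMT2"],
        default="untargeted",
    )
    return TargetClassification(
        labels=pd.Series(labels, index=panel.dml.columns), dml_threshold=dml_threshold
    )


def metaplot_profile(
    table: MethylCountTable,
    te_set: list[str],
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-group 60-bin weighted methylation over a TE set.

    Bins 0-19 are upstream flank, 20-39 the element body, 40-59
    downstream.  Each bin pools counts across all lines of the group
    and all TEs of the set (weighted methylation, not mean of ratios).
    """
    if table.mc_bins is None:
        raise ValueError("count table carries no per-bin counts")
    te_idx = [table.te_ids.index(t) for t in te_set]
    out = {}
    for name, lines in groups.items():
        if not lines:
            raise ValueError(f"genotype group {name!r} is empty")
        li = [table.line_ids.index(l) for l in lines]
        mc = table.mc_bins[np.ix_(li, te_idx)].sum(axis=(0, 1)).astype(float)
        tot = table.total_bins[np.ix_(li, te_idx)].sum(axis=(0, 1)).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(tot > 0, mc / np.where(tot > 0, tot, 1), np.nan)
    return pd.DataFrame(out).T


def cluster_families(
    family_pheno: MethylationPhenotype, k: int = 4
) -> tuple[np.ndarray, pd.Series]:
    """Complete-linkage tree over family methylation profiles.

    Levels are rank-transformed per line, families compared by
    Euclidean distance, and groups obtained by cutting the tree at
    ``k`` clusters (default 4).  Returns the scipy linkage matrix and a
    family -> group-label Series.
    """
    vals = family_pheno.values
    if vals.shape[1] < 4:
        raise ValueError("need >= 4 families to cluster")
    if k > vals.shape[1]:
        raise ValueError(f"k={k} exceeds number of families {vals.shape[1]}")
    ranked = rank_transform_frame(vals, axis=1)  # rank order per line
    X = ranked.T.to_numpy()  # families x lines
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=vals.columns, name="group")


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({rec(tree.get_left(), tree.dist)},{rec(tree.get_right(), tree.dist)});"
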