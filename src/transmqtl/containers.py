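"""In-memory containers shared across the pipeline.

Inbred, selfing lines are haploid-coded: a genotype is 0 (reference) or
1 (alternative), so haplotypes are observed directly and kinship is the
plain identity-by-state fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Lines x biallelic SNPs, haploid 0/1.

    Attributes
    ----------
    G:
        ``(n_lines, n_snps)`` int8 array; -1 marks a missing call.
    line_ids:
        Line identifiers, row order of ``G``.
    snps:
        Per-SNP table with columns ``snp_id, chrom, pos, maf``
        (1-based positions, strictly increasing within chromosome).
    """

    G: np.ndarray
    line_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.line_ids), len(self.snps)):
            raise ValueError(
                f"genotype shape {self.G.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.snps)} SNPs"
            )
        self.snps = self.snps.reset_index(drop=True)
        for chrom, grp in self.snps.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on chrom {chrom}")

    @property
    def n_lines(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternative-allele frequency per SNP, missing calls excluded."""
        g = self.G.astype(float)
        g[self.G < 0] = np.nan
        return np.nanmean(g, axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def column(self, snp: str | int) -> np.ndarray:
        """Genotype column by index, snp_id, or ``chrom:pos`` string."""
        return self.G[:, self.snp_index(snp)]

    def snp_index(self, snp: str | int) -> int:
        if isinstance(snp, (int, np.integer)):
            return int(snp)
        ids = self.snps["snp_id"].to_numpy()
        hit = np.flatnonzero(ids == snp)
        if hit.size:
            return int(hit[0])
        if ":" in snp:
            chrom_s, pos_s = snp.split(":")
            mask = (self.snps["chrom"].astype(str) == chrom_s) & (
                self.snps["pos"] == int(pos_s)
            )
            hit = np.flatnonzero(mask.to_numpy())
            if hit.size:
                return int(hit[0])
        raise KeyError(f"SNP {snp!r} not found")

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.G[:, mask], list(self.line_ids), self.snps.loc[mask].reset_index(drop=True)
        )


@dataclass
class MethylCountTable:
    """Per-line, per-TE bisulfite read counts in the CHH context.

    ``mc`` holds reads supporting methylation, ``total`` covered reads;
    a zero total marks a missing cell.  Optional 60-bin positional
    counts (20 upstream / 20 body / 20 downstream) support metaplots.
    """

    line_ids: list[str]
    te_ids: list[str]
    mc: np.ndarray
    total: np.ndarray
    mc_bins: np.ndarray | None = None
    total_bins: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mc = np.asarray(self.mc)
        self.total = np.asarray(self.total)
        if np.any(self.mc > self.total):
            raise ValueError("mc_count exceeds total_count")
        if np.any(self.mc < 0) or np.any(self.total < 0):
            raise ValueError("negative read counts")

    @property
    def n_bins(self) -> int:
        return 0 if self.mc_bins is None else self.mc_bins.shape[2]

    def to_long_frame(self) -> pd.DataFrame:
        """allc-style long format: line_id, te_id, mc_count, total_count."""
        n_l, n_t = self.mc.shape
        return pd.DataFrame(
            {
                "line_id": np.repeat(self.line_ids, n_t),
                "te_id": np.tile(self.te_ids, n_l),
                "mc_count": self.mc.ravel(),
                "total_count": self.total.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "MethylCountTable":
        wide_mc = df.pivot(index="line_id", columns="te_id", values="mc_count")
        wide_tot = df.pivot(index="line_id", columns="te_id", values="total_count")
        wide_tot = wide_tot.loc[wide_mc.index, wide_mc.columns]
        # absent (line, TE) cells are zero-coverage missing data
        wide_mc = wide_mc.fillna(0)
        wide_tot = wide_tot.fillna(0)
        return cls(
            line_ids=list(wide_mc.index),
            te_ids=list(wide_mc.columns),
            mc=wide_mc.to_numpy(dtype=np.int64),
            total=wide_tot.to_numpy(dtype=np.int64),
        )


@dataclass
class MethylationPhenotype:
    """Lines x phenotype units (TEs or TE families) of mCHH levels in [0, 1].

    ``values`` is a DataFrame indexed by line_id with unit columns; NaN
    marks a unit without coverage in that line.  ``units`` carries unit
    metadata (family, superfamily, class) where available.
    """

    values: pd.DataFrame
    units: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < -1e-12 or np.nanmax(v, initial=0.0) > 1 + 1e-12:
                raise ValueError("methylation levels outside [0, 1]")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    def is_common(self) -> bool:
        return not self.values.isna().any().any()


@dataclass
class MutantPanel:
    """Knockout-panel differential methylation levels (DML).

    ``dml`` is mutants x TEs, each entry mean(mutant) - mean(wild-type)
    methylation for that TE; negative = loss of methylation in the
    knockout.  ``rddm_classifier`` / ``cmt2_classifier`` name the two
    designated pathway knockouts used to classify TE targets.
    """

    dml: pd.DataFrame
    wild_type: str = "wild_type"
    rddm_classifier: str = "drm1drm2_ko"
    cmt2_classifier: str = "cmt2_ko"

    def __post_init__(self) -> None:
        v = self.dml.to_numpy(dtype=float)
        if np.nanmax(np.abs(v), initial=0.0) > 1 + 1e-12:
            raise ValueError("DML outside [-1, 1]")

    @property
    def mutants(self) -> list[str]:
        return list(self.dml.index)


@dataclass
class ExpressionPhenotype:
    """Strictly positive per-line expression values, with the Box-Cox
    exponent recorded once the transform has been applied."""

    values: pd.Series
    lambda_: float | None = None
    transformed: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            raise ValueError("expression values must be strictly positive")


@dataclass
class EffectProfile:
    """Per-TE differential methylation attributed to one source.

    ``source`` is a natural-allele SNP id or a mutant id; ``dml`` maps
    te_id -> mean(alternative/mutant group) - mean(reference group).
    Negative = the alternative allele (or knockout) lowers methylation.
    """

    source: str
    dml: pd.Series
    n_ref: int = 0
    n_alt: int = 0

    def __post_init__(self) -> None:
        v = self.dml.to_numpy(dtype=float)
        if np.nanmax(np.abs(v), initial=0.0) > 1 + 1e-12:
            raise ValueError("DML outside [-1, 1]")


@dataclass
class LineMetadataTable:
    """Per-line geography: line_id, longitude, latitude, subpopulation."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"line_id", "longitude", "latitude", "subpopulation"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
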