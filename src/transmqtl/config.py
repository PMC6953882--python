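"""Simulation and pipeline configuration.

The synthetic cohort emulates a panel of inbred, selfing accessions
genotyped at biallelic SNPs and bisulfite-sequenced over annotated
transposable elements (TEs).  Two de novo CHH-methylation pathways are
modelled as latent TE classes: "RdDM" (RNA-directed DNA methylation,
short elements throughout the genome) and "CMT2" (CHROMOMETHYLASE 2,
long pericentromeric elements), plus an untargeted remainder.

Trans-acting causal loci are declared in :class:`CausalLocus` entries.
The default configuration plants three alleles mirroring the canonical
architecture of natural mCHH variation:

* ``NRPE1p`` — a Pol V subunit allele lowering methylation on RdDM
  targets with a weaker cross-class effect on CMT2 targets, frequent
  only in the east of the sampled range (strong longitudinal cline);
* ``CMT2bp`` / ``CMT2ap`` — two alleles at one chromomethylase locus
  with opposite effects (decrease / increase) restricted to CMT2
  targets, both western, so their clines cancel on the class average.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

TE_CLASSES = ("RdDM", "CMT2", "untargeted")

#: longitude window of the sampled range, degrees east
LON_RANGE = (-25.0, 100.0)


@dataclass(frozen=True)
class CausalLocus:
    """A planted trans-acting variant.

    Parameters
    ----------
    label:
        Identifier used in outputs (e.g. ``"NRPE1p"``).
    target_class:
        TE class whose methylation the alternative allele shifts.
    effect:
        Additive shift (methylation-level units) on target-class TEs
        per copy of the alternative allele.  Negative = hypomethylating.
    cross_effect:
        Shift applied to the *other* targeted class (RdDM<->CMT2);
        0 for a class-specific regulator.
    maf:
        Target population frequency of the alternative allele, in (0, 0.5].
    cline_slope:
        Slope (per degree longitude) of the logistic allele-frequency
        gradient.  0 plants no geographic structure.
    chrom, pos:
        Placement of the SNP (1-based position).  ``pos=None`` lets the
        simulator choose a position on ``chrom``.
    """

    label: str
    target_class: str = "RdDM"
    effect: float = -0.05
    cross_effect: float = 0.0
    maf: float = 0.1
    cline_slope: float = 0.0
    chrom: int = 1
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.target_class not in TE_CLASSES[:2]:
            raise ValueError(
                f"locus {self.label}: target_class must be 'RdDM' or 'CMT2', "
                f"got {self.target_class!r}"
            )
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"locus {self.label}: MAF must be in (0, 0.5], got {self.maf}")
        for name in ("effect", "cross_effect", "cline_slope"):
            v = getattr(self, name)
            if not (v == v and abs(v) < float("inf")):
                raise ValueError(f"locus {self.label}: {name} must be finite")


def default_causal_spec() -> tuple[CausalLocus, ...]:
    """Three-allele architecture: one cross-class eastern allele plus an
    opposite-effect western pair at a second locus."""
    return (
        CausalLocus(
            label="NRPE1p", target_class="RdDM", effect=-0.06, cross_effect=-0.03,
            maf=0.09, cline_slope=0.08, chrom=2,
        ),
        CausalLocus(
            label="CMT2bp", target_class="CMT2", effect=-0.05, cross_effect=0.0,
            maf=0.237, cline_slope=-0.04, chrom=4,
        ),
        CausalLocus(
            label="CMT2ap", target_class="CMT2", effect=0.04, cross_effect=0.0,
            maf=0.10, cline_slope=-0.04, chrom=4,
        ),
    )


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort.

    Defaults give a desk-scale panel (500 lines, 5,000 SNPs, 400 TEs in
    30 families) with the same statistical structure the analysis
    assumes at full scale.
    """

    n_lines: int = 500
    n_snps: int = 5000
    n_chrom: int = 5
    n_te: int = 400
    n_families: int = 30
    #: fractions of TEs assigned RdDM / CMT2 / untargeted
    class_fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    causal_spec: Sequence[CausalLocus] = field(default_factory=default_causal_spec)
    #: mean sequencing depth per TE per line (Poisson)
    read_depth_mean: float = 40.0
    #: beta-binomial intra-class correlation, in (0, 1)
    overdispersion: float = 0.1
    #: fraction of latent line-level variance from the polygenic background
    h2_background: float = 0.3
    #: residual per-line noise SD on the methylation-level scale
    line_noise_sd: float = 0.02
    #: per-(line, TE) micro-heterogeneity SD
    te_noise_sd: float = 0.02
    #: class baseline methylation levels (RdDM, CMT2, untargeted)
    class_baselines: tuple[float, float, float] = (0.15, 0.25, 0.05)
    #: median TE length per class (RdDM, CMT2, untargeted), bp
    te_mean_length: tuple[float, float, float] = (500.0, 4000.0, 800.0)
    #: lognormal sigma of TE lengths
    te_length_sd: float = 0.4
    n_subpop: int = 3
    #: Balding-Nichols divergence parameter (Fst-like); 0 = panmictic
    divergence: float = 0.1
    chrom_length: int = 1_000_000
    lon_range: tuple[float, float] = LON_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_lines < 4:
            raise ValueError("n_lines must be >= 4")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(f < 0 for f in self.class_fractions):
            raise ValueError("class_fractions must be non-negative")
        if not (0.0 <= self.h2_background <= 1.0):
            raise ValueError("h2_background must be in [0, 1]")
        if not (0.0 < self.overdispersion < 1.0):
            raise ValueError("overdispersion must be in (0, 1)")
        if self.n_chrom < 1 or self.n_snps < 1 or self.n_te < 1:
            raise ValueError("n_chrom, n_snps and n_te must be positive")
        labels = [c.label for c in self.causal_spec]
        if len(set(labels)) != len(labels):
            raise ValueError("causal locus labels must be unique")
        for c in self.causal_spec:
            if c.chrom < 1 or c.chrom > self.n_chrom:
                raise ValueError(f"locus {c.label}: chrom {c.chrom} outside 1..{self.n_chrom}")

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["causal_spec"] = [dataclasses.asdict(c) for c in self.causal_spec]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "causal_spec" in d:
            d["causal_spec"] = tuple(
                c if isinstance(c, CausalLocus) else CausalLocus(**c)
                for c in d["causal_spec"]
            )
        for key in ("class_fractions", "class_baselines", "lon_range", "te_mean_length"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload.get("simulate", payload))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"simulate": self.to_dict()}, fh, sort_keys=False)
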