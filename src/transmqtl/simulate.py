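"""Synthetic cohort generator.

Emulates the data a population bisulfite + genotype study produces:

* a structured panel of inbred lines (haploid 0/1 genotypes) with
  Balding-Nichols subpopulation divergence and geographic sampling;
* planted trans-acting causal SNPs whose population frequency follows a
  logistic longitudinal gradient;
* a TE annotation with two latently targeted classes (RdDM-like short
  elements in chromosome arms, CMT2-like long pericentromeric
  elements) plus untargeted elements;
* per-line per-TE methylation read counts with beta-binomial
  overdispersion, a kinship-correlated polygenic background, and
  optional 60-bin positional profiles in which CMT2-type effects
  deplete TE bodies while RdDM-type effects deplete whole elements;
* a knockout panel containing pathway-classifier mutants, one mutant
  matched to each planted allele, and random decoys;
* an expression phenotype with a cis effect at a designated locus.

Every generator is a pure function of (config, seed): rerunning with
the same inputs reproduces the output bitwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import TE_CLASSES, CausalLocus, SimConfig
from .containers import (
    ExpressionPhenotype,
    GenotypeMatrix,
    LineMetadataTable,
    MethylCountTable,
    MutantPanel,
)

N_BINS = 60  # 20 upstream + 20 body + 20 downstream
_BODY = slice(20, 40)

_SUPERFAMILIES = {
    "RdDM": ("RC/Helitron", "DNA/MuDR"),
    "CMT2": ("LTR/Gypsy", "LTR/Copia"),
    "untargeted": ("SINE", "RathE1_cons"),
}


class MAFUnreachableError(ValueError):
    """Requested causal MAF cannot be realised at the given panel size."""


def causal_position(cfg: SimConfig, index: int) -> tuple[int, int]:
    """Deterministic (chrom, pos) of the index-th causal locus:
    declared position if given, otherwise staggered mid-chromosome."""
    locus = cfg.causal_spec[index]
    pos = locus.pos if locus.pos is not None else cfg.chrom_length // 2 + 10_000 * (index + 1)
    return locus.chrom, pos


# ---------------------------------------------------------------------------
# population


def _line_geography(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.lon_range
    span = hi - lo
    centers = lo + span * (np.arange(cfg.n_subpop) + 0.5) / cfg.n_subpop
    sub = np.repeat(np.arange(cfg.n_subpop), -(-cfg.n_lines // cfg.n_subpop))[: cfg.n_lines]
    lon = np.clip(
        rng.normal(centers[sub], span / (3 * cfg.n_subpop)), lo, hi
    )
    lat = rng.normal(48.0, 4.0, size=cfg.n_lines)
    return pd.DataFrame(
        {
            "line_id": [f"L{i:04d}" for i in range(cfg.n_lines)],
            "longitude": lon,
            "latitude": lat,
            "subpopulation": [f"pop{s}" for s in sub],
        }
    )


def _background_snps(cfg: SimConfig, sub: np.ndarray, rng: np.random.Generator):
    """Balding-Nichols: subpopulation frequencies diverge from an
    ancestral frequency with parameter F; divergence 0 is panmixia."""
    m = cfg.n_snps
    p_anc = rng.uniform(0.1, 0.9, size=m)
    F = cfg.divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(cfg.n_subpop, m))
    else:
        p_sub = np.broadcast_to(p_anc, (cfg.n_subpop, m)).copy()
    G = (rng.random((cfg.n_lines, m)) < p_sub[sub]).astype(np.int8)
    return G


def _cline_probabilities(
    locus: CausalLocus, lon: np.ndarray
) -> np.ndarray:
    """Per-line carriage probability along the logistic longitude
    gradient, with the intercept solved so the mean equals the target
    frequency."""
    b = locus.cline_slope
    x = b * (lon - lon.mean())
    target = locus.maf

    def mean_minus_target(a: float) -> float:
        return float(expit(a + x).mean() - target)

    if abs(b) < 1e-12:
        return np.full_like(lon, target)
    a = brentq(mean_minus_target, -60.0, 60.0)
    return expit(a + x)


def _draw_causal(
    locus: CausalLocus,
    lon: np.ndarray,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    n = lon.size
    lo_k = int(np.ceil(0.8 * locus.maf * n))
    hi_k = int(np.floor(1.2 * locus.maf * n))
    if lo_k > hi_k or hi_k < 1:
        raise MAFUnreachableError(
            f"locus {locus.label}: MAF {locus.maf} unreachable within +/-20% "
            f"at n_lines={n}"
        )
    prob = _cline_probabilities(locus, lon)
    for _ in range(max_tries):
        g = (rng.random(n) < prob).astype(np.int8)
        if lo_k <= int(g.sum()) <= hi_k:
            return g
    raise MAFUnreachableError(
        f"locus {locus.label}: failed to realise MAF {locus.maf} within "
        f"+/-20% after {max_tries} draws"
    )


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, LineMetadataTable]:
    """Genotypes plus line metadata for a structured inbred panel.

    Causal SNPs from ``cfg.causal_spec`` are inserted at their declared
    chromosome (position auto-assigned mid-chromosome when not given)
    with frequencies following their longitudinal clines; the realised
    frequency of each causal SNP is within 20% (relative) of target.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    meta = _line_geography(cfg, rng)
    sub = meta["subpopulation"].str.removeprefix("pop").astype(int).to_numpy()
    lon = meta["longitude"].to_numpy()

    G_bg = _background_snps(cfg, sub, rng)
    chrom_bg = rng.integers(1, cfg.n_chrom + 1, size=cfg.n_snps)
    pos_bg = rng.integers(1, cfg.chrom_length + 1, size=cfg.n_snps)

    causal_cols, causal_rows = [], []
    for i, locus in enumerate(cfg.causal_spec):
        g = _draw_causal(locus, lon, rng)
        chrom, pos = causal_position(cfg, i)
        causal_cols.append(g)
        causal_rows.append((locus.label, chrom, pos))

    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i:06d}" for i in range(cfg.n_snps)]
            + [r[0] for r in causal_rows],
            "chrom": np.concatenate([chrom_bg, [r[1] for r in causal_rows]]),
            "pos": np.concatenate([pos_bg, [r[2] for r in causal_rows]]),
            "causal": [False] * cfg.n_snps + [True] * len(causal_rows),
        }
    )
    G = np.concatenate([G_bg] + [c[:, None] for c in causal_cols], axis=1)

    # sort genomically; on coordinate collision keep the causal SNP
    order = np.lexsort(
        (~snps["causal"].to_numpy(), snps["pos"].to_numpy(), snps["chrom"].to_numpy())
    )
    snps = snps.iloc[order].reset_index(drop=True)
    G = G[:, order]
    dup = snps.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    snps = snps.loc[~dup].drop(columns="causal").reset_index(drop=True)
    G = G[:, ~dup]

    f = G.mean(axis=0)
    snps["maf"] = np.minimum(f, 1 - f)
    return GenotypeMatrix(G, list(meta["line_id"]), snps), LineMetadataTable(meta)


# ---------------------------------------------------------------------------
# annotation


def _allocate_classes(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation so exact fractions give exact counts."""
    fr = np.asarray(cfg.class_fractions, dtype=float)
    raw = fr * cfg.n_te
    counts = np.floor(raw).astype(int)
    rem = cfg.n_te - counts.sum()
    for idx in np.argsort(-(raw - counts))[:rem]:
        counts[idx] += 1
    labels = np.repeat(np.array(TE_CLASSES), counts)
    return rng.permutation(labels)


def simulate_te_annotation(cfg: SimConfig) -> pd.DataFrame:
    """TE annotation table: chrom, 0-based half-open interval, family,
    superfamily, latent class, length, pericentromeric flag.

    CMT2-class elements are long and placed pericentromerically (middle
    fifth of the chromosome); RdDM-class elements are short and placed
    in the arms.  Overlap between elements is permitted — the table is
    positional only.
    """
    if cfg.n_te < 10:
        raise ValueError("n_te must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    classes = _allocate_classes(cfg, rng)

    mean_len = dict(zip(TE_CLASSES, cfg.te_mean_length))
    lengths = np.array(
        [rng.lognormal(np.log(mean_len[c]), cfg.te_length_sd) for c in classes]
    ).astype(int)
    lengths = np.clip(lengths, 50, None)
    if np.any(lengths >= cfg.chrom_length):
        raise ValueError("TE length exceeds chromosome length")

    chrom = rng.integers(1, cfg.n_chrom + 1, size=cfg.n_te)
    center = cfg.chrom_length / 2
    peri_half = cfg.chrom_length / 10
    starts = np.empty(cfg.n_te, dtype=int)
    for i, c in enumerate(classes):
        if c == "CMT2":
            lo, hi = center - peri_half, center + peri_half - lengths[i]
        else:
            # either arm, outside the pericentromere
            if rng.random() < 0.5:
                lo, hi = 0, center - peri_half - lengths[i]
            else:
                lo, hi = center + peri_half, cfg.chrom_length - lengths[i]
        hi = max(hi, lo + 1)
        start = int(rng.uniform(lo, hi))
        starts[i] = min(max(start, 0), cfg.chrom_length - lengths[i])
    ends = starts + lengths
    if np.any(ends > cfg.chrom_length):
        raise ValueError("TE interval exceeds chromosome length")

    # families nested within classes, proportional to class fractions
    n_fam_by_class = np.maximum(
        np.round(np.asarray(cfg.class_fractions) * cfg.n_families).astype(int), 1
    )
    fam_labels, superfam = [], []
    for cls in classes:
        k = rng.integers(0, n_fam_by_class[TE_CLASSES.index(cls)])
        fam_labels.append(f"{cls}_fam{k:02d}")
        superfam.append(_SUPERFAMILIES[cls][k % 2])

    peri = np.abs(starts + lengths / 2 - center) < peri_half
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "te_id": [f"TE{i:05d}" for i in range(cfg.n_te)],
            "family": fam_labels,
            "superfamily": superfam,
            "te_class": classes,
            "length": lengths,
            "pericentromeric": peri,
        }
    )


# ---------------------------------------------------------------------------
# methylomes


def expected_allele_profile(annotation: pd.DataFrame, locus: CausalLocus) -> pd.Series:
    """Expected per-TE methylation shift for carriers of the
    alternative allele: the class-restricted effect plus the
    cross-class term, zero on untargeted elements."""
    other = "CMT2" if locus.target_class == "RdDM" else "RdDM"
    cls = annotation["te_class"]
    dml = np.where(
        cls == locus.target_class, locus.effect,
        np.where(cls == other, locus.cross_effect, 0.0),
    )
    return pd.Series(dml, index=annotation["te_id"].to_numpy(), name=locus.label)


def _effect_bin_shape(target_class: str) -> np.ndarray:
    """Positional signature of an effect: CMT2-type effects deplete the
    TE body only; RdDM-type effects act over the whole element
    including its edges (flanks at half weight)."""
    w = np.zeros(N_BINS)
    if target_class == "CMT2":
        w[_BODY] = 1.0
    else:
        w[:] = 0.5
        w[_BODY] = 1.0
    return w


def _class_bin_baseline(te_class: str, baselines: dict[str, float]) -> np.ndarray:
    prof = np.full(N_BINS, 0.03)
    body = baselines[te_class]
    prof[_BODY] = body
    # short ramps at the body edges
    prof[18:20] = 0.03 + (body - 0.03) * np.array([0.33, 0.66])
    prof[40:42] = 0.03 + (body - 0.03) * np.array([0.66, 0.33])
    return prof


def _polygenic_background(
    G: np.ndarray, sigma_g: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw u ~ N(0, sigma_g^2 K) with K the IBS kinship, so the mixed
    model downstream has genuine structure to correct."""
    if sigma_g == 0:
        return np.zeros(G.shape[0])
    n, m = G.shape
    Gf = G.astype(np.float64)
    cross = Gf @ Gf.T
    rs = np.diag(cross)
    # |gi - gj| summed over SNPs = rs_i + rs_j - 2*cross for 0/1 codes
    K = 1.0 - (rs[:, None] + rs[None, :] - 2.0 * cross) / m
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    return sigma_g * (V * np.sqrt(w)) @ rng.standard_normal(n)


def simulate_methylomes(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    cfg: SimConfig,
    binned: bool = False,
) -> MethylCountTable:
    """Beta-binomial read counts over a latent per-line per-TE level.

    latent = class baseline + sum_l g_l * (class-restricted effect_l +
    cross-class term_l) + polygenic background (cov ~ IBS kinship,
    variance fraction ``h2_background`` of the line-level variance) +
    line noise + per-cell noise, clipped to [0, 1] (a warning reports
    clipping of more than 5% of cells).  Zero-depth cells are permitted
    and mark missing data.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n, m = cfg.n_lines, len(annotation)
    if genotypes.n_lines != n:
        raise ValueError("genotype panel does not match config n_lines")

    base = dict(zip(TE_CLASSES, cfg.class_baselines))
    latent = np.array([base[c] for c in annotation["te_class"]])[None, :].repeat(n, 0)

    profiles = []
    for locus in cfg.causal_spec:
        try:
            g = genotypes.column(locus.label).astype(float)
        except KeyError as exc:
            raise KeyError(f"causal locus {locus.label} absent from genotypes") from exc
        prof = expected_allele_profile(annotation, locus)
        latent += g[:, None] * prof.to_numpy()[None, :]
        profiles.append((locus, g, prof))

    # variance partition at the line level
    var_line_total = cfg.line_noise_sd**2 / max(1.0 - cfg.h2_background, 1e-12)
    sigma_g = np.sqrt(cfg.h2_background * var_line_total)
    u = _polygenic_background(genotypes.G, sigma_g, rng)
    line_noise = rng.normal(0.0, cfg.line_noise_sd, size=n)
    latent += (u + line_noise)[:, None]
    latent += rng.normal(0.0, cfg.te_noise_sd, size=(n, m))

    clipped = np.mean((latent < 0) | (latent > 1))
    if clipped > 0.05:
        warnings.warn(
            f"latent methylation clipped in {clipped:.1%} of cells "
            f"({int(clipped * latent.size)} cells)",
            stacklevel=2,
        )
    latent = np.clip(latent, 0.0, 1.0)

    mc, total = _beta_binomial_counts(
        latent, cfg.read_depth_mean, cfg.overdispersion, rng
    )
    table = MethylCountTable(
        line_ids=list(genotypes.line_ids),
        te_ids=list(annotation["te_id"]),
        mc=mc,
        total=total,
    )

    if binned:
        bin_latent = np.empty((n, m, N_BINS), dtype=np.float32)
        for cls in TE_CLASSES:
            idx = np.flatnonzero((annotation["te_class"] == cls).to_numpy())
            bin_latent[:, idx, :] = _class_bin_baseline(cls, base)[None, None, :]
        for locus, g, prof in profiles:
            shape = _effect_bin_shape(locus.target_class)
            bin_latent += (
                g[:, None, None] * prof.to_numpy()[None, :, None] * shape[None, None, :]
            )
        bin_latent += (u + line_noise)[:, None, None]
        bin_latent = np.clip(bin_latent, 0.0, 1.0)
        depth = max(cfg.read_depth_mean / 4.0, 2.0)
        mc_b, tot_b = _beta_binomial_counts(
            bin_latent.reshape(n, -1), depth, cfg.overdispersion, rng
        )
        table.mc_bins = mc_b.reshape(n, m, N_BINS)
        table.total_bins = tot_b.reshape(n, m, N_BINS)
    return table


def _beta_binomial_counts(
    latent: np.ndarray,
    depth_mean: float,
    rho: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth, then beta-binomial counts with intra-class
    correlation ``rho`` via the beta-mixture representation."""
    total = rng.poisson(depth_mean, size=latent.shape)
    m = np.clip(latent, 1e-9, 1 - 1e-9)
    conc = (1.0 - rho) / rho
    p_cell = rng.beta(m * conc, (1.0 - m) * conc)
    mc = rng.binomial(total, p_cell)
    return mc.astype(np.int32), total.astype(np.int32)


# ---------------------------------------------------------------------------
# mutant panel


def simulate_mutant_panel(
    annotation: pd.DataFrame,
    cfg: SimConfig,
    n_decoys: int = 12,
    matched_scale: float = 3.0,
    noise_sd: float = 0.01,
    classifier_loss: float = 0.3,
) -> MutantPanel:
    """Knockout panel of per-TE DML (mutant - wild-type).

    Contains (i) the two pathway classifiers, losing ``classifier_loss``
    on their class's TEs; (ii) one matched mutant per planted locus
    whose profile is a positively scaled copy of that locus's expected
    allele effect profile plus noise (scaled by ``matched_scale``,
    knockouts being stronger than natural alleles); and (iii) decoy
    mutants with sparse random profiles.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    te_ids = annotation["te_id"].to_numpy()
    cls = annotation["te_class"].to_numpy()
    m = len(te_ids)
    rows: dict[str, np.ndarray] = {}

    for name, target in (("drm1drm2_ko", "RdDM"), ("cmt2_ko", "CMT2")):
        prof = np.where(cls == target, -classifier_loss, 0.0)
        rows[name] = prof + rng.normal(0.0, noise_sd, size=m)

    for locus in cfg.causal_spec:
        prof = expected_allele_profile(annotation, locus).to_numpy()
        rows[f"ko_{locus.label}"] = matched_scale * prof + rng.normal(
            0.0, noise_sd, size=m
        )

    for d in range(n_decoys):
        prof = np.zeros(m)
        hit = rng.random(m) < 0.1
        prof[hit] = rng.normal(0.0, 0.1, size=int(hit.sum()))
        rows[f"decoy{d:02d}"] = prof + rng.normal(0.0, noise_sd, size=m)

    dml = pd.DataFrame(rows, index=te_ids).T.clip(-1.0, 1.0)
    return MutantPanel(dml=dml)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genotypes: GenotypeMatrix,
    cfg: SimConfig,
    cis_locus: str | None = None,
    baseline: float = 10.0,
    cis_shift: float = 3.0,
    log_noise_sd: float = 0.3,
) -> ExpressionPhenotype:
    """Strictly positive expression with log-normal noise and an
    additive cis shift for alternative-allele carriers at
    ``cis_locus`` (default: the last causal locus, emulating an
    expression-modulating regulatory allele)."""
    if cis_locus is None:
        if not cfg.causal_spec:
            raise ValueError("no causal locus available as the cis SNP")
        cis_locus = cfg.causal_spec[-1].label
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    g = genotypes.column(cis_locus).astype(float)
    mu = baseline + cis_shift * g
    if np.any(mu <= 0):
        raise ValueError("baseline + cis_shift must stay positive")
    vals = mu * np.exp(rng.normal(0.0, log_noise_sd, size=g.size))
    return ExpressionPhenotype(
        values=pd.Series(vals, index=genotypes.line_ids, name=f"expr_{cis_locus}")
    )
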