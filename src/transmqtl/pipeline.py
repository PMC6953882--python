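"""End-to-end orchestration: simulate -> summarize -> gwas -> meta ->
effects -> geo, driven by one config and one seed.

Each stage reads its inputs from, and writes its outputs to, a run
directory; a manifest records config hash, per-stage seeds and output
checksums so identical (config, seed) runs are bitwise reproducible.
Every stochastic stage receives the derived sub-seed ``seed XOR stage
index`` so stages can be re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import ibs_kinship, lmm_scan, maf_filter
from .config import SimConfig
from .containers import MethylationPhenotype
from .effects import (
    allele_mutant_correlation,
    dml_by_allele,
    joint_genotype_profile,
    permutation_null,
)
from .ldgeo import (
    genotype_combination_frequencies,
    longitude_cline,
    matched_maf_null,
    targeted_te_average,
)
from .meta import enrichment_fdr, fisher_combine, gene_level_significance, ld_prune
from .simulate import (
    simulate_methylomes,
    simulate_mutant_panel,
    simulate_population,
    simulate_te_annotation,
)
from .summaries import (
    classify_targets,
    cluster_families,
    common_te_filter,
    family_average,
    levels_from_counts,
    linkage_to_newick,
    rank_transform_frame,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "summarize", "gwas", "meta", "effects", "geo")

#: files each stage must find in the run directory, mapped to producer
_REQUIRES = {
    "simulate": {},
    "summarize": {
        "methylation.allc.tsv": "simulate",
        "annotation.bed": "simulate",
        "mutant_panel.tsv": "simulate",
    },
    "gwas": {"genotypes.tsv": "simulate", "family_levels.tsv": "summarize"},
    "meta": {"scan_pvalues.tsv": "gwas", "genes.tsv": "simulate"},
    "effects": {
        "genotypes.tsv": "simulate",
        "te_levels.tsv": "summarize",
        "mutant_panel.tsv": "simulate",
    },
    "geo": {
        "genotypes.tsv": "simulate",
        "te_levels.tsv": "summarize",
        "metadata.tsv": "simulate",
        "scan_pvalues.tsv": "gwas",
    },
}


def stage_seed(seed: int, stage: str) -> int:
    """Derived sub-seed: seed XOR stage index, kept below 2^31."""
    return (int(seed) ^ (STAGES.index(stage) + 1)) % (2**31)


class MissingUpstreamError(RuntimeError):
    pass


def _check_inputs(stage: str, outdir: Path) -> None:
    for fname, producer in _REQUIRES[stage].items():
        if not (outdir / fname).exists():
            raise MissingUpstreamError(
                f"stage {stage!r} needs {fname}, produced by stage "
                f"{producer!r}; run that stage first"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: SimConfig, seed: int, outdir: Path) -> list[str]:
    cfg = SimConfig.from_dict({**cfg.to_dict(), "seed": stage_seed(seed, "simulate")})
    genotypes, metadata = simulate_population(cfg)
    annotation = simulate_te_annotation(cfg)
    counts = simulate_methylomes(genotypes, annotation, cfg)
    panel = simulate_mutant_panel(annotation, cfg)
    genes = simulate_genes(cfg)
    if cfg.causal_spec:
        from .simulate import simulate_expression

        expr = simulate_expression(genotypes, cfg)
        io.write_table(
            expr.values.rename("expression").rename_axis("line_id").reset_index(),
            outdir / "expression.tsv",
        )

    io.write_vcf(genotypes, outdir / "genotypes.vcf")
    io.write_genotype_tsv(genotypes, outdir / "genotypes.tsv")
    io.write_metadata_tsv(metadata, outdir / "metadata.tsv")
    io.write_annotation_bed(annotation, outdir / "annotation.bed")
    io.write_allc_tsv(counts, outdir / "methylation.allc.tsv")
    io.write_mutant_panel_tsv(panel, outdir / "mutant_panel.tsv")
    io.write_table(genes, outdir / "genes.tsv")
    (outdir / "a_priori_genes.txt").write_text(
        "\n".join(genes.loc[genes["a_priori"], "gene_id"]) + "\n"
    )
    return [
        "genotypes.vcf", "genotypes.tsv", "metadata.tsv", "annotation.bed",
        "methylation.allc.tsv", "mutant_panel.tsv", "genes.tsv",
        "a_priori_genes.txt", "expression.tsv",
    ]


def simulate_genes(cfg: SimConfig, n_background: int = 200, n_apriori_extra: int = 17
                   ) -> pd.DataFrame:
    """Synthetic gene annotation for the enrichment FDR: one gene at
    each planted locus (a priori), extra a priori genes and background
    genes at random positions."""
    from .simulate import causal_position

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
    rows = []
    for i, locus in enumerate(cfg.causal_spec):
        chrom, pos = causal_position(cfg, i)
        rows.append(
            {"gene_id": f"gene_{locus.label}", "chrom": chrom,
             "start": max(pos - 2000, 1), "end": pos + 2000, "a_priori": True}
        )
    for i in range(n_apriori_extra + n_background):
        chrom = int(rng.integers(1, cfg.n_chrom + 1))
        start = int(rng.integers(1, cfg.chrom_length - 5000))
        rows.append(
            {"gene_id": f"gene_{i:04d}", "chrom": chrom, "start": start,
             "end": start + int(rng.integers(500, 5000)),
             "a_priori": i < n_apriori_extra}
        )
    return pd.DataFrame(rows)


def _stage_summarize(cfg: SimConfig, seed: int, outdir: Path) -> list[str]:
    _check_inputs("summarize", outdir)
    counts = io.read_allc_tsv(outdir / "methylation.allc.tsv")
    annotation = io.read_annotation_bed(outdir / "annotation.bed")
    panel = io.read_mutant_panel_tsv(outdir / "mutant_panel.tsv")

    common = common_te_filter(counts, counts.line_ids)
    levels = levels_from_counts(counts)
    common_levels = MethylationPhenotype(values=levels.values[common])
    fam_map = annotation.set_index("te_id")["family"]
    fam = family_average(common_levels, fam_map.loc[common])
    classification = classify_targets(panel)

    io.write_table(common_levels.values.rename_axis("line_id"),
                   outdir / "te_levels.tsv", index=True)
    io.write_table(fam.values.rename_axis("line_id"),
                   outdir / "family_levels.tsv", index=True)
    io.write_table(
        classification.labels.rename("target_class")
        .rename_axis("te_id")
        .reset_index(),
        outdir / "target_classes.tsv",
    )
    if fam.values.shape[1] >= 4:
        Z, groups = cluster_families(fam, k=min(4, fam.values.shape[1]))
        (outdir / "family_dendrogram.nwk").write_text(
            linkage_to_newick(Z, list(fam.values.columns))
        )
        io.write_table(
            groups.rename_axis("family").reset_index(), outdir / "family_groups.tsv"
        )
    return ["te_levels.tsv", "family_levels.tsv", "target_classes.tsv",
            "family_dendrogram.nwk", "family_groups.tsv"]


def _load_levels(path: Path) -> MethylationPhenotype:
    df = io.read_table(path).set_index("line_id")
    return MethylationPhenotype(values=df)


def _stage_gwas(cfg: SimConfig, seed: int, outdir: Path,
                maf: float = 0.05) -> list[str]:
    _check_inputs("gwas", outdir)
    genotypes = io.read_genotype_tsv(outdir / "genotypes.tsv")
    fam = _load_levels(outdir / "family_levels.tsv")
    genotypes = maf_filter(genotypes, maf)
    K = ibs_kinship(genotypes)
    ranked = rank_transform_frame(fam.values, axis=0)

    pvals, betas = {}, {}
    for unit in ranked.columns:
        res = lmm_scan(ranked[unit].to_numpy(), genotypes, K)
        pvals[unit] = res.table["pvalue"].to_numpy()
        betas[unit] = res.table["beta"].to_numpy()
    base = genotypes.snps[["snp_id", "chrom", "pos", "maf"]]
    io.write_table(pd.concat([base, pd.DataFrame(pvals)], axis=1),
                   outdir / "scan_pvalues.tsv")
    io.write_table(pd.concat([base, pd.DataFrame(betas)], axis=1),
                   outdir / "scan_betas.tsv")
    return ["scan_pvalues.tsv", "scan_betas.tsv"]


def _stage_meta(cfg: SimConfig, seed: int, outdir: Path, target_fdr: float = 0.2,
                window: int = 15_000, r2_cut: float = 0.2) -> list[str]:
    _check_inputs("meta", outdir)
    scans = io.read_table(outdir / "scan_pvalues.tsv")
    meta_cols = ["snp_id", "chrom", "pos", "maf"]
    P = scans.drop(columns=meta_cols).to_numpy(dtype=float)
    meta = fisher_combine(P, scans[meta_cols])
    io.write_table(meta.table, outdir / "meta.tsv")

    genes = io.read_table(outdir / "genes.tsv")
    a_priori = [
        l.strip() for l in (outdir / "a_priori_genes.txt").read_text().splitlines()
        if l.strip()
    ]
    gene_sig = gene_level_significance(meta, genes, window=window)
    io.write_table(gene_sig, outdir / "gene_significance.tsv")
    curve = enrichment_fdr(gene_sig, a_priori, target_fdr=target_fdr)
    io.write_table(curve.as_frame(), outdir / "fdr_curve.tsv")

    threshold = curve.threshold
    if threshold is None:
        logger.warning("no threshold reaches FDR %.2f; no peaks called", target_fdr)
        peaks = meta.table.iloc[0:0]
    else:
        cand = meta.table[-np.log10(meta.table["pvalue"]) >= threshold]
        genotypes = io.read_genotype_tsv(outdir / "genotypes.tsv")
        peaks = ld_prune(cand, genotypes, r2_cut=r2_cut).peaks
    io.write_table(peaks, outdir / "peaks.tsv")
    (outdir / "meta_threshold.json").write_text(
        json.dumps({"target_fdr": target_fdr, "neglog10p_threshold": threshold})
    )
    return ["meta.tsv", "gene_significance.tsv", "fdr_curve.tsv", "peaks.tsv",
            "meta_threshold.json"]


def _stage_effects(cfg: SimConfig, seed: int, outdir: Path,
                   n_perm: int = 300) -> list[str]:
    _check_inputs("effects", outdir)
    genotypes = io.read_genotype_tsv(outdir / "genotypes.tsv")
    pheno = _load_levels(outdir / "te_levels.tsv")
    panel = io.read_mutant_panel_tsv(outdir / "mutant_panel.tsv")
    filtered = maf_filter(genotypes)
    sub_seed = stage_seed(seed, "effects")

    profiles, corr_rows, perm_rows = {}, [], []
    for locus in cfg.causal_spec:
        prof = dml_by_allele(pheno, genotypes, locus.label)
        profiles[locus.label] = prof.dml
        corr = allele_mutant_correlation(prof, panel)
        corr_rows.append(corr.rename(locus.label))
        perm = permutation_null(
            pheno, filtered, panel.dml.loc[f"ko_{locus.label}"],
            locus.label, n_perm=n_perm, seed=sub_seed,
        )
        perm_rows.append(
            {"locus": locus.label, "mutant": f"ko_{locus.label}",
             "r_obs": perm.r_obs, "p_empirical": perm.p_empirical,
             "n_perm": perm.n_perm}
        )
    io.write_table(pd.DataFrame(profiles), outdir / "effect_profiles.tsv", index=True)
    io.write_table(pd.concat(corr_rows, axis=1), outdir / "allele_mutant_corr.tsv",
                   index=True)
    io.write_table(pd.DataFrame(perm_rows), outdir / "permutation_tests.tsv")

    # joint-genotype metaplot on the class shared by the first two loci
    if len(cfg.causal_spec) >= 2:
        sim_cfg = SimConfig.from_dict(
            {**cfg.to_dict(), "seed": stage_seed(seed, "simulate")}
        )
        sim_geno, _ = simulate_population(sim_cfg)
        annotation = simulate_te_annotation(sim_cfg)
        binned = simulate_methylomes(sim_geno, annotation, sim_cfg, binned=True)
        te_set = list(
            annotation.loc[annotation["te_class"] == "CMT2", "te_id"]
        )
        a, b = cfg.causal_spec[0].label, cfg.causal_spec[1].label
        joint = joint_genotype_profile(binned, sim_geno, a, b, te_set)
        io.write_table(joint.profiles, outdir / "joint_genotype_profiles.tsv",
                       index=True)
        (outdir / "joint_genotype_test.json").write_text(
            json.dumps({"pair": joint.tested, "t": joint.t_stat,
                        "p": joint.p_value, "groups": joint.group_sizes})
        )
    return ["effect_profiles.tsv", "allele_mutant_corr.tsv",
            "permutation_tests.tsv", "joint_genotype_profiles.tsv",
            "joint_genotype_test.json"]


def _stage_geo(cfg: SimConfig, seed: int, outdir: Path,
               threshold_log10p: float = 1.3, maf_tol: float = 0.005) -> list[str]:
    # threshold_log10p is calibrated to the synthetic read depth; at
    # full biobank scale the corresponding choice is 6 (config-exposed
    # through targeted_te_average).
    _check_inputs("geo", outdir)
    genotypes = io.read_genotype_tsv(outdir / "genotypes.tsv")
    pheno = _load_levels(outdir / "te_levels.tsv")
    metadata = io.read_metadata_tsv(outdir / "metadata.tsv")
    scans = io.read_table(outdir / "scan_pvalues.tsv")

    # per-TE focal-SNP association from the family scans is not
    # available per TE; use the single-TE association of each causal
    # SNP computed directly (lm on ranks would do; use correlation test)
    cline_rows, combo_frames = [], []
    for locus in cfg.causal_spec:
        g = genotypes.column(locus.label).astype(float)
        V = pheno.values.to_numpy(dtype=float)
        te_p = _per_te_association_p(V, g)
        te_scores = pd.Series(-np.log10(te_p), index=pheno.values.columns)
        thr = threshold_log10p
        try:
            avg, te_set = targeted_te_average(pheno, te_scores, thr)
        except ValueError:
            thr = float(np.quantile(te_scores, 0.9))
            avg, te_set = targeted_te_average(pheno, te_scores, thr)
        raw = longitude_cline(avg, metadata, lon_range=cfg.lon_range)
        resid = longitude_cline(avg, metadata, covariate_snp=genotypes.column(locus.label),
                                lon_range=cfg.lon_range)
        cline_rows.extend(
            [
                {"locus": locus.label, "covariate": "none", "n_te": len(te_set),
                 "threshold": thr, "slope": raw.slope, "r2": raw.r2,
                 "p": raw.p_value, "n": raw.n},
                {"locus": locus.label, "covariate": "allele", "n_te": len(te_set),
                 "threshold": thr, "slope": resid.slope, "r2": resid.r2,
                 "p": resid.p_value, "n": resid.n},
            ]
        )
    io.write_table(pd.DataFrame(cline_rows), outdir / "longitude_clines.tsv")

    labels = [l.label for l in cfg.causal_spec]
    if len(labels) >= 2:
        combos = genotype_combination_frequencies(genotypes, labels[:2])
        io.write_table(combos, outdir / "genotype_combinations.tsv")
        combo_frames.append(combos)
        try:
            res = matched_maf_null(genotypes, labels[0], labels[1], maf_tol=maf_tol)
            io.write_table(
                pd.DataFrame(
                    {"snp_id": res.matched_snp_ids, "d_prime": res.null_d_prime,
                     "fisher_p": res.fisher_p_null}
                ),
                outdir / "matched_null_dprime.tsv",
            )
            (outdir / "ld_summary.json").write_text(
                json.dumps(
                    {"target": labels[0], "partner": labels[1],
                     "d_prime": res.observed.d_prime, "D": res.observed.D,
                     "r2": res.observed.r2, "p_empirical": res.p_empirical,
                     "fisher_p": res.fisher_p_observed,
                     "n_matched": len(res.matched_snp_ids)}
                )
            )
        except ValueError as exc:
            logger.warning("matched-MAF null skipped: %s", exc)
            (outdir / "ld_summary.json").write_text(json.dumps({"skipped": str(exc)}))
    return ["longitude_clines.tsv", "genotype_combinations.tsv",
            "matched_null_dprime.tsv", "ld_summary.json"]


def _per_te_association_p(V: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Two-sided t-test p of each TE's level on the focal genotype."""
    n = g.size
    gc = g - g.mean()
    Vc = V - np.nanmean(V, axis=0)
    Vc = np.nan_to_num(Vc)
    beta = gc @ Vc / (gc @ gc)
    rss = (Vc**2).sum(axis=0) - beta**2 * (gc @ gc)
    se = np.sqrt(np.maximum(rss, 1e-300) / (n - 2) / (gc @ gc))
    from scipy import stats as st

    t = beta / se
    return np.clip(2 * st.t.sf(np.abs(t), n - 2), 1e-300, 1.0)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "summarize": _stage_summarize,
    "gwas": _stage_gwas,
    "meta": _stage_meta,
    "effects": _stage_effects,
    "geo": _stage_geo,
}


def run_pipeline(
    cfg: SimConfig,
    outdir: str | Path,
    seed: int = 0,
    stages: list[str] | None = None,
) -> dict:
    """Execute the requested stages in dependency order and write a
    manifest (config hash, per-stage sub-seeds, output checksums)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    cfg_payload = json.dumps(cfg.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_payload.encode()).hexdigest(),
        "seed": seed,
        "stages": [],
    }
    for stage in stages:
        t0 = time.time()
        outputs = _STAGE_FN[stage](cfg, seed, outdir)
        entry = {
            "stage": stage,
            "sub_seed": stage_seed(seed, stage),
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": {
                f: _sha256(outdir / f) for f in outputs if (outdir / f).exists()
            },
        }
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.1fs", stage, entry["elapsed_s"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict[str, str | Path]) -> dict:
    """Cross-check user-supplied input files: format dialects, line-ID
    consistency, coordinate sanity.  Returns a machine-readable report
    with an ``issues`` list (empty = valid)."""
    issues: list[str] = []
    line_sets: dict[str, set] = {}
    if "genotypes" in paths:
        p = Path(paths["genotypes"])
        try:
            geno = (io.read_vcf(p) if p.suffix == ".vcf" else io.read_genotype_tsv(p))
            line_sets["genotypes"] = set(geno.line_ids)
        except Exception as exc:
            issues.append(f"genotypes: {exc}")
    if "methylation" in paths:
        try:
            counts = io.read_allc_tsv(paths["methylation"])
            line_sets["methylation"] = set(counts.line_ids)
        except Exception as exc:
            issues.append(f"methylation: {exc}")
    if "annotation" in paths:
        try:
            io.read_annotation_bed(paths["annotation"])
        except Exception as exc:
            issues.append(f"annotation: {exc}")
    if "metadata" in paths:
        try:
            meta = io.read_metadata_tsv(paths["metadata"])
            line_sets["metadata"] = set(meta.table["line_id"])
        except Exception as exc:
            issues.append(f"metadata: {exc}")
    names = list(line_sets)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            diff = line_sets[names[i]] ^ line_sets[names[j]]
            if diff:
                issues.append(
                    f"line-ID mismatch between {names[i]} and {names[j]}: "
                    f"{sorted(diff)[:10]}"
                )
    return {"issues": issues, "n_files": len(paths)}
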