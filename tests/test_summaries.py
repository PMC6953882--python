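"""Weighted methylation, filtering, ranks, target classification,
metaplots and family clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score

from transmqtl.config import SimConfig
from transmqtl.containers import MethylationPhenotype, MethylCountTable, MutantPanel
from transmqtl import simulate
from transmqtl.summaries import (
    classify_targets,
    cluster_families,
    common_te_filter,
    family_average,
    levels_from_counts,
    linkage_to_newick,
    metaplot_profile,
    rank_transform,
    weighted_methylation,
)


class TestWeightedMethylation:
    @pytest.mark.parametrize(
        "mc,total,expected",
        [
            ([2, 3, 0], [10, 10, 5], 0.2),
            ([0, 0], [7, 3], 0.0),
            ([5], [5], 1.0),
        ],
    )
    def test_worked_examples(self, mc, total, expected):
        assert weighted_methylation(mc, total) == pytest.approx(expected)

    def test_zero_total_is_missing_not_zero(self):
        assert np.isnan(weighted_methylation([0, 0], [0, 0]))

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # 102/1010 != mean(0.2, 0.1)
        v = weighted_methylation([2, 100], [10, 1000])
        assert v == pytest.approx(102 / 1010)
        assert v != pytest.approx((2 / 10 + 100 / 1000) / 2)

    @pytest.mark.parametrize(
        "mc,total,msg",
        [([-1], [2], "negative"), ([3], [2], "exceeds")],
    )
    def test_invalid_counts_raise(self, mc, total, msg):
        with pytest.raises(ValueError, match=msg):
            weighted_methylation(mc, total)


class TestCommonTeFilter:
    def _table(self, total):
        total = np.asarray(total)
        return MethylCountTable(
            line_ids=[f"l{i}" for i in range(total.shape[0])],
            te_ids=[f"t{j}" for j in range(total.shape[1])],
            mc=np.zeros_like(total),
            total=total,
        )

    def test_zero_coverage_cell_drops_te(self):
        t = self._table([[5, 0, 2], [4, 9, 1]])
        assert common_te_filter(t, ["l0", "l1"]) == ["t0", "t2"]

    def test_full_coverage_keeps_all(self):
        t = self._table([[1, 1], [2, 2]])
        assert common_te_filter(t, ["l0", "l1"]) == ["t0", "t1"]

    def test_empty_line_list_raises(self):
        with pytest.raises(ValueError):
            common_te_filter(self._table([[1]]), [])

    def test_default_synthetic_depth_keeps_every_te(self, small_cfg, counts):
        kept = common_te_filter(counts, counts.line_ids)
        assert len(kept) == small_cfg.n_te


class TestFamilyAverage:
    def _pheno(self, data, tes):
        return MethylationPhenotype(values=pd.DataFrame(data, columns=tes))

    def test_mean_of_members(self):
        p = self._pheno([[0.1, 0.3]], ["a", "b"])
        out = family_average(p, {"a": "f", "b": "f"})
        assert out.values.loc[0, "f"] == pytest.approx(0.2)

    def test_single_member_identity(self):
        p = self._pheno([[0.4, 0.6]], ["a", "b"])
        out = family_average(p, {"a": "fa", "b": "fb"})
        assert out.values.loc[0, "fa"] == pytest.approx(0.4)

    def test_member_order_invariance(self):
        p1 = self._pheno([[0.1, 0.5, 0.3]], ["a", "b", "c"])
        p2 = self._pheno([[0.3, 0.1, 0.5]], ["c", "a", "b"])
        fam = {"a": "f", "b": "f", "c": "f"}
        assert family_average(p1, fam).values.equals(family_average(p2, fam).values)

    def test_unmapped_te_raises_with_name(self):
        p = self._pheno([[0.1]], ["orphan"])
        with pytest.raises(KeyError, match="orphan"):
            family_average(p, {"other": "f"})


class TestRankTransform:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([0.2, 0.5, 0.1], [2, 3, 1]),
            ([0.2, 0.2, 0.7], [1.5, 1.5, 3]),
        ],
    )
    def test_worked_examples(self, values, expected):
        np.testing.assert_allclose(rank_transform(values), expected)

    def test_missing_stays_missing(self):
        out = rank_transform([0.2, np.nan, 0.1])
        assert np.isnan(out[1]) and list(out[[0, 2]]) == [2, 1]

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            rank_transform([np.nan, np.nan])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.001, 0.999), min_size=3, max_size=30),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_monotone_transform_invariance(self, vals, fn):
        v = np.asarray(vals)
        f = {"exp": np.exp, "cube": lambda x: x**3, "affine": lambda x: 3 * x + 1}[fn]
        np.testing.assert_allclose(rank_transform(v), rank_transform(f(v)))

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=3, max_size=30, unique=True))
    def test_idempotent(self, vals):
        r = rank_transform(np.asarray(vals))
        np.testing.assert_allclose(rank_transform(r), r)


class TestClassifyTargets:
    def _panel(self, rddm_dml, cmt2_dml):
        tes = [f"t{i}" for i in range(len(rddm_dml))]
        dml = pd.DataFrame(
            [rddm_dml, cmt2_dml], index=["drm1drm2_ko", "cmt2_ko"], columns=tes
        )
        return MutantPanel(dml=dml)

    @pytest.mark.parametrize(
        "rddm,cmt2,expected",
        [
            (0.15, 0.02, "RdDM"),
            (0.12, 0.30, "both"),
            (0.10, 0.10, "untargeted"),  # strict inequality at threshold
            (0.02, 0.25, "CMT2"),
            (-0.15, 0.02, "RdDM"),  # knockout losses are negative DML
        ],
    )
    def test_threshold_logic(self, rddm, cmt2, expected):
        cls = classify_targets(self._panel([rddm], [cmt2]))
        assert cls.labels["t0"] == expected

    def test_partitions_te_universe(self, panel):
        cls = classify_targets(panel)
        assert set(cls.labels.unique()) <= {"RdDM", "CMT2", "both", "untargeted"}
        assert cls.labels.index.tolist() == list(panel.dml.columns)
        assert not cls.labels.isna().any()

    def test_missing_classifier_raises(self):
        p = self._panel([0.2], [0.2])
        p.dml = p.dml.drop(index="cmt2_ko")
        with pytest.raises(KeyError, match="cmt2_ko"):
            classify_targets(p)

    def test_recovers_planted_classes(self, small_cfg, annotation, panel):
        cls = classify_targets(panel)
        truth = annotation.set_index("te_id")["te_class"]
        # classifier knockouts lose 0.3 on their class: recovery is exact
        # up to decoy noise
        agree = (cls.labels.loc[truth.index] == truth).mean()
        assert agree > 0.95


class TestMetaplot:
    def test_flat_latent_profile(self):
        cfg = SimConfig(
            n_lines=40, n_snps=100, n_te=20, causal_spec=(),
            class_baselines=(0.3, 0.3, 0.3), read_depth_mean=400,
            overdispersion=1e-4, h2_background=0.0, line_noise_sd=1e-4,
            te_noise_sd=0.0, seed=4,
        )
        genotypes, _ = simulate.simulate_population(cfg)
        ann = simulate.simulate_te_annotation(cfg)
        counts = simulate.simulate_methylomes(genotypes, ann, cfg, binned=True)
        prof = metaplot_profile(
            counts, list(ann["te_id"]), {"all": counts.line_ids}
        )
        body = prof.loc["all"].to_numpy()[22:38]
        assert np.all(np.abs(body - 0.3) < 0.01)

    def test_body_depletion_for_carriers(self, small_cfg, binned_counts, population,
                                         annotation):
        genotypes, _ = population
        g = genotypes.column("CMT2bp")
        lines = np.asarray(binned_counts.line_ids)
        te_set = list(annotation.loc[annotation["te_class"] == "CMT2", "te_id"])
        prof = metaplot_profile(
            binned_counts, te_set,
            {"carrier": lines[g == 1].tolist(), "ref": lines[g == 0].tolist()},
        )
        carrier = prof.loc["carrier"].to_numpy()
        body, flank = carrier[25:35].mean(), carrier[:15].mean()
        ref_body = prof.loc["ref"].to_numpy()[25:35].mean()
        assert ref_body - body > 0.02  # body depleted vs reference group
        assert flank < body  # flanks remain low-methylation

    def test_single_line_group_identity(self, binned_counts):
        line = binned_counts.line_ids[0]
        tes = binned_counts.te_ids[:5]
        prof = metaplot_profile(binned_counts, tes, {"solo": [line]})
        te_idx = [binned_counts.te_ids.index(t) for t in tes]
        mc = binned_counts.mc_bins[0, te_idx].sum(axis=0)
        tot = binned_counts.total_bins[0, te_idx].sum(axis=0)
        np.testing.assert_allclose(
            prof.loc["solo"].to_numpy(), mc / np.maximum(tot, 1), atol=1e-12
        )

    def test_empty_group_raises_with_name(self, binned_counts):
        with pytest.raises(ValueError, match="ghost"):
            metaplot_profile(binned_counts, binned_counts.te_ids[:3], {"ghost": []})


class TestClusterFamilies:
    def _pheno_from(self, X, families):
        return MethylationPhenotype(
            values=pd.DataFrame(
                X, columns=families, index=[f"l{i}" for i in range(X.shape[0])]
            )
        )

    def test_recovers_two_planted_classes(self, rng):
        n_lines, n_fam = 60, 12
        g = rng.integers(0, 2, n_lines).astype(float)
        X = np.empty((n_lines, n_fam))
        for j in range(n_fam):
            effect = -0.2 if j < 6 else 0.2
            X[:, j] = 0.5 + effect * g + rng.normal(0, 0.01, n_lines)
        pheno = self._pheno_from(np.clip(X, 0, 1), [f"f{j}" for j in range(n_fam)])
        _, labels = cluster_families(pheno, k=2)
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, labels.to_numpy()) > 0.95

    def test_duplicate_family_joins_twin_at_zero_height(self, rng):
        X = rng.uniform(0.2, 0.8, size=(20, 5))
        X = np.column_stack([X, X[:, 0]])  # f5 duplicates f0
        pheno = self._pheno_from(X, [f"f{j}" for j in range(6)])
        Z, _ = cluster_families(pheno, k=2)
        first = Z[0]
        assert {int(first[0]), int(first[1])} == {0, 5}
        assert first[2] == pytest.approx(0.0, abs=1e-9)

    def test_line_permutation_symmetry(self, rng):
        X = rng.uniform(0, 1, size=(25, 6))
        fams = [f"f{j}" for j in range(6)]
        perm = rng.permutation(25)
        Z1, l1 = cluster_families(self._pheno_from(X, fams))
        Z2, l2 = cluster_families(self._pheno_from(X[perm], fams))
        # identical topology and heights; group labels identical
        np.testing.assert_allclose(Z1[:, 2], Z2[:, 2], atol=1e-9)
        assert (l1 == l2).all()

    def test_k_exceeding_families_raises(self, rng):
        pheno = self._pheno_from(rng.uniform(0, 1, (10, 4)), list("abcd"))
        with pytest.raises(ValueError):
            cluster_families(pheno, k=5)

    def test_newick_roundtrips_leaf_names(self, rng):
        X = rng.uniform(0, 1, (15, 5))
        pheno = self._pheno_from(X, [f"fam{j}" for j in range(5)])
        Z, _ = cluster_families(pheno, k=2)
        nwk = linkage_to_newick(Z, [f"fam{j}" for j in range(5)])
        import io as _io
        from Bio import Phylo

        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [
            f"fam{j}" for j in range(5)
        ]


def test_levels_from_counts_masks_zero_depth(counts):
    lv = levels_from_counts(counts)
    zero = counts.total == 0
    if zero.any():
        assert lv.values.to_numpy()[zero].size == np.isnan(
            lv.values.to_numpy()[zero]
        ).sum()
    assert np.nanmax(lv.values.to_numpy()) <= 1.0
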