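import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import silhouette_score

from methylscreen import dmp_analysis as da
from methylscreen import synthetic_data as sd
from methylscreen.manifest_io import Manifest

from conftest import make_beta, make_probe, make_sheet


def bh_brute_force(p):
    """Textbook step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


class TestGroupStats:
    def test_delta_beta(self):
        bm = make_beta([[0.5, 0.5, 0.3, 0.3]], sample_ids=["HT1", "HT2", "C1", "C2"])
        gs = da.group_stats(bm, make_sheet())
        assert gs.delta_beta[0] == pytest.approx(0.2)

    def test_identical_groups_zero(self):
        bm = make_beta([[0.4, 0.6, 0.4, 0.6]], sample_ids=["HT1", "HT2", "C1", "C2"])
        gs = da.group_stats(bm, make_sheet())
        assert gs.delta_beta[0] == pytest.approx(0.0)

    def test_swapped_labels_negate(self):
        bm = make_beta([[0.7, 0.8, 0.2, 0.3]], sample_ids=["A", "B", "C", "D"])
        import pandas as pd

        from methylscreen.manifest_io import SampleSheet

        fwd = SampleSheet(
            pd.DataFrame({"sample_id": list("ABCD"), "group": ["case", "case", "control", "control"]})
        )
        rev = SampleSheet(
            pd.DataFrame({"sample_id": list("ABCD"), "group": ["control", "control", "case", "case"]})
        )
        d1 = da.group_stats(bm, fwd).delta_beta[0]
        d2 = da.group_stats(bm, rev).delta_beta[0]
        assert d1 == pytest.approx(-d2)

    def test_missing_group_errors(self):
        import pandas as pd

        from methylscreen.manifest_io import SampleSheet

        bm = make_beta([[0.5, 0.5]], sample_ids=["A", "B"])
        sheet = SampleSheet(pd.DataFrame({"sample_id": ["A", "B"], "group": ["case", "case"]}))
        with pytest.raises(ValueError):
            da.group_stats(bm, sheet)


class TestDmpTest:
    def test_equal_means_p_near_one(self):
        rng = np.random.default_rng(0)
        vals = 0.5 + 0.01 * rng.standard_normal(20)
        bm = make_beta(
            np.concatenate([vals[:10], vals[:10]])[None, :],
            sample_ids=[f"HT{i+1}" for i in range(10)] + [f"C{i+1}" for i in range(10)],
        )
        p = da.dmp_test(bm, make_sheet(10, 10), method="welch_t")
        assert p[0] > 0.5

    def test_welch_hand_computed(self):
        bm = make_beta(
            [[0.8, 0.9, 0.85, 0.1, 0.2, 0.15]],
            sample_ids=["HT1", "HT2", "HT3", "C1", "C2", "C3"],
        )
        p = da.dmp_test(bm, make_sheet(3, 3), method="welch_t")
        # hand computation: se = sqrt(0.0025/3 + 0.0025/3), t = 0.7/se = 17.146
        t, p_ref = stats.ttest_ind([0.8, 0.9, 0.85], [0.1, 0.2, 0.15], equal_var=False)
        assert t == pytest.approx(17.146, abs=0.005)
        assert p[0] == pytest.approx(p_ref)
        assert p[0] < 0.01

    def test_zero_variance_equal_means(self):
        bm = make_beta([[0.5, 0.5, 0.5, 0.5]], sample_ids=["HT1", "HT2", "C1", "C2"])
        for method in ("welch_t", "moderated_t"):
            p = da.dmp_test(bm, make_sheet(), method=method)
            assert p[0] == pytest.approx(1.0)

    def test_methods_agree_in_ordering_on_null(self):
        rng = np.random.default_rng(42)
        beta = np.clip(rng.normal(0.5, 0.1, size=(100, 20)), 0, 1)
        bm = make_beta(beta, sample_ids=[f"S{i}" for i in range(20)])
        sheet = make_sheet(10, 10)
        sheet.df["sample_id"] = [f"S{i}" for i in range(20)]
        p_w = da.dmp_test(bm, sheet, method="welch_t")
        p_m = da.dmp_test(bm, sheet, method="moderated_t")
        rho = stats.spearmanr(p_w, p_m).statistic
        assert rho > 0.9

    def test_unknown_method(self):
        bm = make_beta([[0.5] * 4], sample_ids=["HT1", "HT2", "C1", "C2"])
        with pytest.raises(ValueError):
            da.dmp_test(bm, make_sheet(), method="bogus")


class TestAdjustBH:
    def test_worked_example(self):
        # ranks 1..4: 0.01*4/1, 0.02*4/2, 0.03*4/3, 0.04*4/4 = .04,.04,.04,.04
        adj = da.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert da.adjust_bh([0.123])[0] == pytest.approx(0.123)

    def test_empty(self):
        assert da.adjust_bh([]).size == 0

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        adj = da.adjust_bh(p)
        assert (adj >= p - 1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            da.adjust_bh([0.5, 1.5])

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50)
    )
    def test_matches_brute_force(self, p):
        assert np.allclose(da.adjust_bh(p), bh_brute_force(p), atol=0)


class TestCallDmps:
    def _gs(self, deltas):
        n = len(deltas)
        return da.GroupStats(
            [f"p{i}" for i in range(n)],
            np.full(n, 0.5) + np.asarray(deltas) / 2,
            np.full(n, 0.5) - np.asarray(deltas) / 2,
            np.asarray(deltas, dtype=float),
        )

    def test_strict_delta_threshold(self):
        gs = self._gs([0.10])
        assert da.call_dmps(gs, [0.001], [0.01]) == []

    def test_strict_alpha_threshold(self):
        gs = self._gs([0.3])
        assert da.call_dmps(gs, [0.05], [0.06]) == []
        assert da.call_dmps(gs, [0.05], [0.05]) == []

    def test_direction_by_sign(self):
        gs = self._gs([0.2, -0.2])
        dmps = da.call_dmps(gs, [0.001, 0.001], [0.01, 0.01])
        assert [d.direction for d in dmps] == ["hyper", "hypo"]

    def test_hyper_plus_hypo_equals_total(self, default_cohort):
        _, _, bm, sheet, _ = default_cohort
        dmps, _, _, _ = da.run_dmp_analysis(bm, sheet)
        n_hyper = sum(d.direction == "hyper" for d in dmps)
        n_hypo = sum(d.direction == "hypo" for d in dmps)
        assert n_hyper + n_hypo == len(dmps)

    def test_record_invariants(self, default_cohort):
        _, _, bm, sheet, _ = default_cohort
        dmps, _, _, _ = da.run_dmp_analysis(bm, sheet)
        assert dmps  # planted effects exist
        for d in dmps:
            assert -1 <= d.delta_beta <= 1
            assert abs(d.delta_beta) > 0.1
            assert d.p_adj < 0.05
            assert d.p_adj >= d.p_raw
            assert (d.direction == "hyper") == (d.delta_beta > 0)


class TestPCA:
    def test_identical_samples_identical_coords(self):
        beta = np.tile(np.linspace(0.1, 0.9, 5)[:, None], (1, 4))
        bm = make_beta(beta)
        scores, frac = da.pca_embed(bm, k=2)
        assert np.allclose(scores.iloc[0], scores.iloc[1])

    def test_variance_fractions_sum_le_one(self, default_cohort):
        _, _, bm, _, _ = default_cohort
        _, frac = da.pca_embed(bm, k=2)
        assert frac.sum() <= 1.0 + 1e-12

    def test_k_too_large(self):
        bm = make_beta(np.full((3, 2), 0.5))
        with pytest.raises(ValueError):
            da.pca_embed(bm, k=3)

    def test_dmp_subset_separates_groups_better(self, default_cohort):
        _, _, bm, sheet, _ = default_cohort
        dmps, _, _, _ = da.run_dmp_analysis(bm, sheet)
        labels = sheet.df["group"].to_numpy()
        all_scores, _ = da.pca_embed(bm, k=2)
        sub = bm.subset_probes([d.probe_id for d in dmps])
        dmp_scores, _ = da.pca_embed(sub, k=2)
        s_all = silhouette_score(all_scores.to_numpy(), labels)
        s_dmp = silhouette_score(dmp_scores.to_numpy(), labels)
        assert s_dmp > s_all


class TestRegionCompare:
    def _manifest(self):
        probes = [
            make_probe(probe_id="p0", gene_mappings=[("G1", "TSS200")]),
            make_probe(probe_id="p1", gene_mappings=[("G1", "5UTR")]),
            make_probe(probe_id="p2", gene_mappings=[("G2", "Body")]),
            make_probe(probe_id="p3", gene_mappings=[("G2", "3UTR")]),
            make_probe(probe_id="p4"),
        ]
        return Manifest(probes)

    def test_identical_groups(self):
        beta = np.tile(np.linspace(0.1, 0.9, 5)[:, None], (1, 4))
        bm = make_beta(beta, probe_ids=[f"p{i}" for i in range(5)],
                       sample_ids=["HT1", "HT2", "C1", "C2"])
        mc, mn, p = da.region_methylation_compare(bm, make_sheet(), self._manifest(), "genome")
        assert mc == pytest.approx(mn)
        assert p == pytest.approx(1.0)

    def test_promoter_subset_definition(self):
        manifest = self._manifest()
        ids = da._region_probe_ids(manifest, "promoter", {f"p{i}" for i in range(5)})
        assert ids == ["p0", "p1"]
        assert da._region_probe_ids(manifest, "IGR", {f"p{i}" for i in range(5)}) == ["p4"]

    def test_empty_region_errors(self):
        beta = np.full((1, 4), 0.5)
        bm = make_beta(beta, probe_ids=["p2"], sample_ids=["HT1", "HT2", "C1", "C2"])
        with pytest.raises(ValueError, match="promoter"):
            da.region_methylation_compare(bm, make_sheet(), Manifest(
                [make_probe(probe_id="p2", gene_mappings=[("G", "Body")])]), "promoter")

    def test_planted_hypomethylation_detected(self):
        rng = np.random.default_rng(7)
        n, npg = 400, 10

        def expit(x):
            return 1 / (1 + np.exp(-x))

        base = rng.uniform(-2, 2, size=n)
        control = expit(base[:, None] + rng.normal(0, 0.3, (n, npg)))
        case = expit(base[:, None] - 0.3 + rng.normal(0, 0.3, (n, npg)))
        bm = make_beta(
            np.round(np.hstack([case, control]), 6),
            probe_ids=[f"q{i}" for i in range(n)],
            sample_ids=[f"HT{i+1}" for i in range(npg)] + [f"C{i+1}" for i in range(npg)],
        )
        manifest = Manifest([make_probe(probe_id=f"q{i}") for i in range(n)])
        mc, mn, p = da.region_methylation_compare(bm, make_sheet(npg, npg), manifest, "genome")
        assert mc < mn
        assert p < 0.001
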