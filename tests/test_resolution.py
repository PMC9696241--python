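"""Replicate error estimation and error-thresholded genotype resolution."""

import numpy as np
import pytest

from clonotyper.distance import pairwise_p_distance, single_linkage
from clonotyper.errors import MetadataError, UndefinedDistanceError
from clonotyper.matrix import SampleRecord, recode_binary
from clonotyper.resolution import (
    estimate_error,
    pair_replicates,
    resolution_report,
    resolve_genotypes,
)

from conftest import PANEL, make_matrix, matrix_with_edges, random_nucleotide_matrix


class TestPairReplicates:
    def test_suffix_pairing(self):
        samples = [
            SampleRecord("7379"),
            SampleRecord("7379r", replicate_of="7379"),
            SampleRecord("9242"),
        ]
        assert pair_replicates(samples) == [("7379", "7379r")]

    def test_no_replicates(self):
        assert pair_replicates([SampleRecord("a"), SampleRecord("b")]) == []

    def test_eight_pairs(self):
        samples = []
        for i in range(8):
            samples.append(SampleRecord(f"c{i}"))
            samples.append(SampleRecord(f"c{i}r", replicate_of=f"c{i}"))
        assert len(pair_replicates(samples)) == 8

    def test_dangling_pointer(self):
        with pytest.raises(MetadataError, match="ghost"):
            pair_replicates([SampleRecord("x", replicate_of="ghost")])


class TestEstimateError:
    def test_identical_replicates(self):
        d = pairwise_p_distance(make_matrix({"A": "acgt", "Ar": "acgt"}))
        est = estimate_error(d, [("A", "Ar")])
        assert est.mean_rate == est.max_rate == 0.0
        assert est.determined

    def test_ssr_style_mean_over_eight_pairs(self):
        # 8 replicate pairs over 95 binary characters; two pairs carry one
        # mismatch each -> mean rate 2/760 ~ 0.263%, printed as 0.26
        rows = {}
        base = "1" * 95
        for i in range(8):
            rows[f"c{i}"] = base
            rep = base if i >= 2 else base[:-1] + "0"
            rows[f"c{i}r"] = rep
        m = recode_binary(make_matrix(rows, marker_type="FLP"))
        d = pairwise_p_distance(m)
        est = estimate_error(d, pair_replicates(m.samples))
        assert est.n_pairs == 8
        assert est.mean_rate == pytest.approx(2 / 760)
        assert f"{est.mean_pct:.2f}" == "0.26"
        assert est.max_rate == pytest.approx(1 / 95)
        assert est.pooled_rate == pytest.approx(2 / 760)

    def test_zero_pairs_not_determined(self):
        d = pairwise_p_distance(make_matrix({"A": "ac", "B": "ac"}))
        est = estimate_error(d, [])
        assert not est.determined
        assert est.mean_rate is None and est.mean_pct is None

    def test_undefined_replicate_distance_refused(self):
        d = pairwise_p_distance(make_matrix({"A": "nn", "Ar": "aa"}))
        with pytest.raises(UndefinedDistanceError):
            estimate_error(d, [("A", "Ar")])




class TestResolveGenotypes:
    def test_all_distinct_is_trivial(self):
        d = pairwise_p_distance(matrix_with_edges(PANEL, {}))
        res = resolve_genotypes(d, 0.0)
        assert res.n_genotypes == 23
        assert res.indistinguishable_pairs == []

    def test_identical_triple_at_zero_threshold(self):
        # three clones sharing one data point -> 21 genotypes from 23
        rows = {cid: "a" * 50 for cid in PANEL}
        rng = np.random.default_rng(0)
        for i, cid in enumerate(PANEL):
            if cid not in {"7379", "9503", "9506"}:
                r = list(rows[cid])
                for j in range(3):
                    r[(3 * i + j) % 50] = "cgt"[j]
                rows[cid] = "".join(r)
        d = pairwise_p_distance(make_matrix(rows))
        res = resolve_genotypes(d, 0.0)
        assert res.n_genotypes == 21
        assert frozenset({"7379", "9503", "9506"}) in res.clusters

    def test_six_edges_chain_to_seventeen(self):
        # chaining: six indistinguishable pairs collapse 23 clones into 17
        # genotypes because {7379,9503,9506,9316,9290} forms one component
        edges = {
            "7551": ["9512"],
            "9506": ["7379", "9503", "9316"],
            "9316": ["9290"],
            "9509": ["9508"],
        }
        # 9316 is both leaf of 9506 and hub of 9290: build explicitly
        m = matrix_with_edges(
            PANEL, {"7551": ["9512"], "9506": ["7379", "9503"], "9509": ["9508"]}
        )
        rows = {cid: "".join(m.row(cid)) for cid in PANEL}
        # attach 9316 near 9506 and 9290 near 9316
        rows["9316"] = rows["9506"][:-4] + "cc" + rows["9506"][-2:]
        rows["9290"] = rows["9316"][:-2] + "cc"
        d = pairwise_p_distance(make_matrix(rows))
        res = resolve_genotypes(d, threshold=0.003)
        assert res.n_genotypes == 17
        comp = {c for c in res.clusters if "9506" in c}
        assert comp == {frozenset({"7379", "9503", "9506", "9316", "9290"})}
        assert ("9316", "9506") in res.indistinguishable_pairs
        assert ("7379", "9503") not in res.indistinguishable_pairs

    def test_threshold_is_inclusive(self):
        m = matrix_with_edges(["A", "B"], {"A": ["B"]}, n_chars=100, k_edge=1)
        d = pairwise_p_distance(m)
        p = d.get("A", "B")
        assert resolve_genotypes(d, p).n_genotypes == 1
        assert resolve_genotypes(d, p * 0.99).n_genotypes == 2

    def test_replicates_excluded_with_metadata(self):
        m = make_matrix({"A": "acgt", "Ar": "acgt", "B": "tttt"})
        d = pairwise_p_distance(m)
        res = resolve_genotypes(d, 0.0, samples=m.samples)
        assert res.n_genotypes == 2
        assert all("Ar" not in c for c in res.clusters)

    def test_nontransitive_zero_distances_chain(self):
        # pairwise deletion can make indistinguishability non-transitive:
        # A~B and B~C at p=0 while A and C differ; chaining merges all three
        m = make_matrix({"A": "aan", "B": "ann", "C": "acn"})
        d = pairwise_p_distance(m)
        assert d.get("A", "B") == 0.0
        assert d.get("B", "C") == 0.0
        assert d.get("A", "C") == 0.5
        res = resolve_genotypes(d, 0.0)
        assert res.n_genotypes == 1

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        m = random_nucleotide_matrix(rng, n_samples=10, n_chars=60, p_ambig=0.1)
        d = pairwise_p_distance(m)
        counts = [
            resolve_genotypes(d, t).n_genotypes
            for t in np.linspace(0, 1, 21)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_zero_threshold_without_ambiguity_dedups_rows(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            m = random_nucleotide_matrix(rng, n_samples=8, n_chars=6, p_ambig=0.0)
            d = pairwise_p_distance(m)
            res = resolve_genotypes(d, 0.0)
            distinct_rows = {"".join(m.row(i)) for i in m.sample_ids}
            assert res.n_genotypes == len(distinct_rows)

    def test_components_equal_dendrogram_cut(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            m = random_nucleotide_matrix(rng, n_samples=8, n_chars=40, p_ambig=0.05)
            d = pairwise_p_distance(m)
            if d.undefined_pairs:
                continue
            tree = single_linkage(d)
            for t in [0.0, 0.05, 0.1, 0.2, 0.5]:
                res = resolve_genotypes(d, t)
                assert set(res.clusters) == set(tree.cut(t))

    def test_undefined_pair_names_the_pair(self):
        d = pairwise_p_distance(make_matrix({"A": "nn", "B": "aa", "C": "aa"}))
        with pytest.raises(UndefinedDistanceError, match="'A' and 'B'"):
            resolve_genotypes(d, 0.0)


class TestResolutionReport:
    def test_flp_without_replicates_reports_nd(self):
        rows = {f"s{i}": "".join("01"[(i >> j) & 1] for j in range(13)) for i in range(8)}
        m = make_matrix(rows, marker_type="FLP")
        summary = resolution_report(m, name="tbp")
        assert summary.n_characters == 13
        assert not summary.error.determined
        assert list(summary.resolutions) == ["zero"]
        assert summary.to_row()["error_display"] == "n.d."

    def test_report_matches_simulated_truth(self):
        from clonotyper.simulate import SimulationConfig, simulate_panel

        cfg = SimulationConfig(
            n_genotypes=6,
            clones_per_genotype=[2, 1, 1, 1, 1, 1],
            n_characters=300,
            divergence=0.1,
            heterozygosity=0.0,
            error_rate=0.0,
            seed=4,
        )
        matrix, samples, truth = simulate_panel(cfg)
        summary = resolution_report(matrix, name="sim")
        assert summary.resolutions["zero"].n_genotypes == 6
        assert summary.error.mean_rate == 0.0

    def test_replicate_columns_not_counted_as_clones(self):
        m = make_matrix({"A": "acgt", "Ar": "acgt", "B": "tttt", "C": "gggg"})
        summary = resolution_report(m)
        assert summary.resolutions["zero"].n_genotypes == 3
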