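"""Marker QC, recombination fractions, grouping, ordering, map building."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aphidqtl import linkage, simulate
from aphidqtl.simulate import AA, AB, BB, MISSING

from conftest import make_founders_from_map


def _two_marker_founders(chrom="A1"):
    markers = pd.DataFrame(
        {"marker": ["a", "b"], "chrom": [chrom] * 2, "bp": [1, 2],
         "cM": [0.0, 1.0]}
    )
    return make_founders_from_map(markers)


class TestFilterMarkers:
    def test_perfect_1_2_1_retained(self):
        fd = _two_marker_founders()
        col = np.array([AA] * 48 + [AB] * 96 + [BB] * 48, dtype=np.int8)
        geno = pd.DataFrame({"a": col, "b": col[::-1]})
        retained, report = linkage.filter_markers(geno, fd,
                                                  collapse_redundant=False)
        assert list(retained.columns) == ["a", "b"]
        assert report.counts() == {}

    def test_distorted_marker_removed(self):
        # 96:96:0 of 192 gives a chi-square of 96 >> the 13.8 cutoff at p=0.001
        fd = _two_marker_founders()
        ok = np.array([AA] * 48 + [AB] * 96 + [BB] * 48, dtype=np.int8)
        bad = np.array([AA] * 96 + [AB] * 96 + [BB] * 0, dtype=np.int8)
        geno = pd.DataFrame({"a": ok, "b": bad})
        retained, report = linkage.filter_markers(geno, fd,
                                                  collapse_redundant=False)
        assert "b" in report.removed["distorted"]
        assert list(retained.columns) == ["a"]

    def test_uninformative_parents_removed(self):
        markers = pd.DataFrame(
            {"marker": ["u", "h", "ok"], "chrom": ["A1"] * 3, "bp": [1, 2, 3],
             "cM": [0.0, 1.0, 2.0]}
        )
        fd = make_founders_from_map(markers)
        fd.f0[:, 0] = AA            # monomorphic across races
        fd.f0[0, 1] = AB            # heterozygous F0
        col = np.array([AA] * 48 + [AB] * 96 + [BB] * 48, dtype=np.int8)
        geno = pd.DataFrame({"u": col, "h": col, "ok": col[::-1]})
        retained, report = linkage.filter_markers(geno, fd,
                                                  collapse_redundant=False)
        assert sorted(report.removed["uninformative"]) == ["h", "u"]
        assert list(retained.columns) == ["ok"]

    def test_all_missing_column_flagged_no_data(self):
        fd = _two_marker_founders()
        ok = np.array([AA] * 48 + [AB] * 96 + [BB] * 48, dtype=np.int8)
        geno = pd.DataFrame({"a": ok, "b": np.full(192, MISSING, dtype=np.int8)})
        _retained, report = linkage.filter_markers(geno, fd)
        assert report.removed["no_data"] == ["b"]

    def test_redundant_collapse_keeps_least_missing(self):
        markers = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": ["A1"] * 2, "bp": [1, 2],
             "cM": [0.0, 0.0]}
        )
        fd = make_founders_from_map(markers)
        col = np.array([AA] * 48 + [AB] * 96 + [BB] * 48, dtype=np.int8)
        col2 = col.copy()
        col2[:5] = MISSING
        geno = pd.DataFrame({"a": col2, "b": col})
        retained, report = linkage.filter_markers(geno, fd)
        assert report.removed["redundant"] == ["a"]
        assert list(retained.columns) == ["b"]

    def test_truth_record_oracle_on_simulated_cross(self):
        """On error-free data the filter removes exactly the markers
        constructed to violate each rule."""
        cfg = simulate.CrossConfig(
            n_f2=192, n_markers=50, error_rate=0.0, missing_rate=0.0,
            frac_uninformative=0.1, frac_f0_het=0.05, frac_distorted=0.05,
            seed=21,
        )
        fd = simulate.simulate_founders(cfg)
        geno, _truth = simulate.simulate_f2_genotypes(fd, cfg)
        _retained, report = linkage.filter_markers(geno, fd,
                                                   collapse_redundant=False)
        mk = fd.markers
        expected_uninf = set(mk.loc[mk["uninformative"] | mk["f0_het"], "marker"])
        assert set(report.removed["uninformative"]) == expected_uninf
        distorted_true = set(mk.loc[mk["distorted"] & ~mk["uninformative"]
                                    & ~mk["f0_het"], "marker"])
        assert set(report.removed.get("distorted", [])) == distorted_true


class TestEstimateRF:
    def test_identical_columns_r_zero_lod_maximal(self):
        col = np.array([AA] * 50 + [AB] * 100 + [BB] * 50, dtype=np.int8)
        r, lod, flags = linkage.estimate_rf(col, col)
        assert r == 0.0
        assert lod == pytest.approx(200 * np.log10(2))
        assert flags == []

    def test_unlinked_markers_near_half_low_lod(self):
        rng = np.random.default_rng(0)
        lods, rs = [], []
        for _ in range(20):
            a = rng.choice([AA, AB, AB, BB], size=188).astype(np.int8)
            b = rng.choice([AA, AB, AB, BB], size=188).astype(np.int8)
            r, lod, _ = linkage.estimate_rf(a, b)
            rs.append(r)
            lods.append(lod)
        assert np.mean(rs) > 0.45
        assert np.median(lods) < 3

    def test_low_support_flag(self):
        a = np.array([AA] * 5 + [MISSING] * 50, dtype=np.int8)
        _r, _lod, flags = linkage.estimate_rf(a, a)
        assert "low_support" in flags

    def test_conflict_cells_flagged(self):
        a = np.array([AA, BB] * 20, dtype=np.int8)
        b = np.array([BB, AA] * 20, dtype=np.int8)
        _r, _lod, flags = linkage.estimate_rf(a, b)
        assert "conflict" in flags

    def test_estimator_consistency_at_r_010(self):
        """Mean r over replicates within +/-0.01 of the true female r."""
        rng = np.random.default_rng(42)
        n, r_true = 2000, 0.10
        est = []
        for _ in range(100):
            m1 = rng.integers(0, 2, n)
            rec = rng.random(n) < r_true
            m2 = np.where(rec, 1 - m1, m1)
            h = rng.integers(0, 2, n)
            g1 = (m1 + h).astype(np.int8)
            g2 = (m2 + h).astype(np.int8)
            r, _lod, _ = linkage.estimate_rf(g1, g2)
            est.append(r)
        assert abs(np.mean(est) - r_true) < 0.01

    def test_pairwise_matches_single_pair_oracle(self, clean_cross, marker_info):
        _cfg, _fd, geno, _truth = clean_cross
        cols = [c for c in geno.columns[::13]]
        sub = geno[cols]
        is_x = (marker_info.loc[cols, "chrom"] == "X").to_numpy()
        R, LOD = linkage.pairwise_rf(sub, is_x)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                r, lod, _ = linkage.estimate_rf(
                    sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy(),
                    bool(is_x[i]), bool(is_x[j]),
                )
                assert R[i, j] == pytest.approx(r, abs=1e-12)
                assert LOD[i, j] == pytest.approx(lod, abs=1e-9)


@pytest.fixture(scope="module")
def lod_and_markers(clean_cross, marker_info):
    _cfg, _fd, geno, _truth = clean_cross
    is_x = (marker_info.loc[geno.columns, "chrom"] == "X").to_numpy()
    _r, lod = linkage.pairwise_rf(geno, is_x)
    return lod, list(geno.columns)


class TestGrouping:
    def test_four_chromosome_plateau(self, lod_and_markers, marker_info):
        lod, markers = lod_and_markers
        scan = linkage.threshold_scan(lod, markers, np.arange(4, 20, 2.0),
                                      size_limit=5)
        assert (scan["n_groups"] == 4).sum() >= 3  # a plateau of thresholds
        gs = linkage.group_markers(lod, markers, 8.0, size_limit=5)
        assert sorted(gs.sizes()) == [30, 30, 30, 30]
        for g in gs.groups:
            assert marker_info.loc[g, "chrom"].nunique() == 1

    def test_threshold_above_all_lods_dissolves_everything(self, lod_and_markers):
        lod, markers = lod_and_markers
        gs = linkage.group_markers(lod, markers, lod.max() + 1, size_limit=2)
        assert gs.groups == []
        assert len(gs.singletons) == len(markers)

    def test_join_singles_rule(self):
        markers = ["g1a", "g1b", "g1c", "g2a", "g2b", "g2c", "lone"]
        lod = np.zeros((7, 7))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            lod[i, j] = lod[j, i] = 20.0
        lod[6, 3] = lod[3, 6] = 3.2  # best link of the singleton: group 2
        gs = linkage.group_markers(lod, markers, 10.0, size_limit=3, join_lod=3.0)
        joined = [g for g in gs.groups if "lone" in g]
        assert len(joined) == 1 and "g2a" in joined[0]
        gs2 = linkage.group_markers(lod, markers, 10.0, size_limit=3, join_lod=3.5)
        assert gs2.singletons == ["lone"]

    def test_input_order_invariance(self, lod_and_markers):
        lod, markers = lod_and_markers
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(markers))
        gs1 = linkage.group_markers(lod, markers, 8.0, size_limit=5)
        gs2 = linkage.group_markers(
            lod[np.ix_(perm, perm)], [markers[i] for i in perm], 8.0, size_limit=5
        )
        assert gs1.groups == gs2.groups

    def test_nonpositive_threshold_rejected(self, lod_and_markers):
        lod, markers = lod_and_markers
        with pytest.raises(ValueError):
            linkage.group_markers(lod, markers, 0.0)


class TestOrdering:
    def test_triangle_order(self):
        r = np.array([[0.0, 0.1, 0.18], [0.1, 0.0, 0.1], [0.18, 0.1, 0.0]])
        order, _rep = linkage.order_markers(r, ["A", "B", "C"], n_runs=3, seed=0)
        assert order in (["A", "B", "C"], ["C", "B", "A"])

    def test_known_order_recovered(self):
        """Markers at uniform r=0.05 spacing, n=500 meioses."""
        rng = np.random.default_rng(8)
        m, n = 12, 500
        mat = np.empty((n, m), dtype=np.int8)
        mat[:, 0] = rng.integers(0, 2, n)
        for j in range(1, m):
            rec = rng.random(n) < 0.05
            mat[:, j] = np.where(rec, 1 - mat[:, j - 1], mat[:, j - 1])
        h = rng.integers(0, 2, n)
        geno = pd.DataFrame(
            {f"m{j:02d}": (mat[:, j] + h).astype(np.int8) for j in range(m)}
        )
        r, _lod = linkage.pairwise_rf(geno, np.zeros(m, dtype=bool))
        names = list(geno.columns)
        order, report = linkage.order_markers(r, names, n_runs=6, seed=1)
        assert not report["unstable"].any()
        assert order in (names, names[::-1])

    def test_cosegregating_group_stable(self):
        r = np.zeros((4, 4))
        order, report = linkage.order_markers(r, list("dcba"), n_runs=3, seed=0)
        assert order == list("abcd")
        assert (report["flag"] == "co-segregating").all()

    def test_rank_range_bookkeeping(self):
        rng = np.random.default_rng(3)
        m = 8
        base = np.abs(np.subtract.outer(np.arange(m), np.arange(m))) * 0.05
        noise = rng.normal(0, 0.04, (m, m))
        r = np.clip(base + (noise + noise.T) / 2, 0.001, 0.5)
        np.fill_diagonal(r, 0)
        _order, report = linkage.order_markers(r, [f"m{i}" for i in range(m)],
                                               n_runs=10, seed=5)
        assert (report["unstable"] == (report["rank_range"] > 2)).all()


class TestGeneticMap:
    def test_haldane_round_trip(self):
        assert linkage.haldane_cm(0.0) == 0.0
        assert linkage.haldane_cm(0.0906346) == pytest.approx(10.0, abs=1e-3)
        assert linkage.inverse_haldane(10.0) == pytest.approx(0.0906346, abs=1e-6)

    def test_cosegregating_markers_share_position(self):
        col = np.array([AA] * 50 + [AB] * 100 + [BB] * 50, dtype=np.int8)
        geno = pd.DataFrame({"a": col, "b": col, "c": col})
        gmap = linkage.build_genetic_map({"g": ["a", "b", "c"]}, geno)
        assert np.allclose(gmap["cM"], 0.0)

    def test_unlinked_adjacent_capped_and_flagged(self):
        rng = np.random.default_rng(0)
        a = rng.choice([AA, AB, AB, BB], size=500).astype(np.int8)
        b = rng.choice([AA, AB, AB, BB], size=500).astype(np.int8)
        geno = pd.DataFrame({"a": a, "b": b})
        gmap = linkage.build_genetic_map({"g": ["a", "b"]}, geno, max_gap_cm=50.0)
        assert gmap["cM"].iloc[-1] <= 50.0
        assert (gmap["flag"] == "capped").any()

    def test_a3_scale_length_recovery(self):
        """62 markers on a 114 cM chromosome, n=188: estimated length
        within 15% of truth on average."""
        lengths = []
        for rep in range(50):
            cfg = simulate.CrossConfig(
                n_f2=188, chromosomes=(("A3", 114.0, 135.0),), n_markers=62,
                error_rate=0.0, missing_rate=0.0, seed=1000 + rep,
            )
            fd = simulate.simulate_founders(cfg)
            geno, _ = simulate.simulate_f2_genotypes(fd, cfg)
            order = list(fd.markers.sort_values("cM")["marker"])
            gmap = linkage.build_genetic_map({"A3": order}, geno)
            true_len = fd.markers["cM"].max() - fd.markers["cM"].min()
            lengths.append(gmap["cM"].max() / true_len)
        assert abs(np.mean(lengths) - 1.0) < 0.15


class TestErrorLod:
    def _map(self, n_markers, spacing):
        return pd.DataFrame(
            {
                "marker": [f"m{j}" for j in range(n_markers)],
                "chrom": ["A1"] * n_markers,
                "cM": np.arange(n_markers) * spacing,
            }
        )

    def test_concordant_call_negative(self):
        n_markers = 5
        geno = pd.DataFrame(
            {f"m{j}": np.full(4, BB, dtype=np.int8) for j in range(n_markers)}
        )
        report, flagged = linkage.error_lod_flag(
            geno, self._map(n_markers, 1.0), epsilon=0.001
        )
        assert flagged == []
        assert (report["max_error_lod"] < 0).all()

    def test_isolated_discordant_call_flagged(self):
        n_markers = 21
        codes = np.full((4, n_markers), BB, dtype=np.int8)
        codes[0, 10] = AA  # single AA amid dense BB neighbors
        geno = pd.DataFrame({f"m{j}": codes[:, j] for j in range(n_markers)})
        report, flagged = linkage.error_lod_flag(
            geno, self._map(n_markers, 0.5), threshold=5.0, epsilon=0.001
        )
        assert "m10" in flagged
        row = report.set_index("marker").loc["m10"]
        assert row["max_error_lod"] > 5

    def test_error_free_data_rarely_flagged(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = simulate.CrossConfig(
                n_f2=96, n_markers=25, error_rate=0.0, missing_rate=0.0,
                chromosomes=(("A1", 100.0, 100.0),), seed=300 + seed,
            )
            fd = simulate.simulate_founders(cfg)
            geno, _ = simulate.simulate_f2_genotypes(fd, cfg)
            _rep, flagged = linkage.error_lod_flag(
                geno, fd.markers[["marker", "chrom", "cM"]], threshold=5.0,
                epsilon=0.001,
            )
            hits += bool(flagged)
        assert hits <= 1  # >= 95% of seeds clean, at 10 seeds allow one

    def test_sparse_chromosome_flagged(self):
        geno = pd.DataFrame({"m0": np.full(4, AA, dtype=np.int8),
                             "m1": np.full(4, AA, dtype=np.int8)})
        report, _ = linkage.error_lod_flag(geno, self._map(2, 1.0))
        assert (report["flag"] == "too_sparse").all()
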