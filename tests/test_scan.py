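"""HMM genotype probabilities and the two single-QTL scan statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aphidqtl import scan, simulate
from aphidqtl.linkage import inverse_haldane
from aphidqtl.simulate import AA, AB, BB, MISSING

from conftest import make_founders_from_map

LN10 = np.log(10.0)


@pytest.fixture(scope="module")
def genoprob(clean_cross):
    _cfg, fd, geno, _truth = clean_cross
    return scan.calc_genoprob(
        geno, fd.markers[["marker", "chrom", "cM"]], step=2.0, epsilon=0.0
    )


class TestGenoProb:
    def test_probabilities_normalize(self, genoprob):
        for dat in genoprob.chromosomes.values():
            s = dat["probs"].sum(axis=2)
            assert np.allclose(s, 1.0, atol=1e-12)

    def test_typed_marker_degenerate_at_zero_error(self, genoprob, clean_cross):
        _cfg, _fd, geno, _truth = clean_cross
        for dat in genoprob.chromosomes.values():
            for slot, mk in enumerate(dat["marker_ids"]):
                if not mk:
                    continue
                obs = geno[mk].to_numpy()
                p = dat["probs"][np.arange(len(obs)), slot, obs]
                assert np.allclose(p, 1.0, atol=1e-12)
                break  # one marker per chromosome is enough

    def test_interior_posterior_matches_path_enumeration(self):
        """Pseudo-position between AA and AB flanks: enumerate the hidden
        paths by hand and compare posteriors."""
        markers = pd.DataFrame(
            {"marker": ["l", "r"], "chrom": ["A1"] * 2, "bp": [1, 2],
             "cM": [0.0, 20.0]}
        )
        geno = pd.DataFrame({"l": [AA], "r": [AB]}, index=["o1"], dtype=np.int8)
        gp = scan.calc_genoprob(geno, markers, step=5.0, epsilon=0.0)
        dat = gp.chromosomes["A1"]
        # AA at the left marker pins the paternal haplotype to A; the
        # maternal allele runs A -> B, so at an interior point
        # P(class AA) = P(maternal still A) over the two-interval paths
        for slot, pos in enumerate(dat["positions"]):
            if dat["is_marker"][slot]:
                continue
            r1 = inverse_haldane(pos - 0.0)
            r2 = inverse_haldane(20.0 - pos)
            p_aa = (1 - r1) * r2 / ((1 - r1) * r2 + r1 * (1 - r2))
            assert dat["probs"][0, slot, 0] == pytest.approx(p_aa, abs=1e-10)
            assert dat["probs"][0, slot, 1] == pytest.approx(1 - p_aa, abs=1e-10)
            assert dat["probs"][0, slot, 2] == pytest.approx(0.0, abs=1e-12)

    def test_error_rate_softens_posteriors(self, clean_cross):
        _cfg, fd, geno, _truth = clean_cross
        gp = scan.calc_genoprob(
            geno, fd.markers[["marker", "chrom", "cM"]], step=0.0, epsilon=0.01
        )
        dat = gp.chromosomes["A1"]
        p = dat["probs"]
        assert p.max() < 1.0
        assert np.allclose(p.sum(axis=2), 1.0, atol=1e-12)

    def test_x_chromosome_two_classes(self, genoprob):
        dat = genoprob.chromosomes["X"]
        assert dat["n_classes"] == 2
        assert np.allclose(dat["probs"][:, :, 2], 0.0)

    def test_invalid_epsilon_rejected(self, clean_cross):
        _cfg, fd, geno, _truth = clean_cross
        with pytest.raises(ValueError):
            scan.calc_genoprob(geno, fd.markers, epsilon=0.7)


class TestNonparametricScan:
    def test_equals_kruskal_wallis_at_informative_marker(
        self, genoprob, clean_cross
    ):
        _cfg, fd, geno, truth = clean_cross
        rng = np.random.default_rng(0)
        y = pd.Series(rng.normal(size=192) + geno.iloc[:, 5].to_numpy(),
                      index=geno.index)
        res = scan.scan_nonparametric(genoprob, y)
        for chrom, dat in genoprob.chromosomes.items():
            for slot, mk in enumerate(dat["marker_ids"]):
                if not mk:
                    continue
                obs = geno[mk].to_numpy()
                groups = [y.to_numpy()[obs == g] for g in range(dat["n_classes"])]
                groups = [g for g in groups if len(g)]
                if len(groups) < 2:
                    continue
                H = stats.kruskal(*groups).statistic
                got = res.table[
                    (res.table["chrom"] == chrom)
                    & (np.isclose(res.table["pos"], dat["positions"][slot]))
                ]["lod"].iloc[0]
                assert got == pytest.approx(H / (2 * LN10), abs=1e-10)

    def test_monotone_transform_invariance(self, genoprob, clean_cross):
        _cfg, _fd, geno, _truth = clean_cross
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(size=192), index=geno.index)
        a = scan.scan_nonparametric(genoprob, y)
        b = scan.scan_nonparametric(genoprob, np.exp(y) - 3.0)
        assert np.allclose(a.table["lod"], b.table["lod"], atol=1e-10)

    def test_constant_trait_warns_and_returns_zero(self, genoprob):
        y = pd.Series(np.ones(192), index=genoprob.individuals)
        with pytest.warns(UserWarning, match="constant"):
            res = scan.scan_nonparametric(genoprob, y)
        assert (res.table["lod"] == 0).all()

    def test_perfect_signal_peaks_at_marker(self, genoprob, clean_cross):
        _cfg, fd, geno, _truth = clean_cross
        mk = fd.markers.iloc[40]
        y = pd.Series(geno[mk["marker"]].to_numpy().astype(float),
                      index=geno.index)
        res = scan.scan_nonparametric(genoprob, y)
        best = res.table.loc[res.table["lod"].idxmax()]
        assert best["chrom"] == mk["chrom"]
        assert abs(best["pos"] - mk["cM"]) < 1.0


def _twopart_marker_ml(y, z, obs, n_classes):
    """Closed-form marker ML for the two-part model (hard classes)."""

    def part_ll(zz, yy):
        ll = 0.0
        k, n = zz.sum(), len(zz)
        if 0 < k < n:
            pi = k / n
            ll += k * np.log(pi) + (n - k) * np.log(1 - pi)
        return ll

    ll0 = part_ll(z, y)
    ynz = y[~z]
    sd0 = ynz.std()
    if ynz.size and sd0 > 0:
        ll0 += stats.norm.logpdf(ynz, ynz.mean(), sd0).sum()
    # alternative: class-specific spike probability and mean, shared sd
    ll_alt = 0.0
    resid_ss, n_nz = 0.0, 0
    means = {}
    for g in range(n_classes):
        sel = obs == g
        ll_alt += part_ll(z[sel], y[sel])
        ynzg = y[sel & ~z]
        if ynzg.size:
            means[g] = ynzg.mean()
            resid_ss += ((ynzg - ynzg.mean()) ** 2).sum()
            n_nz += ynzg.size
    if n_nz:
        sd = np.sqrt(resid_ss / n_nz)
        for g, mu in means.items():
            ynzg = y[(obs == g) & ~z]
            ll_alt += stats.norm.logpdf(ynzg, mu, sd).sum()
    return (ll_alt - ll0) / LN10


class TestTwoPartScan:
    def test_all_spike_gives_zero(self, genoprob):
        y = pd.Series(np.full(192, 17.0), index=genoprob.individuals)
        res = scan.scan_twopart(genoprob, y)
        assert (res.table["lod"] == 0).all()

    def test_matches_closed_form_ml_at_informative_marker(
        self, genoprob, clean_cross
    ):
        _cfg, fd, geno, truth = clean_cross
        model = simulate.PhenotypeModel(
            name="sv", architecture=[("A2", 50.0, 0.7, 0.0)], polygenic_var=0.1,
            h2=0.35,
        )
        ph = simulate.simulate_phenotypes(truth, model, seed=6, mode="direct")
        y = ph["survival_steps"]
        res = scan.scan_twopart(genoprob, y)
        yv = y.to_numpy()
        z = yv == yv.max()
        checked = 0
        for chrom, dat in genoprob.chromosomes.items():
            for slot, mk in enumerate(dat["marker_ids"]):
                if not mk or not dat["is_marker"][slot]:
                    continue
                obs = geno[mk].to_numpy()
                want = _twopart_marker_ml(yv, z, obs, dat["n_classes"])
                got = res.table[
                    (res.table["chrom"] == chrom)
                    & (np.isclose(res.table["pos"], dat["positions"][slot]))
                ]["lod"].iloc[0]
                assert got == pytest.approx(max(want, 0.0), abs=1e-6)
                checked += 1
                break  # first marker of each chromosome
        assert checked == 4

    def test_joint_lod_bounded_by_components_at_marker(self, genoprob,
                                                       clean_cross):
        _cfg, _fd, geno, truth = clean_cross
        model = simulate.PhenotypeModel(name="sv2", polygenic_var=1.0, h2=0.3)
        ph = simulate.simulate_phenotypes(truth, model, seed=9, mode="direct")
        res = scan.scan_twopart(genoprob, ph["survival_steps"])
        t = res.table
        assert (t["lod"] >= t["lod_spike"] - 1e-6).all()
        assert (t["lod"] >= t["lod_quant"] - 1e-6).all()

    def test_survival_qtl_recovery(self):
        """A spike trait with a hazard-shifting QTL of ~10% PVE is
        localized within 15 cM (median over replicates)."""
        errors = []
        for rep in range(30):
            cfg = simulate.CrossConfig(
                n_f2=192, chromosomes=(("A1", 100.0, 100.0),), n_markers=25,
                error_rate=0.0, missing_rate=0.0, seed=500 + rep,
            )
            fd = simulate.simulate_founders(cfg)
            geno, truth = simulate.simulate_f2_genotypes(fd, cfg)
            model = simulate.PhenotypeModel(
                name="sv", architecture=[("A1", 45.0, 0.6, 0.0)],
                polygenic_var=0.05, h2=0.35, base_step_hazard=0.01,
                hazard_beta=1.0,
            )
            ph = simulate.simulate_phenotypes(truth, model, seed=rep,
                                              mode="mechanistic")
            gp = scan.calc_genoprob(
                geno, fd.markers[["marker", "chrom", "cM"]], step=2.0,
                epsilon=0.0,
            )
            res = scan.scan_twopart(gp, ph["survival_steps"])
            best = res.table.loc[res.table["lod"].idxmax()]
            errors.append(abs(best["pos"] - 45.0))
        assert np.median(errors) <= 15.0


class TestThresholdsIntervalsPVE:
    def test_threshold_deterministic_and_rank_invariant(self, genoprob):
        rng = np.random.default_rng(5)
        y = pd.Series(rng.normal(size=192), index=genoprob.individuals)
        t1, _ = scan.scan_permutation_threshold(genoprob, y, n_perm=100, seed=42)
        t2, _ = scan.scan_permutation_threshold(genoprob, y, n_perm=100, seed=42)
        assert t1 == t2
        t3, _ = scan.scan_permutation_threshold(genoprob, np.exp(y), n_perm=100,
                                                seed=42)
        assert t3 == pytest.approx(t1, abs=1e-12)

    def test_null_calibration(self, clean_cross):
        """Observed genome-wide max exceeds its own permutation threshold
        about 5% of the time under the null."""
        _cfg, fd, geno, _truth = clean_cross
        gp = scan.calc_genoprob(
            geno, fd.markers[["marker", "chrom", "cM"]], step=0.0, epsilon=0.0
        )
        rng = np.random.default_rng(7)
        hits = 0
        outer = 100
        for rep in range(outer):
            y = pd.Series(rng.normal(size=192), index=gp.individuals)
            thr, _ = scan.scan_permutation_threshold(gp, y, n_perm=100,
                                                     seed=rep)
            obs = scan.scan_nonparametric(gp, y).max_lod()
            hits += obs > thr
        assert 0.02 <= hits / outer <= 0.10

    def test_lod_interval_quadratic_profile(self):
        pos = np.linspace(0, 100, 101)
        lod = 8.0 - 1.5 * ((pos - 50) / 10) ** 2
        table = pd.DataFrame(
            {"chrom": "A1", "pos": pos, "is_marker": (pos % 10 == 0),
             "lod": np.maximum(lod, 0)}
        )
        res = scan.ScanResult("t", "nonparametric", table, 192)
        lo, hi = scan.lod_interval(res, "A1", drop=1.5)
        assert lo == 40.0 and hi == 60.0

    def test_lod_interval_clipped_at_chromosome_end(self):
        pos = np.linspace(0, 50, 51)
        table = pd.DataFrame(
            {"chrom": "A1", "pos": pos, "is_marker": True, "lod": pos / 10}
        )
        res = scan.ScanResult("t", "nonparametric", table, 192)
        lo, hi = scan.lod_interval(res, "A1", drop=1.5)
        assert hi == 50.0 and lo < 50.0

    def test_lod_interval_contains_peak_and_widens(self):
        rng = np.random.default_rng(11)
        pos = np.arange(0.0, 80.0)
        lod = np.abs(np.cumsum(rng.normal(size=80))) + 0.1
        table = pd.DataFrame({"chrom": "A1", "pos": pos, "is_marker": True,
                              "lod": lod})
        res = scan.ScanResult("t", "nonparametric", table, 192)
        peak = float(pos[lod.argmax()])
        prev_width = -1.0
        for drop in (0.5, 1.5, 3.0):
            lo, hi = scan.lod_interval(res, "A1", drop=drop)
            assert lo <= peak <= hi
            assert hi - lo >= prev_width
            prev_width = hi - lo

    def test_variance_explained_formula(self):
        assert scan.variance_explained(0.0, 188) == 0.0
        assert scan.variance_explained(6.63, 188) == pytest.approx(0.150,
                                                                   abs=5e-4)
        lods = np.linspace(0, 30, 50)
        pve = scan.variance_explained(lods, 188)
        assert np.all(np.diff(pve) > 0) and pve.max() < 1.0

    def test_find_peaks_reports_interval_and_pve(self, genoprob, clean_cross):
        _cfg, fd, geno, _truth = clean_cross
        mk = fd.markers.iloc[10]
        y = pd.Series(geno[mk["marker"]].to_numpy().astype(float),
                      index=geno.index)
        res = scan.scan_nonparametric(genoprob, y)
        peaks = scan.find_peaks(res, threshold=3.0)
        assert len(peaks) >= 1
        top = max(peaks, key=lambda p: p["lod"])
        assert top["chrom"] == mk["chrom"]
        assert top["interval"][0] <= top["pos"] <= top["interval"][1]
        assert 0 < top["pve"] < 1
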