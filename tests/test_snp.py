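"""SNP filtering, dosage coding, imputation, PCA, clustering, LD and Ne."""

import numpy as np
import pandas as pd
import pytest

import ricegain as rg
from ricegain.snp import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    FilterError,
    GenotypeMatrix,
    MarkerMap,
)


def _gm(calls, lines=None, markers=None):
    calls = np.asarray(calls, dtype=np.int8)
    lines = lines or [f"L{i}" for i in range(calls.shape[0])]
    markers = markers or [f"M{j}" for j in range(calls.shape[1])]
    return GenotypeMatrix(lines, markers, calls)


def _map(markers, chrom=1, spacing=100_000):
    return MarkerMap(
        pd.DataFrame(
            {
                "marker": markers,
                "chrom": chrom,
                "pos": np.arange(1, len(markers) + 1) * spacing,
            }
        )
    )


class TestFilterGenotypes:
    def test_crafted_matrix_filters_expected_rows_and_columns(self):
        # 6 lines x 8 markers; line 0 has 25% heterozygous calls, marker 0
        # has 25% missing among surviving lines, marker 1 has MAF ~0.03
        calls = np.zeros((6, 8), dtype=np.int8)
        calls[:, 2:] = np.tile([0, 2, 0, 2, 0, 2], (6, 1)).T[:, : 6].T  # mixed
        calls[:, 2:] = 0
        calls[::2, 2:] = 2  # markers 2..7: alt in half the lines -> MAF 0.5
        calls[0, [2, 3]] = HET  # line 0: 2/8 het = 25%
        calls[1:3, 0] = MISSING  # marker 0 (after line 0 removed): 2/5 missing
        calls[:, 1] = 0  # marker 1 all hom-ref except ...
        calls[1, 1] = HET  # one het among 5 survivors -> MAF 0.1/... small
        g = _gm(calls)
        out = rg.filter_genotypes(g, het_max=0.15, miss_max=0.25, maf_min=0.15)
        assert out.lines == [f"L{i}" for i in range(1, 6)]
        assert "M0" not in out.markers  # 2/5 = 40% missing
        assert "M1" not in out.markers  # MAF 0.1 < 0.15
        assert out.calls.shape == (5, 6)

    def test_loose_thresholds_are_identity(self):
        rng = np.random.default_rng(0)
        g = _gm(rng.integers(0, 3, (10, 12)))
        out = rg.filter_genotypes(g, het_max=1.0, miss_max=1.0, maf_min=0.0)
        assert out.lines == g.lines and out.markers == g.markers
        assert np.array_equal(out.calls, g.calls)

    def test_clean_common_matrix_unchanged_under_defaults(self):
        calls = np.zeros((8, 5), dtype=np.int8)
        calls[:4] = 2  # every marker at 50% frequency, no het, no missing
        out = rg.filter_genotypes(_gm(calls))
        assert out.calls.shape == (8, 5)

    def test_everything_removed_is_an_error(self):
        calls = np.full((4, 3), HET, dtype=np.int8)
        with pytest.raises(FilterError):
            rg.filter_genotypes(_gm(calls), het_max=0.1)

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 1, 2, -1], size=(20, 30),
                           p=[0.45, 0.1, 0.35, 0.1]).astype(np.int8)
        g = _gm(calls)
        tight = rg.filter_genotypes(g, het_max=0.2, miss_max=0.2, maf_min=0.2)
        loose = rg.filter_genotypes(g, het_max=0.4, miss_max=0.4, maf_min=0.05)
        assert set(tight.lines) <= set(loose.lines)
        assert set(tight.markers) <= set(loose.markers)


class TestDosage:
    def test_coding_rules(self):
        g = _gm([[HOM_REF, HET, HOM_ALT, MISSING]])
        d = rg.to_dosage(g)
        assert d.values[0, 0] == 0.0
        assert d.values[0, 1] == 0.5
        assert d.values[0, 2] == 1.0
        assert np.isnan(d.values[0, 3])

    def test_minor_count_orientation_flips_major_columns(self):
        calls = np.array([[2], [2], [2], [0]], dtype=np.int8)  # alt freq 0.75
        d = rg.to_dosage(_gm(calls), orientation="minor_count")
        assert d.values[:, 0].tolist() == [0.0, 0.0, 0.0, 1.0]

    def test_r2_invariant_to_orientation_flip(self):
        rng = np.random.default_rng(2)
        vals = rng.choice([0.0, 1.0], size=(50, 4))
        markers = [f"M{j}" for j in range(4)]
        d1 = rg.DosageMatrix([f"L{i}" for i in range(50)], markers, vals)
        flipped = vals.copy()
        flipped[:, 1] = 1.0 - flipped[:, 1]
        d2 = rg.DosageMatrix(d1.lines, markers, flipped)
        mm = _map(markers)
        p1 = rg.ld_pairs(d1, mm).set_index(["marker1", "marker2"])["r2"]
        p2 = rg.ld_pairs(d2, mm).set_index(["marker1", "marker2"])["r2"]
        assert np.allclose(p1, p2)


class TestImputation:
    def test_complete_matrix_returned_identical(self):
        rng = np.random.default_rng(3)
        vals = rng.choice([0.0, 0.5, 1.0], size=(10, 8))
        d = rg.DosageMatrix([f"L{i}" for i in range(10)],
                            [f"M{j}" for j in range(8)], vals)
        out = rg.impute_ld_knn(d)
        assert np.array_equal(out.values, vals)

    def test_block_of_identical_lines_forces_imputed_value(self):
        vals = np.tile([1.0, 0.0, 1.0, 0.0, 1.0, 0.0], (8, 1))
        vals = np.ascontiguousarray(vals)
        vals[0, 2] = np.nan
        d = rg.DosageMatrix([f"L{i}" for i in range(8)],
                            [f"M{j}" for j in range(6)], vals)
        out = rg.impute_ld_knn(d, k_lines=3)
        assert out.values[0, 2] == pytest.approx(1.0)

    def test_beats_marker_mean_on_ld_structured_data(self, rng):
        ped, _ = rg.simulate_breeding_program(
            rg.SimConfig(seed=5, years=8, burnin_years=6, crosses_per_year=10)
        )
        gm, mm = rg.gene_drop(ped, rg.MapConfig(n_chrom=4, markers_per_chrom=40),
                              seed=5)
        d = rg.to_dosage(gm)
        truth = d.values.copy()
        r = np.random.default_rng(6)
        mask = r.random(truth.shape) < 0.10
        vals = truth.copy()
        vals[mask] = np.nan
        masked = rg.DosageMatrix(d.lines, d.markers, vals)
        out = rg.impute_ld_knn(masked, mm)
        err_knn = np.abs(out.values[mask] - truth[mask]).mean()
        col_mean = np.nanmean(vals, axis=0)
        err_mean = np.abs(
            np.broadcast_to(col_mean, truth.shape)[mask] - truth[mask]
        ).mean()
        assert not np.isnan(out.values).any()
        assert err_knn < err_mean

    def test_entirely_missing_marker_filled_with_half(self):
        vals = np.array([[0.0, np.nan], [1.0, np.nan]])
        d = rg.DosageMatrix(["A", "B"], ["M0", "M1"], vals)
        out = rg.impute_ld_knn(d)
        assert np.allclose(out.values[:, 1], 0.5)


class TestPca:
    def test_two_fixed_difference_populations_separate_on_pc1(self):
        rng = np.random.default_rng(7)
        a = rng.choice([0.0, 1.0], (20, 50), p=[0.9, 0.1])
        b = rng.choice([0.0, 1.0], (20, 50), p=[0.1, 0.9])
        vals = np.vstack([a, b])
        d = rg.DosageMatrix([f"L{i}" for i in range(40)],
                            [f"M{j}" for j in range(50)], vals)
        coords = rg.pca_project(d)
        pc1 = coords["PC1"].to_numpy()
        assert (np.sign(pc1[:20]) == np.sign(pc1[0])).all()
        assert (np.sign(pc1[20:]) == -np.sign(pc1[0])).all()

    def test_duplicate_line_identical_coordinates(self):
        rng = np.random.default_rng(8)
        vals = rng.choice([0.0, 0.5, 1.0], (10, 30))
        vals[1] = vals[0]
        d = rg.DosageMatrix([f"L{i}" for i in range(10)],
                            [f"M{j}" for j in range(30)], vals)
        coords = rg.pca_project(d)
        assert np.allclose(coords.iloc[0, :-1].astype(float),
                           coords.iloc[1, :-1].astype(float))

    def test_single_population_has_no_dominant_pc(self):
        rng = np.random.default_rng(9)
        vals = rng.choice([0.0, 1.0], (100, 200))
        d = rg.DosageMatrix([f"L{i}" for i in range(100)],
                            [f"M{j}" for j in range(200)], vals)
        coords = rg.pca_project(d, n_components=20)
        ev = np.array(coords.attrs["explained"])
        assert ev[0] < 3 * ev.mean()

    def test_reference_projection_uses_shared_markers(self):
        rng = np.random.default_rng(10)
        vals = rng.choice([0.0, 1.0], (10, 30))
        d = rg.DosageMatrix([f"P{i}" for i in range(10)],
                            [f"M{j}" for j in range(30)], vals)
        ref = rg.DosageMatrix([f"R{i}" for i in range(15)],
                              [f"M{j}" for j in range(10, 40)],
                              rg_vals(rng, 15, 30))
        coords = rg.pca_project(d, reference=ref)
        assert (coords["source"] == "panel").sum() == 10
        assert (coords["source"] == "reference").sum() == 15

    def test_order_permutation_invariance_up_to_sign(self):
        rng = np.random.default_rng(11)
        vals = rng.choice([0.0, 0.5, 1.0], (30, 40))
        lines = [f"L{i}" for i in range(30)]
        d1 = rg.DosageMatrix(lines, [f"M{j}" for j in range(40)], vals)
        perm = rng.permutation(30)
        d2 = rg.DosageMatrix([lines[i] for i in perm],
                             [f"M{j}" for j in range(40)], vals[perm])
        c1 = rg.pca_project(d1)["PC1"]
        c2 = rg.pca_project(d2)["PC1"].reindex(c1.index)
        assert np.allclose(np.abs(c1), np.abs(c2), atol=1e-8)


def rg_vals(rng, n, m):
    return rng.choice([0.0, 1.0], (n, m))


class TestClustering:
    def test_identical_lines_merge_first_at_zero_distance(self):
        rng = np.random.default_rng(12)
        vals = rng.choice([0.0, 1.0], (6, 20))
        vals[1] = vals[0]
        d = rg.DosageMatrix([f"L{i}" for i in range(6)],
                            [f"M{j}" for j in range(20)], vals)
        res = rg.cluster_lines(d)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_two_families_recovered_at_k2(self):
        # two unrelated full-sib families via gene drop
        recs = [rg.PedigreeRecord(p) for p in ("A", "B", "C", "D")]
        for i in range(12):
            recs.append(rg.PedigreeRecord(f"FAM1_{i}", "A", "B"))
            recs.append(rg.PedigreeRecord(f"FAM2_{i}", "C", "D"))
        ped = rg.build_pedigree(recs)
        gm, _ = rg.gene_drop(ped, rg.MapConfig(n_chrom=6, markers_per_chrom=50),
                             seed=13)
        keep = [l for l in gm.lines if l.startswith("FAM")]
        idx = [gm.lines.index(l) for l in keep]
        d = rg.DosageMatrix(keep, gm.markers, gm.calls[idx] / 2.0)
        res = rg.cluster_lines(d, k=2)
        lab = res.labels
        fam1 = set(lab[[l for l in keep if l.startswith("FAM1")]])
        fam2 = set(lab[[l for l in keep if l.startswith("FAM2")]])
        assert len(fam1) == 1 and len(fam2) == 1 and fam1 != fam2

    def test_newick_roundtrip_contains_all_lines(self):
        rng = np.random.default_rng(14)
        vals = rng.choice([0.0, 1.0], (5, 10))
        d = rg.DosageMatrix([f"L{i}" for i in range(5)],
                            [f"M{j}" for j in range(10)], vals)
        nwk = rg.cluster_lines(d).newick()
        assert nwk.endswith(";")
        for l in d.lines:
            assert l in nwk


class TestLdPairs:
    def test_identical_columns_at_250kb(self):
        vals = np.tile(np.array([[0.0], [1.0], [0.0], [1.0]]), (1, 2))
        mm = MarkerMap(pd.DataFrame(
            {"marker": ["M0", "M1"], "chrom": [1, 1], "pos": [1, 250_001]}
        ))
        d = rg.DosageMatrix(["a", "b", "c", "d"], ["M0", "M1"], vals)
        pairs = rg.ld_pairs(d, mm)
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)
        assert pairs["c"].iloc[0] == pytest.approx(0.01)  # 250 kb = 1 cM = 0.01 M

    def test_literal_morgan_convention(self):
        vals = np.tile(np.array([[0.0], [1.0], [0.0], [1.0]]), (1, 2))
        mm = MarkerMap(pd.DataFrame(
            {"marker": ["M0", "M1"], "chrom": [1, 1], "pos": [1, 250_001]}
        ))
        d = rg.DosageMatrix(["a", "b", "c", "d"], ["M0", "M1"], vals)
        pairs = rg.ld_pairs(d, mm, literal_250kb_units=True)
        assert pairs["c"].iloc[0] == pytest.approx(1.0)

    def test_different_chromosomes_emit_no_pair(self):
        rng = np.random.default_rng(15)
        vals = rng.choice([0.0, 1.0], (10, 2))
        mm = MarkerMap(pd.DataFrame(
            {"marker": ["M0", "M1"], "chrom": [1, 2], "pos": [100, 100]}
        ))
        d = rg.DosageMatrix([f"L{i}" for i in range(10)], ["M0", "M1"], vals)
        assert rg.ld_pairs(d, mm).empty

    def test_independent_columns_mean_r2_near_one_over_n(self):
        rng = np.random.default_rng(16)
        n, m = 1000, 40
        vals = rng.choice([0.0, 1.0], (n, m))
        d = rg.DosageMatrix([f"L{i}" for i in range(n)],
                            [f"M{j}" for j in range(m)], vals)
        pairs = rg.ld_pairs(d, _map(d.markers))
        assert pairs["r2"].mean() == pytest.approx(1.0 / n, rel=0.35)

    def test_zero_variance_markers_skipped(self):
        vals = np.column_stack([np.zeros(8), np.tile([0.0, 1.0], 4)])
        d = rg.DosageMatrix([f"L{i}" for i in range(8)], ["M0", "M1"], vals)
        assert rg.ld_pairs(d, _map(["M0", "M1"])).empty


class TestEstimateNe:
    def test_single_bin_arithmetic(self):
        pairs = pd.DataFrame({"c": [0.01] * 40, "r2": [0.25] * 40})
        est = rg.estimate_ne(pairs, n_bins=1)
        assert est.ne == pytest.approx(75.0)

    def test_perfect_ld_gives_zero(self):
        pairs = pd.DataFrame({"c": [0.01] * 40, "r2": [1.0] * 40})
        assert rg.estimate_ne(pairs, n_bins=1).ne == pytest.approx(0.0)

    def test_negative_bins_floored_and_flagged(self):
        pairs = pd.DataFrame({"c": [0.5] * 40, "r2": [0.999] * 40})
        est = rg.estimate_ne(pairs, n_bins=1)
        assert est.ne >= 0.0

    def test_too_few_pairs_is_an_error(self):
        pairs = pd.DataFrame({"c": [0.01] * 5, "r2": [0.2] * 5})
        with pytest.raises(ValueError):
            rg.estimate_ne(pairs, min_pairs_per_bin=30)

    def test_sample_correction_raises_estimate(self):
        pairs = pd.DataFrame({"c": [0.05] * 100, "r2": [0.10] * 100})
        plain = rg.estimate_ne(pairs, n_bins=1).ne
        corr = rg.estimate_ne(pairs, n_bins=1, r2_sample_correction_n=50).ne
        assert corr > plain


class TestFavorableAlleleFrequency:
    def _calls(self, fav, unf, miss, gene="Pi-ta"):
        rows = []
        i = 0
        for call, k in (("favorable", fav), ("unfavorable", unf), ("missing", miss)):
            for _ in range(k):
                rows.append({"line_id": f"L{i}", "gene": gene, "call": call})
                i += 1
        return pd.DataFrame(rows)

    def test_simple_frequency_and_full_coverage(self):
        out = rg.favorable_allele_frequency(self._calls(7, 3, 0))
        r = out.iloc[0]
        assert r["frequency_pct"] == pytest.approx(70.0)
        assert r["coverage_pct"] == pytest.approx(100.0)
        assert not r["low_confidence"]

    def test_ninety_four_of_hundred_called_is_low_confidence(self):
        out = rg.favorable_allele_frequency(self._calls(50, 44, 6))
        assert out.iloc[0]["coverage_pct"] == pytest.approx(94.0)
        assert bool(out.iloc[0]["low_confidence"])

    def test_fixed_favorable_is_hundred_percent(self):
        out = rg.favorable_allele_frequency(self._calls(10, 0, 0))
        assert out.iloc[0]["frequency_pct"] == pytest.approx(100.0)

    def test_zero_calls_reported_missing(self):
        out = rg.favorable_allele_frequency(self._calls(0, 0, 5))
        assert np.isnan(out.iloc[0]["frequency_pct"])
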