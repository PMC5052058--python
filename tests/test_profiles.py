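"""Composite profiles: dedup rule, identities, orientation, stratification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import repairmap as rm


def _constant_track(layout, spacing, c):
    grid = rm.generate_probe_grid(layout, spacing)
    return grid.with_values(np.full(len(grid), float(c)))


class TestSelectGenes:
    def test_inclusive_length_bounds(self):
        genes = rm.GeneAnnotation(
            ["c"] * 4, [0, 1000, 3000, 6000], [499, 1500, 4500, 7501],
            ["+"] * 4, ["a", "b", "c", "d"],
        )
        kept = rm.select_genes(genes)
        assert set(kept.gene_id) == {"b", "c"}  # lengths 499,500,1500,1501

    def test_empty_result_warns(self, caplog):
        genes = rm.GeneAnnotation(["c"], [0], [100], ["+"], ["a"])
        with caplog.at_level("WARNING"):
            assert len(rm.select_genes(genes)) == 0

    def test_matches_brute_force_on_synthetic_annotation(self, small_genome):
        _, genes, _ = small_genome
        kept = rm.select_genes(genes)
        brute = sum(1 for L in (genes.end - genes.start) if 500 <= L <= 1500)
        assert len(kept) == brute


class TestGenomeFraction:
    def test_single_window_arithmetic(self):
        layout = rm.GenomeLayout((("c", 10_000),))
        genes = rm.GeneAnnotation(["c"], [4000], [5000], ["+"], ["g"])
        assert rm.genome_fraction_covered(genes, layout, 2000) == pytest.approx(0.5)

    def test_overlapping_windows_form_union_not_sum(self):
        layout = rm.GenomeLayout((("c", 10_000),))
        genes = rm.GeneAnnotation(["c"] * 2, [2000, 3000], [3000, 4000], ["+", "+"], ["a", "b"])
        # union of [0,5000) and [1000,6000) = [0,6000)
        assert rm.genome_fraction_covered(genes, layout, 2000) == pytest.approx(0.6)

    def test_zero_flank_counts_gene_bp_only(self):
        layout = rm.GenomeLayout((("c", 10_000),))
        genes = rm.GeneAnnotation(["c"] * 2, [0, 5000], [1000, 5500], ["+", "+"], ["a", "b"])
        assert rm.genome_fraction_covered(genes, layout, 0) == pytest.approx(0.15)


class TestAssignProbes:
    def test_nearest_anchor_wins(self):
        layout = rm.GenomeLayout((("c", 20_000),))
        grid = rm.generate_probe_grid(layout, 250)
        # gene A ends at 5000, gene B starts at 6000; probe mid 5425 is 425 bp
        # from A's end and 575 bp from B's start -> A
        genes = rm.GeneAnnotation(["c"] * 2, [3000, 6000], [5000, 8000], ["+", "+"], ["A", "B"])
        a = rm.assign_probes(genes, grid, rm.ProfileSchema())
        probe = np.flatnonzero(grid.midpoint == 5375.0)[0]
        assert a.feature_index[probe] == 0

    def test_exact_tie_goes_to_lower_index(self):
        layout = rm.GenomeLayout((("c", 20_000),))
        grid = rm.generate_probe_grid(layout, 250)
        genes = rm.GeneAnnotation(["c"] * 2, [3000, 6250], [5000, 8000], ["+", "+"], ["A", "B"])
        a = rm.assign_probes(genes, grid, rm.ProfileSchema())
        probe = np.flatnonzero(grid.midpoint == 5625.0)[0]  # 625 bp from both anchors
        assert a.feature_index[probe] == 0

    def test_each_probe_counted_at_most_once(self, small_spec, small_genome):
        _, genes, _ = small_genome
        layout = small_spec.layout()
        grid = rm.generate_probe_grid(layout, small_spec.probe_spacing)
        a = rm.assign_probes(genes, grid, rm.ProfileSchema())
        assert a.n_assigned <= len(grid)
        prof = rm.gene_profile(grid.with_values(np.ones(len(grid))), genes)
        assert prof.n_contributions.sum() <= len(grid)
        assert prof.n_contributions.sum() == a.n_assigned


class TestProfileIdentities:
    @pytest.mark.parametrize("mode", ["gene", "point"])
    def test_constant_track_gives_constant_profile(self, mode, small_spec, small_genome):
        _, genes, sites = small_genome
        track = _constant_track(small_spec.layout(), small_spec.probe_spacing, 2.5)
        if mode == "gene":
            prof = rm.gene_profile(track, rm.select_genes(genes))
        else:
            prof = rm.point_profile(track, sites)
        nz = prof.nonempty
        assert nz.any()
        assert np.allclose(prof.mean[nz], 2.5)
        assert np.allclose(prof.dispersion[nz], 0.0)

    def test_minus_strand_signal_flipped_to_left(self):
        layout = rm.GenomeLayout((("c", 20_000),))
        grid = rm.generate_probe_grid(layout, 250)
        genes = rm.GeneAnnotation(["c"], [8000], [10_000], ["-"], ["g"])
        # signal only near the TSS of the minus-strand gene (its right end)
        v = np.where(grid.midpoint >= 9_500, 1.0, 0.0)
        prof = rm.gene_profile(grid.with_values(v), genes)
        nz = prof.nonempty
        body = prof.segment == "body"
        first_quarter = body & (prof.coord <= 0.25)
        last_quarter = body & (prof.coord >= 0.75)
        assert np.nansum(prof.mean[first_quarter & nz]) > 0
        assert np.nansum(prof.mean[last_quarter & nz]) == 0

    def test_flipping_all_strands_reverses_gene_profile(self, small_spec, small_genome):
        _, genes, _ = small_genome
        rng = np.random.default_rng(5)
        grid = rm.generate_probe_grid(small_spec.layout(), small_spec.probe_spacing)
        track = grid.with_values(rng.normal(size=len(grid)))
        flipped = rm.GeneAnnotation(
            genes.chrom, genes.start, genes.end,
            np.where(genes.strand == "+", "-", "+").astype(object),
            genes.gene_id, genes.expression,
        )
        p1 = rm.gene_profile(track, genes)
        p2 = rm.gene_profile(track, flipped)
        assert np.allclose(p1.mean, p2.mean[::-1], equal_nan=True)

    def test_point_profile_symmetric_for_planted_peaks(self, small_spec, small_genome):
        _, genes, sites = small_genome
        sset = rm.simulate_binding_signal(small_spec, sites, genes, "pre")
        prof = rm.point_profile(sset, sites)
        nz = prof.nonempty
        mean = prof.mean
        n = len(prof)
        asym = np.abs(mean[: n // 2][::-1] - mean[n // 2:])
        comb = np.sqrt(
            prof.dispersion[: n // 2][::-1] ** 2 + prof.dispersion[n // 2:] ** 2
        )
        ok = nz[: n // 2][::-1] & nz[n // 2:]
        assert np.nanmean(asym[ok] <= 4 * comb[ok]) > 0.9


class TestStratifyByExpression:
    def test_exact_quantile_split(self):
        rng = np.random.default_rng(1)
        expr = rng.permutation(100).astype(float)
        genes = rm.GeneAnnotation(
            ["c"] * 100, np.arange(100) * 2000, np.arange(100) * 2000 + 1000,
            ["+"] * 100, [f"g{i}" for i in range(100)], expr,
        )
        low, rest = rm.stratify_by_expression(genes)
        assert (len(low), len(rest)) == (15, 85)
        assert low.expression.max() < rest.expression.min()

    def test_ties_at_cut_go_low(self):
        expr = np.array([0.0] * 30 + list(range(1, 71)), dtype=float)
        genes = rm.GeneAnnotation(
            ["c"] * 100, np.arange(100) * 2000, np.arange(100) * 2000 + 1000,
            ["+"] * 100, [f"g{i}" for i in range(100)], expr,
        )
        low, _ = rm.stratify_by_expression(genes)
        assert len(low) == 30  # all tied zeros included

    def test_all_missing_is_error(self):
        genes = rm.GeneAnnotation(["c"], [0], [1000], ["+"], ["g"])
        with pytest.raises(ValueError):
            rm.stratify_by_expression(genes)

    def test_low_stratum_has_flat_body_repair(self, small_spec, small_genome):
        layout, genes, sites = small_genome
        model = rm.RepairModel()
        t0 = rm.simulate_damage_signal(small_spec, genes, sites, model, 0)
        t120 = rm.simulate_damage_signal(small_spec, genes, sites, model, 120)
        rate = rm.repair_rate(
            rm.normalize_set(t0, "quantile_only"), rm.normalize_set(t120, "quantile_only")
        )
        low, rest = rm.stratify_by_expression(genes)
        p_low = rm.gene_profile(rate.track, low)
        p_rest = rm.gene_profile(rate.track, rest)
        body = p_low.segment == "body"
        up_far = (p_low.segment == "upstream") & (p_low.coord < -1500)
        lift = lambda p: np.nanmean(p.mean[body & p.nonempty]) - np.nanmean(
            p.mean[up_far & p.nonempty]
        )
        assert lift(p_rest) > lift(p_low) + 0.05


class TestRandomFeatures:
    def test_reproducible_and_non_overlapping(self):
        layout = rm.GenomeLayout((("c", 200_000),))
        a = rm.random_features(layout, 50, (500, 1500), seed=9)
        b = rm.random_features(layout, 50, (500, 1500), seed=9)
        assert np.array_equal(a.start, b.start) and np.array_equal(a.strand, b.strand)
        order = np.argsort(a.start)
        assert np.all(a.start[order][1:] >= a.end[order][:-1])

    def test_zero_features_is_error(self):
        layout = rm.GenomeLayout((("c", 200_000),))
        with pytest.raises(ValueError):
            rm.random_features(layout, 0, (500, 1500))

    def test_impossible_placement_errors_after_budget(self):
        layout = rm.GenomeLayout((("c", 3000),))
        with pytest.raises(RuntimeError, match="attempts"):
            rm.random_features(layout, 10, (1000, 1500), max_attempts_per_feature=20)

    def test_flat_null_control(self, small_spec):
        layout = small_spec.layout()
        grid = rm.generate_probe_grid(layout, small_spec.probe_spacing)
        passes = 0
        n_runs = 10
        for s in range(n_runs):
            rng = np.random.default_rng(100 + s)
            track = grid.with_values(rng.normal(0.3, 0.2, size=len(grid)))
            feats = rm.random_features(layout, 120, (500, 1500), seed=200 + s)
            prof = rm.gene_profile(track, feats)
            _, _, ok = rm.flatness_check(prof, alpha=0.01)
            passes += ok
        assert passes / n_runs >= 0.8


class TestLocalizeSites:
    def test_upstream_site_coordinates(self):
        genes = rm.GeneAnnotation(["c"], [1000], [2000], ["+"], ["g"])
        sites = rm.SiteSet(["c"], [900.0], [1.0], [900], [901])
        loc = rm.localize_sites(sites, genes)
        assert loc.region_class[0] == "upstream"
        assert loc.rel_coord[0] == pytest.approx(-100.0)

    def test_body_midpoint_is_half(self):
        genes = rm.GeneAnnotation(["c"], [1000], [2000], ["+"], ["g"])
        sites = rm.SiteSet(["c"], [1500.0], [1.0], [1500], [1501])
        loc = rm.localize_sites(sites, genes)
        assert loc.region_class[0] == "body"
        assert loc.rel_coord[0] == pytest.approx(0.5)

    def test_minus_strand_upstream_is_right_of_gene(self):
        genes = rm.GeneAnnotation(["c"], [1000], [2000], ["-"], ["g"])
        sites = rm.SiteSet(["c"], [2100.0], [1.0], [2100], [2101])
        loc = rm.localize_sites(sites, genes)
        assert loc.region_class[0] == "upstream"
        assert loc.rel_coord[0] == pytest.approx(-100.0)

    def test_classes_match_brute_force_oracle(self, small_genome):
        """Each site's class equals an independent per-site enumeration of the
        nearest-anchor/lower-index rule; intergenic sites dominate."""
        _, genes, sites = small_genome
        schema = rm.ProfileSchema()
        loc = rm.localize_sites(sites, genes)
        for i in range(len(sites)):
            best = (np.inf, -1)
            m = sites.midpoint[i]
            for gi in range(len(genes)):
                if genes.chrom[gi] != sites.chrom[i]:
                    continue
                s, e = genes.start[gi], genes.end[gi]
                if not (s - schema.flank_bp <= m < e + schema.flank_bp):
                    continue
                d = min(abs(m - s), abs(m - e))
                if d < best[0]:
                    best = (d, gi)
            assert loc.gene_index[i] == best[1]
            if best[1] >= 0:
                s, e = genes.start[best[1]], genes.end[best[1]]
                mm = s + e - m if genes.strand[best[1]] == "-" else m
                expected = "upstream" if mm < s else ("body" if mm < e else "downstream")
                assert loc.region_class[i] == expected
        # sites are planted intergenic, so few classify into ORF bodies
        attached = loc.gene_index >= 0
        assert np.mean(loc.region_class[attached] == "body") < 0.1


class TestSchemaValidation:
    @pytest.mark.parametrize("kwargs", [
        {"flank_bp": 2000, "flank_bin_bp": 300},
        {"body_bins": 0},
        {"halfwidth_bp": 2025},
    ])
    def test_invalid_schema_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rm.ProfileSchema(**kwargs)
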