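"""Difference profiles, domain calling and profile correlation."""

import numpy as np
import pytest

import repairmap as rm
from repairmap.domains import NO_DOMAIN


def _profile(values, n=None):
    values = np.asarray(values, dtype=float)
    B = len(values)
    n = np.full(B, 10) if n is None else np.asarray(n)
    coord = -B / 2 * 50 + (np.arange(B) + 0.5) * 50
    seg = np.repeat("point", B).astype(object)
    disp = np.full(B, 0.1)
    mean = np.where(n > 0, values, np.nan)
    return rm.CompositeProfile(coord, seg, mean, np.where(n > 0, disp, np.nan), n)


class TestProfileDifference:
    def test_self_difference_is_zero(self):
        p = _profile(np.sin(np.linspace(0, 3, 20)))
        d = rm.profile_difference(p, p)
        assert np.allclose(d.mean[d.nonempty], 0.0)

    def test_antisymmetric_under_swap(self):
        p1 = _profile(np.linspace(0, 1, 20))
        p2 = _profile(np.linspace(1, 0, 20))
        d12 = rm.profile_difference(p1, p2)
        d21 = rm.profile_difference(p2, p1)
        assert np.allclose(d12.mean[d12.nonempty], -d21.mean[d21.nonempty])

    def test_empty_bins_propagate(self):
        n = np.full(20, 10)
        n[3] = 0
        d = rm.profile_difference(_profile(np.ones(20), n), _profile(np.zeros(20)))
        assert not d.nonempty[3]
        assert d.nonempty.sum() == 19

    def test_schema_mismatch_is_error(self):
        with pytest.raises(ValueError, match="schema"):
            rm.profile_difference(_profile(np.ones(20)), _profile(np.ones(30)))

    def test_wt_minus_rad16_isolates_gg_term(self, noise_free_spec, noise_free_genome):
        layout, genes, sites = noise_free_genome
        rates = {}
        for scn in ("wildtype", "rad16_null"):
            model = rm.RepairModel(scenario=scn)
            t0 = rm.simulate_damage_signal(noise_free_spec, genes, sites, model, 0)
            t120 = rm.simulate_damage_signal(noise_free_spec, genes, sites, model, 120)
            rates[scn] = rm.repair_rate(
                rm.normalize_set(t0, "quantile_only"),
                rm.normalize_set(t120, "quantile_only"),
            )
        p_wt = rm.point_profile(rates["wildtype"].track, sites)
        p_mut = rm.point_profile(rates["rad16_null"].track, sites)
        diff = rm.profile_difference(p_wt, p_mut)
        # brute-force composite of the planted gg term over the same assignment
        grid = rm.generate_probe_grid(layout, noise_free_spec.probe_spacing)
        model = rm.RepairModel()
        a = rm.assign_probes(sites, grid, rm.ProfileSchema())
        sel = a.feature_index >= 0
        d = np.abs(grid.midpoint[sel] - sites.midpoint[a.feature_index[sel]])
        gg = model.gg_boost_amplitude * np.exp(-d / model.gg_decay_scale)
        signed = grid.midpoint[sel] - sites.midpoint[a.feature_index[sel]]
        bins = np.clip(((signed + 2000) // 50).astype(int), 0, len(diff) - 1)
        expected = np.full(len(diff), np.nan)
        for b in np.unique(bins):
            expected[b] = gg[bins == b].mean()
        nz = diff.nonempty & np.isfinite(expected)
        assert np.allclose(diff.mean[nz], expected[nz], atol=1e-9)


class TestUvInducedChange:
    def test_no_induction_gives_zero_change(self, noise_free_spec, noise_free_genome):
        _, _, sites = noise_free_genome
        pre = rm.simulate_acetylation_signal(noise_free_spec, sites, "pre",
                                             induction_amplitude=0.0, induction_offset_bp=300.0)
        post = rm.simulate_acetylation_signal(noise_free_spec, sites, "post",
                                              induction_amplitude=0.0, induction_offset_bp=300.0)
        change = rm.uv_induced_change(
            rm.point_profile(post, sites), rm.point_profile(pre, sites)
        )
        assert np.allclose(change.mean[change.nonempty], 0.0, atol=1e-12)

    def test_nested_difference_identity(self):
        rng = np.random.default_rng(3)
        prof = lambda: _profile(rng.normal(size=24))
        wt_post, wt_pre, mu_post, mu_pre = prof(), prof(), prof(), prof()
        a = rm.profile_difference(
            rm.uv_induced_change(wt_post, wt_pre), rm.uv_induced_change(mu_post, mu_pre)
        )
        b = rm.profile_difference(
            rm.profile_difference(wt_post, mu_post), rm.profile_difference(wt_pre, mu_pre)
        )
        assert np.allclose(a.mean, b.mean, equal_nan=True)

    def test_nested_difference_isolates_wt_only_induction(self, noise_free_spec, noise_free_genome):
        _, _, sites = noise_free_genome
        amp = 0.7
        mk = lambda state, a: rm.point_profile(
            rm.simulate_acetylation_signal(
                noise_free_spec, sites, state,
                induction_amplitude=a, induction_offset_bp=300.0,
            ),
            sites,
        )
        gg_component = rm.profile_difference(
            rm.uv_induced_change(mk("post", amp), mk("pre", amp)),
            rm.uv_induced_change(mk("post", 0.0), mk("pre", 0.0)),
        )
        nz = gg_component.nonempty
        peak = np.nanmax(gg_component.mean[nz])
        assert peak == pytest.approx(amp, rel=0.1)


class TestCallDomain:
    def test_triangular_profile_half_height(self):
        vals = np.concatenate([np.linspace(0, 2, 11), np.linspace(2, 0, 11)[1:]])
        call = rm.call_domain(_profile(vals), 0.5)
        assert call.found
        assert call.peak_value == pytest.approx(2.0)
        in_dom = vals[call.start_bin: call.end_bin + 1]
        assert np.all(in_dom >= 1.0)
        assert vals[call.start_bin - 1] < 1.0 and vals[call.end_bin + 1] < 1.0

    def test_flat_zero_profile_no_domain(self):
        call = rm.call_domain(_profile(np.zeros(20)))
        assert call is NO_DOMAIN or not call.found

    def test_scale_invariant_bin_range(self):
        rng = np.random.default_rng(4)
        vals = np.abs(rng.normal(size=30)) + 0.1
        c1 = rm.call_domain(_profile(vals))
        c2 = rm.call_domain(_profile(7.5 * vals))
        assert (c1.start_bin, c1.end_bin, c1.peak_bin) == (c2.start_bin, c2.end_bin, c2.peak_bin)

    def test_domain_width_grows_with_gg_decay_scale(self, noise_free_spec, noise_free_genome):
        _, genes, sites = noise_free_genome
        widths = []
        for scale in (400.0, 1000.0, 1800.0):
            rates = {}
            for scn in ("wildtype", "rad16_null"):
                model = rm.RepairModel(scenario=scn, gg_decay_scale=scale)
                t0 = rm.simulate_damage_signal(noise_free_spec, genes, sites, model, 0)
                t120 = rm.simulate_damage_signal(noise_free_spec, genes, sites, model, 120)
                rates[scn] = rm.repair_rate(
                    rm.normalize_set(t0, "quantile_only"),
                    rm.normalize_set(t120, "quantile_only"),
                )
            diff = rm.profile_difference(
                rm.point_profile(rates["wildtype"].track, sites),
                rm.point_profile(rates["rad16_null"].track, sites),
            )
            widths.append(rm.call_domain(diff).n_bins)
        assert widths[0] < widths[1] < widths[2]


class TestProfileCorrelation:
    def test_perfect_and_anti_correlation(self):
        vals = np.sin(np.linspace(0, 4, 30))
        p = _profile(vals)
        q = _profile(-vals)
        assert rm.profile_correlation(p, p)[0] == pytest.approx(1.0)
        assert rm.profile_correlation(p, q)[0] == pytest.approx(-1.0)

    def test_too_few_shared_bins_is_error(self):
        n = np.zeros(20, dtype=int)
        n[:2] = 5
        with pytest.raises(ValueError, match="shared"):
            rm.profile_correlation(_profile(np.ones(20), n), _profile(np.ones(20), n))

    def test_repair_and_acetylation_deficits_correlate(self, small_spec, small_genome):
        """Deficit profiles generated from one site set share their spatial form."""
        _, genes, sites = small_genome
        rates = {}
        for scn in ("wildtype", "rad16_null"):
            model = rm.RepairModel(scenario=scn)
            t0 = rm.simulate_damage_signal(small_spec, genes, sites, model, 0)
            t120 = rm.simulate_damage_signal(small_spec, genes, sites, model, 120)
            rates[scn] = rm.repair_rate(
                rm.normalize_set(t0, "quantile_only"),
                rm.normalize_set(t120, "quantile_only"),
            )
        repair_deficit = rm.profile_difference(
            rm.point_profile(rates["wildtype"].track, sites),
            rm.point_profile(rates["rad16_null"].track, sites),
        )
        ac_wt = rm.simulate_acetylation_signal(small_spec, sites, "post",
                                               induction_amplitude=0.6, induction_offset_bp=300.0)
        ac_mut = rm.simulate_acetylation_signal(small_spec, sites, "post",
                                                induction_amplitude=0.0, induction_offset_bp=300.0,
                                                seed=small_spec.seed + 1)
        ac_deficit = rm.profile_difference(
            rm.point_profile(ac_wt, sites), rm.point_profile(ac_mut, sites)
        )
        r, n = rm.profile_correlation(repair_deficit, ac_deficit)
        assert n >= 70
        # the two deficits share the promoter-proximal domain but have
        # different spatial kernels (exponential vs lobed-with-dip), so the
        # alignment shows as a substantial positive correlation and
        # co-located peaks, not near-unity r
        assert r > 0.4
        peak_r = repair_deficit.coord[np.nanargmax(np.where(repair_deficit.nonempty, repair_deficit.mean, -np.inf))]
        peak_a = ac_deficit.coord[np.nanargmax(np.where(ac_deficit.nonempty, ac_deficit.mean, -np.inf))]
        assert abs(peak_r) <= 500 and abs(peak_a) <= 500

    def test_matched_kernel_deficits_correlate_near_unity(self, small_spec, small_genome):
        """Deficits built from the same spatial kernel correlate almost perfectly."""
        _, _, sites = small_genome
        a1 = rm.simulate_acetylation_signal(small_spec, sites, "post",
                                            induction_amplitude=0.6, induction_offset_bp=300.0)
        a2 = rm.simulate_acetylation_signal(small_spec, sites, "post",
                                            induction_amplitude=0.3, induction_offset_bp=300.0,
                                            seed=small_spec.seed + 5)
        base = rm.simulate_acetylation_signal(small_spec, sites, "post",
                                              induction_amplitude=0.0, induction_offset_bp=300.0,
                                              seed=small_spec.seed + 9)
        pb = rm.point_profile(base, sites)
        d1 = rm.profile_difference(rm.point_profile(a1, sites), pb)
        d2 = rm.profile_difference(rm.point_profile(a2, sites), pb)
        r, _ = rm.profile_correlation(d1, d2)
        assert r > 0.8
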