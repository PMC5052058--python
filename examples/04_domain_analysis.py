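"""Quantify the GG-NER-dependent repair domain around binding sites.

Computes the wild-type minus rad16-null difference of repair-rate composite
profiles around Abf1 sites, calls the contiguous half-height domain around
the difference peak, and correlates the repair deficit with the acetylation
deficit generated from the same site set.
"""

import numpy as np

import repairmap as rm

spec = rm.SyntheticSpec(seed=23, chrom_lengths=[("chrI", 700_000), ("chrII", 500_000)])
layout, genes, sites = rm.generate_genome(spec)


def rate(scenario):
    model = rm.RepairModel(scenario=scenario)
    t0 = rm.simulate_damage_signal(spec, genes, sites, model, 0)
    t120 = rm.simulate_damage_signal(spec, genes, sites, model, 120)
    return rm.repair_rate(
        rm.normalize_set(t0, "quantile_only"), rm.normalize_set(t120, "quantile_only")
    )


diff = rm.profile_difference(
    rm.point_profile(rate("wildtype").track, sites),
    rm.point_profile(rate("rad16_null").track, sites),
)
dom = rm.call_domain(diff, threshold_fraction=0.5)
lo, hi = diff.coord[dom.start_bin], diff.coord[dom.end_bin]
print(f"difference peak : {dom.peak_value:.3f} log2 units at {diff.coord[dom.peak_bin]:+.0f} bp")
print(f"half-height domain: {lo:+.0f} .. {hi:+.0f} bp ({dom.n_bins} bins, area {dom.area:.1f})")

ac_wt = rm.simulate_acetylation_signal(spec, sites, "post", induction_amplitude=0.6,
                                       induction_offset_bp=300.0)
ac_mut = rm.simulate_acetylation_signal(spec, sites, "post", induction_amplitude=0.0,
                                        induction_offset_bp=300.0, seed=spec.seed + 1)
ac_deficit = rm.profile_difference(
    rm.point_profile(ac_wt, sites), rm.point_profile(ac_mut, sites)
)
r, n = rm.profile_correlation(diff, ac_deficit)
print(f"repair-deficit vs acetylation-deficit correlation: r = {r:.2f} over {n} bins")
print(
    "\nThe shaded-domain analogue: repair and chromatin-modification deficits\n"
    "both concentrate in the ~1 kb around Abf1 sites, with different kernels\n"
    "(monotone decay vs lobes-with-NFR-dip), giving a positive but sub-unity r."
)
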