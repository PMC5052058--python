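"""The m-shaped histone H3 acetylation profile around binding sites.

Histone H3 acetylation forms two lobes flanking each Abf1 site with a
central dip over the nucleosome-free region.  UV irradiation raises the
lobes and pushes their maxima outward (300 bp -> 500 bp in this simulation).
The composite point profile recovers both planted offsets.
"""

import numpy as np

import repairmap as rm

spec = rm.SyntheticSpec(seed=19, chrom_lengths=[("chrI", 600_000)])
layout, genes, sites = rm.generate_genome(spec)

for state in ("pre", "post"):
    sset = rm.simulate_acetylation_signal(
        spec, sites, state, induction_amplitude=0.5, induction_offset_bp=500.0
    )
    prof = rm.point_profile(sset, sites)
    m = np.where(prof.nonempty, prof.mean, -np.inf)
    left = prof.coord[np.argmax(np.where(prof.coord < 0, m, -np.inf))]
    right = prof.coord[np.argmax(np.where(prof.coord > 0, m, -np.inf))]
    center = float(np.nanmean(prof.mean[np.abs(prof.coord) < 100]))
    print(
        f"{state}-UV : lobe maxima at {left:+.0f} / {right:+.0f} bp, "
        f"central (NFR) level {center:.2f} vs lobe {m.max():.2f}"
    )
print(
    "\nLobe maxima sit within one probe spacing (250 bp) of the planted\n"
    "offsets; the central dip marks the nucleosome-free region at the site."
)
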