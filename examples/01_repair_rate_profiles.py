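"""Relative CPD repair rates around gene structures, wild type vs rad16-null.

Simulates two UV-damage time courses (0 and 120 min post-UV), quantile-
normalizes each replicate set, subtracts the timepoint means probe-wise, and
builds deduplicated composite gene profiles.  The wild-type profile peaks
near the TSS (GG-NER organized from promoter-proximal Abf1 sites plus
transcription-coupled repair in bodies); the rad16-null profile lacks the
site-proximal component.
"""

import numpy as np

import repairmap as rm

spec = rm.SyntheticSpec(seed=11, chrom_lengths=[("chrI", 600_000), ("chrII", 500_000)])
layout, genes, sites = rm.generate_genome(spec)
print(f"genome: {layout.total_bp/1e6:.1f} Mb, {len(genes)} genes, {len(sites)} Abf1 sites")

for scenario in ("wildtype", "rad16_null"):
    model = rm.RepairModel(scenario=scenario)
    t0 = rm.simulate_damage_signal(spec, genes, sites, model, 0)
    t120 = rm.simulate_damage_signal(spec, genes, sites, model, 120)
    rate = rm.repair_rate(
        rm.normalize_set(t0, "quantile_only"), rm.normalize_set(t120, "quantile_only")
    )
    prof = rm.gene_profile(rate.track, rm.select_genes(genes))
    nz = prof.nonempty
    body = (prof.segment == "body") & nz
    up = (prof.segment == "upstream") & (prof.coord >= -500) & nz
    print(
        f"{scenario:11s}  mean rate {rate.track.value.mean():.3f}  "
        f"TSS-proximal {np.nanmean(prof.mean[up]):.3f}  "
        f"gene body {np.nanmean(prof.mean[body]):.3f}   (log2 arbitrary units)"
    )

print(
    "\nThe wild-type excess over rad16-null in the TSS-proximal bins is the\n"
    "GG-NER contribution organized from promoter Abf1 binding sites."
)
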