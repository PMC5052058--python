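"""Synthetic tiling-array data with planted, recoverable structure.

The generator builds toy yeast-like genomes and probe-level signal tracks in
which every qualitative feature the analysis pipeline is meant to detect is
planted explicitly and analytically:

* heterogeneous UV-damage (CPD) levels immediately after irradiation,
* repair removing damage with a gene-body (transcription-coupled) component
  scaled by expression and an Abf1-site-proximal (global-genome) component
  decaying exponentially with distance,
* protein-binding Gaussian peaks at planted Abf1 sites, with optional
  UV-induced redistribution of peak mass into the nearest ORF,
* "m-shaped" histone-acetylation profiles around sites: two symmetric lobes
  multiplied by a central nucleosome-free-region dip.

Noise-free tracks equal the closed-form truth functions exactly, so every
downstream stage is testable by parameter recovery.  All randomness flows
from explicit integer seeds through independent named streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import rankdata

from .core import GeneAnnotation, GenomeLayout, ProbeTrack, SignalSet, SiteSet, TrackMeta
from . import io_formats

__all__ = [
    "SyntheticSpec",
    "RepairModel",
    "SCENARIO_GG_FACTORS",
    "generate_genome",
    "generate_probe_grid",
    "planted_repair_field",
    "simulate_damage_signal",
    "simulate_binding_signal",
    "simulate_acetylation_signal",
    "write_dataset",
]

# Residual fraction of the Abf1-proximal (GG-NER) repair component retained in
# each mutant scenario.  rad16 deletion abolishes it; the gcn5 deletion and the
# Rad16 RING / ATPase point mutants retain partial function; the double point
# mutant is nearly null.
SCENARIO_GG_FACTORS: dict[str, float] = {
    "wildtype": 1.0,
    "rad16_null": 0.0,
    "gcn5_null": 0.4,
    "rad16_ring": 0.5,
    "rad16_atpase": 0.5,
    "rad16_double": 0.1,
}


@dataclass
class SyntheticSpec:
    """Experiment-design constants of the simulated study.

    Defaults describe a compact two-chromosome genome probed at Agilent-like
    250 bp spacing, a 100 J/m^2 UV dose, and replicate noise of 0.3 log2
    units, mirroring the measured-data design (timepoints 0/120 min,
    replicate counts 2-3, SEM/SD shading).
    """

    seed: int = 0
    chrom_lengths: list[tuple[str, int]] = field(
        default_factory=lambda: [("chrI", 300_000), ("chrII", 200_000)]
    )
    probe_spacing: int = 250
    gene_length_range: tuple[int, int] = (300, 3000)
    intergenic_gap_range: tuple[int, int] = (200, 1500)
    expression_dist: tuple[float, float] = (1.0, 1.0)  # lognormal (mu, sigma)
    abf1_promoter_prob: float = 0.6
    abf1_tes_prob: float = 0.15
    site_offset_range: tuple[int, int] = (50, 500)
    # Sites closer than ~6 probe spacings produce one contiguous enriched
    # region under gap-tolerant run merging and are not independently
    # resolvable by any probe-level method; the generator thins them.
    min_site_separation_bp: int = 1500
    peak_sigma: float = 200.0
    peak_height: float = 3.0
    nfr_halfwidth: float = 100.0
    noise_sd: float = 0.3
    n_replicates: int = 3
    uv_dose_label: str = "100 J/m^2"
    # CPD level field at t0 (lognormal on the log2-signal scale)
    cpd_level_mu: float = 0.8
    cpd_level_sigma: float = 0.25
    signal_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        for p, name in [
            (self.abf1_promoter_prob, "abf1_promoter_prob"),
            (self.abf1_tes_prob, "abf1_tes_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ValueError("invalid gene_length_range")
        lo, hi = self.intergenic_gap_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid intergenic_gap_range")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = [list(x) for x in self.chrom_lengths]
        for key in ("gene_length_range", "intergenic_gap_range", "expression_dist", "site_offset_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        d["chrom_lengths"] = [tuple(x) for x in d["chrom_lengths"]]
        for key in ("gene_length_range", "intergenic_gap_range", "expression_dist", "site_offset_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(tuple((str(c), int(l)) for c, l in self.chrom_lengths))


@dataclass
class RepairModel:
    """Planted repair-rate model: base + gene-body (TC) + site-proximal (GG) terms.

    The per-probe repair amount (log2 units removed between t0 and the repair
    timepoint) is::

        base_rate
        + tc_boost * expression_rank(gene) * [probe inside ORF]
        + gg_amplitude_eff * exp(-d / gg_decay_scale)

    where ``d`` is the distance from the probe midpoint to the nearest Abf1
    site and ``gg_amplitude_eff`` is ``gg_boost_amplitude`` times the
    scenario's residual-function factor.
    """

    base_rate: float = 0.2
    tc_boost: float = 0.4
    gg_boost_amplitude: float = 0.6
    gg_decay_scale: float = 1000.0
    scenario: str = "wildtype"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_GG_FACTORS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose one of {sorted(SCENARIO_GG_FACTORS)}"
            )
        for v, name in [
            (self.base_rate, "base_rate"),
            (self.tc_boost, "tc_boost"),
            (self.gg_boost_amplitude, "gg_boost_amplitude"),
        ]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def gg_amplitude_eff(self) -> float:
        return self.gg_boost_amplitude * SCENARIO_GG_FACTORS[self.scenario]


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


def generate_genome(spec: SyntheticSpec) -> tuple[GenomeLayout, GeneAnnotation, SiteSet]:
    """Lay out genes and Abf1 sites on the toy genome.

    Genes tile each chromosome: an intergenic gap is drawn, then a gene, and a
    gene is placed only when the full gene-plus-following-gap slot fits on the
    chromosome (last partial slot dropped).  Each gene gets a random strand
    and a lognormal expression draw.  Abf1 sites are placed 50-500 bp upstream
    of the TSS with probability ``abf1_promoter_prob`` and 50-500 bp
    downstream of the TES with probability ``abf1_tes_prob``; sites closer
    than ``min_site_separation_bp`` to an already-kept site are thinned.
    """
    rng = _rng(spec.seed, 1)
    layout = spec.layout()
    glo, ghi = spec.gene_length_range
    ilo, ihi = spec.intergenic_gap_range
    olo, ohi = spec.site_offset_range

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    site_records: list[tuple[int, float, str]] = []  # (chrom index, pos, class) per gene loop

    sites_by_chrom: dict[str, list[tuple[float, str]]] = {}
    for ci, (cname, clen) in enumerate(layout.chroms):
        pos = int(rng.integers(ilo, ihi + 1))  # leading gap gives the first gene a promoter region
        n_before = len(starts)
        site_list = sites_by_chrom.setdefault(cname, [])
        while True:
            gene_len = int(rng.integers(glo, ghi + 1))
            gap = int(rng.integers(ilo, ihi + 1))
            if pos + gene_len + gap > clen:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            chroms.append(cname)
            starts.append(pos)
            ends.append(pos + gene_len)
            strands.append(strand)
            tss = pos if strand == "+" else pos + gene_len
            tes = pos + gene_len if strand == "+" else pos
            sgn = 1 if strand == "+" else -1
            # draws happen unconditionally so the layout does not depend on
            # site probabilities
            u_prom, u_tes = rng.random(), rng.random()
            off_prom = int(rng.integers(olo, ohi + 1))
            off_tes = int(rng.integers(olo, ohi + 1))
            if u_prom < spec.abf1_promoter_prob:
                p = tss - sgn * off_prom
                if 0 <= p < clen:
                    site_list.append((float(p), "promoter"))
            if u_tes < spec.abf1_tes_prob:
                p = tes + sgn * off_tes
                if 0 <= p < clen:
                    site_list.append((float(p), "tes"))
            pos += gene_len + gap
        if len(starts) == n_before:
            raise ValueError(f"chromosome {cname!r} ({clen} bp) is too short to hold one gene")

    n_genes = len(starts)
    mu, sigma = spec.expression_dist
    expression = rng.lognormal(mean=mu, sigma=sigma, size=n_genes)

    s_chrom: list[str] = []
    s_mid: list[float] = []
    s_label: list[str] = []
    for cname, _ in layout.chroms:
        kept_last = -np.inf
        for p, lab in sorted(sites_by_chrom.get(cname, [])):
            if p - kept_last >= spec.min_site_separation_bp:
                s_chrom.append(cname)
                s_mid.append(p)
                s_label.append(lab)
                kept_last = p

    sites = SiteSet(
        np.asarray(s_chrom, dtype=object),
        np.asarray(s_mid, dtype=np.float64),
        np.ones(len(s_mid)),
        np.asarray([int(m) for m in s_mid], dtype=np.int64),
        np.asarray([int(m) + 1 for m in s_mid], dtype=np.int64),
    )
    sites.labels = np.asarray(s_label, dtype=object)  # class of each planted site

    genes = GeneAnnotation(
        np.asarray(chroms, dtype=object),
        np.asarray(starts),
        np.asarray(ends),
        np.asarray(strands, dtype=object),
        np.asarray([f"gene_{i:05d}" for i in range(n_genes)], dtype=object),
        expression,
    )
    return layout, genes, sites


def generate_probe_grid(layout: GenomeLayout, spacing: int) -> ProbeTrack:
    """Tile each chromosome with half-open probes of width ``spacing`` from 0.

    The last partial probe is dropped.  Values are initialised to 0.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    chroms: list[str] = []
    starts: list[int] = []
    for cname, clen in layout.chroms:
        n = clen // spacing
        chroms.extend([cname] * n)
        starts.extend(range(0, n * spacing, spacing))
    starts_arr = np.asarray(starts, dtype=np.int64)
    return ProbeTrack(
        np.asarray(chroms, dtype=object),
        starts_arr,
        starts_arr + spacing,
        np.zeros(len(starts_arr)),
        _presorted=True,
    )


def _distance_to_nearest_site(grid: ProbeTrack, sites: SiteSet) -> np.ndarray:
    """Per-probe distance (bp) from probe midpoint to the nearest site midpoint."""
    d = np.full(len(grid), np.inf)
    mids = grid.midpoint
    for cname in dict.fromkeys(grid.chrom):
        pmask = grid.chrom == cname
        smask = sites.chrom == cname
        if not np.any(smask):
            continue
        spos = np.sort(sites.midpoint[smask])
        pm = mids[pmask]
        idx = np.searchsorted(spos, pm)
        left = np.where(idx > 0, np.abs(pm - spos[np.maximum(idx - 1, 0)]), np.inf)
        right = np.where(idx < len(spos), np.abs(spos[np.minimum(idx, len(spos) - 1)] - pm), np.inf)
        d[pmask] = np.minimum(left, right)
    return d


def _gene_membership(grid: ProbeTrack, genes: GeneAnnotation) -> np.ndarray:
    """Index of the gene whose body contains each probe midpoint, or -1."""
    member = np.full(len(grid), -1, dtype=np.int64)
    mids = grid.midpoint
    for cname in dict.fromkeys(grid.chrom):
        pmask = grid.chrom == cname
        gmask = genes.chrom == cname
        if not np.any(gmask):
            continue
        gidx = np.flatnonzero(gmask)
        gstart = genes.start[gmask].astype(float)
        gend = genes.end[gmask].astype(float)
        order = np.argsort(gstart)
        gstart, gend, gidx = gstart[order], gend[order], gidx[order]
        pm = mids[pmask]
        j = np.searchsorted(gstart, pm, side="right") - 1
        ok = (j >= 0) & (pm < gend[np.maximum(j, 0)])
        out = np.where(ok, gidx[np.maximum(j, 0)], -1)
        member[pmask] = out
    return member


def expression_rank(genes: GeneAnnotation) -> np.ndarray:
    """Expression quantile rank in [0, 1] per gene (NaN expression -> 0)."""
    expr = genes.expression
    n = len(expr)
    if n == 0:
        return np.zeros(0)
    if n == 1:
        return np.ones(1)
    r = (rankdata(expr, method="average") - 1.0) / (n - 1.0)
    return np.where(np.isfinite(expr), r, 0.0)


def planted_repair_field(
    spec: SyntheticSpec,
    genes: GeneAnnotation,
    sites: SiteSet,
    model: RepairModel,
    grid: ProbeTrack,
    t0_truth: np.ndarray,
) -> np.ndarray:
    """Closed-form per-probe repair amount, clamped so t0 - repair >= floor."""
    d = _distance_to_nearest_site(grid, sites)
    with np.errstate(over="ignore"):
        gg = model.gg_amplitude_eff * np.exp(-d / model.gg_decay_scale)
    member = _gene_membership(grid, genes)
    ranks = expression_rank(genes)
    tc = np.where(member >= 0, model.tc_boost * ranks[np.maximum(member, 0)], 0.0)
    repair = model.base_rate + tc + gg
    return np.minimum(repair, np.maximum(t0_truth - spec.signal_floor, 0.0))


def t0_truth_field(spec: SyntheticSpec, grid: ProbeTrack, seed: int | None = None) -> np.ndarray:
    """Heterogeneous lognormal CPD level immediately after UV (shared across timepoints)."""
    seed = spec.seed if seed is None else seed
    rng = _rng(seed, 11)
    return rng.lognormal(mean=spec.cpd_level_mu, sigma=spec.cpd_level_sigma, size=len(grid))


def _replicates(
    truth: np.ndarray,
    spec: SyntheticSpec,
    grid: ProbeTrack,
    rng: np.random.Generator,
    meta_base: TrackMeta,
) -> list[ProbeTrack]:
    tracks = []
    for r in range(spec.n_replicates):
        noise = rng.normal(0.0, spec.noise_sd, size=len(truth)) if spec.noise_sd > 0 else 0.0
        meta = meta_base.copy()
        meta.label = f"{meta_base.label}_rep{r + 1}"
        tracks.append(grid.with_values(truth + noise, meta=meta))
    return tracks


def simulate_damage_signal(
    spec: SyntheticSpec,
    genes: GeneAnnotation,
    sites: SiteSet,
    model: RepairModel,
    timepoint_min: int,
    seed: int | None = None,
) -> SignalSet:
    """Replicate CPD tracks at t0 or after the repair period (t120).

    The t0 truth field depends only on (spec, seed), so the two timepoints of
    one simulated experiment share it; the planted repair amount is then the
    exact probe-wise difference of the noise-free truths.
    """
    if timepoint_min not in (0, 120):
        raise ValueError("timepoint_min must be 0 or 120")
    seed = spec.seed if seed is None else seed
    grid = generate_probe_grid(spec.layout(), spec.probe_spacing)
    t0 = t0_truth_field(spec, grid, seed)
    if timepoint_min == 0:
        truth = t0
    else:
        truth = t0 - planted_repair_field(spec, genes, sites, model, grid, t0)
    meta = TrackMeta(
        label=f"cpd_{model.scenario}_t{timepoint_min}",
        strain=model.scenario,
        factor="CPD",
        uv_timepoint_min=timepoint_min,
    )
    # noise stream deliberately independent of scenario: same-seed tracks for
    # two scenarios then differ exactly by the planted model terms
    rng = _rng(seed, 23, timepoint_min)
    tracks = _replicates(truth, spec, grid, rng, meta)
    return SignalSet(tracks, strain=model.scenario, factor="CPD", uv_timepoint_min=timepoint_min)


def binding_truth(
    spec: SyntheticSpec,
    sites: SiteSet,
    genes: GeneAnnotation,
    grid: ProbeTrack,
    uv_state: str,
    redistribution_fraction: float,
) -> np.ndarray:
    """Noise-free binding signal: Gaussian peaks over a flat zero background.

    Post-UV, ``redistribution_fraction`` of each peak's probe-summed mass is
    moved into a uniform increment over the probes of the ORF nearest the
    site, conserving total mass exactly.
    """
    if not 0.0 <= redistribution_fraction <= 1.0:
        raise ValueError("redistribution_fraction must be in [0, 1]")
    if len(sites) == 0:
        raise ValueError("need at least one site for peak placement")
    mids = grid.midpoint
    truth = np.zeros(len(grid))
    f = redistribution_fraction if uv_state == "post" else 0.0
    sig = spec.peak_sigma
    for i in range(len(sites)):
        cmask = grid.chrom == sites.chrom[i]
        d = mids[cmask] - sites.midpoint[i]
        contrib = spec.peak_height * np.exp(-(d**2) / (2.0 * sig**2))
        add = np.zeros(len(grid))
        add[cmask] = (1.0 - f) * contrib
        truth += add
        if f > 0:
            removed = f * contrib.sum()
            truth = _add_to_nearest_orf(truth, grid, genes, sites.chrom[i], sites.midpoint[i], removed)
    return truth


def _add_to_nearest_orf(
    truth: np.ndarray,
    grid: ProbeTrack,
    genes: GeneAnnotation,
    chrom: str,
    site_mid: float,
    mass: float,
) -> np.ndarray:
    gmask = genes.chrom == chrom
    if not np.any(gmask):
        # no ORF on this chromosome: park the mass on the nearest probe
        cmask = grid.chrom == chrom
        j = np.flatnonzero(cmask)[np.argmin(np.abs(grid.midpoint[cmask] - site_mid))]
        truth[j] += mass
        return truth
    gs = genes.start[gmask].astype(float)
    ge = genes.end[gmask].astype(float)
    dist = np.where(
        (site_mid >= gs) & (site_mid < ge),
        0.0,
        np.minimum(np.abs(site_mid - gs), np.abs(site_mid - ge)),
    )
    k = int(np.argmin(dist))
    body_mask = (grid.chrom == chrom) & (grid.midpoint >= gs[k]) & (grid.midpoint < ge[k])
    n_body = int(body_mask.sum())
    if n_body == 0:
        cmask = grid.chrom == chrom
        j = np.flatnonzero(cmask)[np.argmin(np.abs(grid.midpoint[cmask] - site_mid))]
        truth[j] += mass
    else:
        truth[body_mask] += mass / n_body
    return truth


def simulate_binding_signal(
    spec: SyntheticSpec,
    sites: SiteSet,
    genes: GeneAnnotation,
    uv_state: str,
    redistribution_fraction: float = 0.0,
    seed: int | None = None,
    factor: str = "Abf1",
) -> SignalSet:
    """Replicate protein-binding tracks pre- or post-UV."""
    if uv_state not in ("pre", "post"):
        raise ValueError("uv_state must be 'pre' or 'post'")
    seed = spec.seed if seed is None else seed
    grid = generate_probe_grid(spec.layout(), spec.probe_spacing)
    truth = binding_truth(spec, sites, genes, grid, uv_state, redistribution_fraction)
    meta = TrackMeta(label=f"{factor}_{uv_state}UV", factor=factor,
                     uv_timepoint_min=0 if uv_state == "post" else None)
    rng = _rng(seed, 31, 0 if uv_state == "pre" else 1)
    tracks = _replicates(truth, spec, grid, rng, meta)
    return SignalSet(tracks, factor=factor, uv_timepoint_min=meta.uv_timepoint_min)


def acetylation_truth(
    spec: SyntheticSpec,
    sites: SiteSet,
    grid: ProbeTrack,
    uv_state: str,
    induction_amplitude: float,
    induction_offset_bp: float,
    base_height: float = 1.0,
    base_offset_bp: float = 300.0,
    lobe_sigma: float = 150.0,
) -> np.ndarray:
    """Noise-free m-shaped acetylation signal around each site.

    Two symmetric Gaussian lobes peaking at +/-offset from the site midpoint,
    multiplied by a central dip of halfwidth ``nfr_halfwidth`` (the NFR).
    Pre-UV the lobes sit at ``base_offset_bp`` with height ``base_height``;
    UV moves them to ``induction_offset_bp`` and adds ``induction_amplitude``.
    """
    if induction_offset_bp < 0:
        raise ValueError("induction_offset_bp must be >= 0")
    if uv_state == "post":
        offset = induction_offset_bp
        height = base_height + induction_amplitude
    else:
        offset = base_offset_bp
        height = base_height
    mids = grid.midpoint
    truth = np.zeros(len(grid))
    for i in range(len(sites)):
        cmask = grid.chrom == sites.chrom[i]
        d = mids[cmask] - sites.midpoint[i]
        lobes = height * np.exp(-((np.abs(d) - offset) ** 2) / (2.0 * lobe_sigma**2))
        dip = 1.0 - np.exp(-(d**2) / (2.0 * spec.nfr_halfwidth**2))
        truth[cmask] += lobes * dip
    return truth


def simulate_acetylation_signal(
    spec: SyntheticSpec,
    sites: SiteSet,
    uv_state: str,
    induction_amplitude: float = 0.5,
    induction_offset_bp: float = 500.0,
    seed: int | None = None,
    base_height: float = 1.0,
    base_offset_bp: float = 300.0,
    lobe_sigma: float = 150.0,
) -> SignalSet:
    """Replicate histone-H3-acetylation tracks pre- or post-UV."""
    if uv_state not in ("pre", "post"):
        raise ValueError("uv_state must be 'pre' or 'post'")
    seed = spec.seed if seed is None else seed
    grid = generate_probe_grid(spec.layout(), spec.probe_spacing)
    truth = acetylation_truth(
        spec, sites, grid, uv_state, induction_amplitude, induction_offset_bp,
        base_height=base_height, base_offset_bp=base_offset_bp, lobe_sigma=lobe_sigma,
    )
    meta = TrackMeta(label=f"H3Ac_{uv_state}UV", factor="H3Ac",
                     uv_timepoint_min=0 if uv_state == "post" else None)
    rng = _rng(seed, 41, 0 if uv_state == "pre" else 1)
    tracks = _replicates(truth, spec, grid, rng, meta)
    return SignalSet(tracks, factor="H3Ac", uv_timepoint_min=meta.uv_timepoint_min)


def write_dataset(
    outdir: str | Path,
    spec: SyntheticSpec,
    genes: GeneAnnotation,
    sites: SiteSet,
    signal_sets: dict[str, SignalSet],
) -> Path:
    """Serialize a synthetic dataset: bedGraph per replicate, GFF3, BED, manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_gff3(genes, outdir / "genes.gff3")
    io_formats.write_bed_sites(sites, outdir / "sites.bed")
    with open(outdir / "expression.tsv", "w") as fh:
        for gid, e in zip(genes.gene_id, genes.expression):
            if np.isfinite(e):
                fh.write(f"{gid}\t{e:.10g}\n")
    groups = {}
    for name, sset in signal_sets.items():
        paths = []
        for t in sset.tracks:
            p = outdir / f"{name}_{t.meta.label}.bedgraph"
            io_formats.write_bedgraph(t, p)
            paths.append(p.name)
        groups[name] = {
            "paths": paths,
            "strain": sset.strain,
            "factor": sset.factor,
            "uv_timepoint_min": sset.uv_timepoint_min,
        }
    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "annotation": "genes.gff3",
        "sites": "sites.bed",
        "expression": "expression.tsv",
        "groups": groups,
    }
    io_formats.write_manifest(manifest, outdir / "manifest.yaml")
    return outdir / "manifest.yaml"
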