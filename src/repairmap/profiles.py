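"""Composite (metagene) profiles around gene structures and point features.

Signal from many features is averaged on a shared relative-coordinate axis:
fixed-bp bins in the flanks, length-normalized fractional bins across the
gene body, and signed-distance bins around point features.  A strict
no-double-counting rule applies throughout: each probe contributes to at most
one feature's window.  When windows overlap, the probe goes to the feature
whose nearest anchor (ORF start/end for gene profiles, site midpoint for
point profiles) is closest to the probe midpoint; exact ties go to the
lower-index feature.

Minus-strand genes are mirrored so transcription always runs left to right
on the profile axis.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .core import GeneAnnotation, GenomeLayout, ProbeTrack, SignalSet, SiteSet

log = logging.getLogger(__name__)

__all__ = [
    "ProfileSchema",
    "CompositeProfile",
    "ProbeAssignment",
    "select_genes",
    "genome_fraction_covered",
    "assign_probes",
    "gene_profile",
    "point_profile",
    "stratify_by_expression",
    "random_features",
    "localize_sites",
    "SiteLocalization",
    "flatness_check",
]


@dataclass(frozen=True)
class ProfileSchema:
    """Binning layout for composite profiles.

    flank_bp/flank_bin_bp set the fixed-bp flank axis of gene profiles;
    body_bins is the number of length-normalized gene-body bins;
    halfwidth_bp is the half-window of point profiles (binned at
    flank_bin_bp).
    """

    flank_bp: int = 2000
    flank_bin_bp: int = 50
    body_bins: int = 40
    halfwidth_bp: int = 2000

    def __post_init__(self) -> None:
        if self.flank_bp % self.flank_bin_bp != 0:
            raise ValueError("flank_bp must be divisible by flank_bin_bp")
        if self.halfwidth_bp % self.flank_bin_bp != 0:
            raise ValueError("halfwidth_bp must be divisible by flank_bin_bp")
        if self.body_bins < 1:
            raise ValueError("body_bins must be >= 1")

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    @property
    def n_gene_bins(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    @property
    def n_point_bins(self) -> int:
        return 2 * self.halfwidth_bp // self.flank_bin_bp


@dataclass
class CompositeProfile:
    """Binned relative-coordinate axis with per-bin mean, dispersion, counts.

    ``coord`` is bp (negative upstream / positive downstream) for flank and
    point bins and a fractional position in (0, 1) for gene-body bins;
    ``segment`` labels each bin upstream/body/downstream/point.  Bins with
    ``n_contributions == 0`` are empty and carry NaN mean/dispersion.
    """

    coord: np.ndarray
    segment: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray
    n_contributions: np.ndarray
    dispersion_kind: str = "SEM"

    def __post_init__(self) -> None:
        if np.any(self.n_contributions < 0):
            raise ValueError("n_contributions must be >= 0")
        if np.any(self.dispersion[self.nonempty] < 0):
            raise ValueError("dispersion must be >= 0")

    @property
    def nonempty(self) -> np.ndarray:
        return self.n_contributions > 0

    def __len__(self) -> int:
        return len(self.coord)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coord": self.coord,
                "segment": self.segment,
                "mean": self.mean,
                "dispersion": self.dispersion,
                "n_contributions": self.n_contributions,
            }
        )

    def same_schema(self, other: "CompositeProfile") -> bool:
        return (
            len(self) == len(other)
            and bool(np.allclose(self.coord, other.coord))
            and bool(np.all(self.segment == other.segment))
        )


@dataclass
class ProbeAssignment:
    """Map probe -> at most one feature (the no-double-counting rule).

    feature_index[i] is the index of the feature owning probe i, or -1.
    Structurally a probe can never appear under two features.
    """

    feature_index: np.ndarray

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.feature_index >= 0))


def select_genes(annotation: GeneAnnotation, min_len: int = 500, max_len: int = 1500) -> GeneAnnotation:
    """Retain genes with min_len <= length <= max_len (inclusive bounds)."""
    mask = (annotation.length >= min_len) & (annotation.length <= max_len)
    if not np.any(mask):
        log.warning("select_genes: no genes in [%d, %d] bp", min_len, max_len)
    return annotation.subset(mask)


def genome_fraction_covered(
    features: GeneAnnotation, layout: GenomeLayout, flank_bp: int
) -> float:
    """Fraction of the genome inside the union of feature-plus-flank windows."""
    covered = 0
    for cname, clen in layout.chroms:
        mask = features.chrom == cname
        if not np.any(mask):
            continue
        s = np.clip(features.start[mask] - flank_bp, 0, clen)
        e = np.clip(features.end[mask] + flank_bp, 0, clen)
        order = np.argsort(s)
        s, e = s[order], e[order]
        cur_s, cur_e = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] <= cur_e:
                cur_e = max(cur_e, e[i])
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = s[i], e[i]
        covered += cur_e - cur_s
    return covered / layout.total_bp


def _feature_windows_and_anchors(
    features: GeneAnnotation | SiteSet, schema: ProfileSchema
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[np.ndarray]]:
    """(chrom, win_start, win_end, anchor position list) per feature."""
    if isinstance(features, SiteSet):
        chrom = features.chrom
        ws = features.midpoint - schema.halfwidth_bp
        we = features.midpoint + schema.halfwidth_bp
        anchors = [np.array([m]) for m in features.midpoint]
    else:
        chrom = features.chrom
        ws = features.start.astype(float) - schema.flank_bp
        we = features.end.astype(float) + schema.flank_bp
        anchors = [
            np.array([float(s), float(e)]) for s, e in zip(features.start, features.end)
        ]
    return chrom, ws, we, anchors


def assign_probes(
    features: GeneAnnotation | SiteSet, track: ProbeTrack, schema: ProfileSchema
) -> ProbeAssignment:
    """Assign each probe to at most one feature window (dedup rule).

    Overlapping windows are resolved by the nearest-anchor rule; exact ties
    go to the lower feature index.
    """
    fchrom, ws, we, anchors = _feature_windows_and_anchors(features, schema)
    pm = track.midpoint
    best_dist = np.full(len(track), np.inf)
    best_feat = np.full(len(track), -1, dtype=np.int64)
    for cname in dict.fromkeys(track.chrom):
        cidx = np.flatnonzero(track.chrom == cname)
        cpm = pm[cidx]
        order = np.argsort(cpm)
        cidx, cpm = cidx[order], cpm[order]
        for fi in np.flatnonzero(fchrom == cname):
            lo = np.searchsorted(cpm, ws[fi], side="left")
            hi = np.searchsorted(cpm, we[fi], side="left")
            if hi <= lo:
                continue
            sub = cidx[lo:hi]
            d = np.min(np.abs(cpm[lo:hi, None] - anchors[fi][None, :]), axis=1)
            upd = d < best_dist[sub]  # strict: earlier (lower-index) feature wins ties
            best_dist[sub[upd]] = d[upd]
            best_feat[sub[upd]] = fi
    return ProbeAssignment(best_feat)


def _gene_bin_for_position(
    m: float, s: float, e: float, strand: str, schema: ProfileSchema
) -> int:
    """Bin index on the gene-profile axis for one genomic position.

    Minus-strand genes take the exact complement bin (N-1 minus the
    plus-strand bin), so flipping every strand reverses a profile exactly,
    including positions that fall on bin boundaries.
    """
    if strand == "-":
        return schema.n_gene_bins - 1 - _gene_bin_for_position(m, s, e, "+", schema)
    U, B = schema.n_flank_bins, schema.body_bins
    fb = schema.flank_bin_bp
    if m < s:
        rel = m - s  # in [-flank, 0)
        k = int(np.floor((rel + schema.flank_bp) / fb))
        return int(np.clip(k, 0, U - 1))
    if m < e:
        frac = (m - s) / (e - s)
        return U + int(np.clip(np.floor(frac * B), 0, B - 1))
    rel = m - e
    k = int(np.floor(rel / fb))
    return U + B + int(np.clip(k, 0, U - 1))


def _gene_axis(schema: ProfileSchema) -> tuple[np.ndarray, np.ndarray]:
    U, B, fb = schema.n_flank_bins, schema.body_bins, schema.flank_bin_bp
    coord = np.concatenate(
        [
            -schema.flank_bp + (np.arange(U) + 0.5) * fb,
            (np.arange(B) + 0.5) / B,
            (np.arange(U) + 0.5) * fb,
        ]
    )
    segment = np.concatenate(
        [np.repeat("upstream", U), np.repeat("body", B), np.repeat("downstream", U)]
    ).astype(object)
    return coord, segment


def _point_axis(schema: ProfileSchema) -> tuple[np.ndarray, np.ndarray]:
    n = schema.n_point_bins
    coord = -schema.halfwidth_bp + (np.arange(n) + 0.5) * schema.flank_bin_bp
    return coord, np.repeat("point", n).astype(object)


def _bin_stats(
    bins: np.ndarray, values: np.ndarray, n_bins: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = np.full(n_bins, np.nan)
    disp = np.full(n_bins, np.nan)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=values, minlength=n_bins)
    nz = counts > 0
    mean[nz] = sums[nz] / counts[nz]
    sq = np.bincount(bins, weights=values**2, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        var = np.where(counts > 1, (sq - counts * mean**2) / (counts - 1), 0.0)
        disp_nz = np.sqrt(np.maximum(var, 0.0) / np.maximum(counts, 1))
    disp[nz] = disp_nz[nz]
    return mean, disp, counts


def _single_track_profile(
    track: ProbeTrack,
    features: GeneAnnotation | SiteSet,
    schema: ProfileSchema,
    mode: str,
    assignment: ProbeAssignment | None,
) -> CompositeProfile:
    if assignment is None:
        assignment = assign_probes(features, track, schema)
    if mode == "gene":
        coord, segment = _gene_axis(schema)
    else:
        coord, segment = _point_axis(schema)
    n_bins = len(coord)
    assigned = np.flatnonzero(assignment.feature_index >= 0)
    bins = np.empty(len(assigned), dtype=np.int64)
    pm = track.midpoint
    if mode == "gene":
        assert isinstance(features, GeneAnnotation)
        for k, pi in enumerate(assigned):
            fi = assignment.feature_index[pi]
            bins[k] = _gene_bin_for_position(
                pm[pi], float(features.start[fi]), float(features.end[fi]),
                str(features.strand[fi]), schema,
            )
    else:
        assert isinstance(features, SiteSet)
        fb = schema.flank_bin_bp
        for k, pi in enumerate(assigned):
            fi = assignment.feature_index[pi]
            d = pm[pi] - features.midpoint[fi]
            bins[k] = int(np.clip(np.floor((d + schema.halfwidth_bp) / fb), 0, n_bins - 1))
    mean, disp, counts = _bin_stats(bins, track.value[assigned], n_bins)
    n_empty = int(np.sum(counts == 0))
    if n_empty:
        log.debug("%d empty profile bins", n_empty)
    return CompositeProfile(coord, segment, mean, disp, counts, dispersion_kind="SEM(contributions)")


def _profile(
    data: ProbeTrack | SignalSet,
    features: GeneAnnotation | SiteSet,
    schema: ProfileSchema,
    mode: str,
) -> CompositeProfile:
    if isinstance(data, SignalSet):
        assignment = assign_probes(features, data.grid, schema)
        reps = [
            _single_track_profile(t, features, schema, mode, assignment) for t in data.tracks
        ]
        if len(reps) == 1:
            return reps[0]
        means = np.stack([r.mean for r in reps])
        with np.errstate(invalid="ignore"):
            mean = means.mean(axis=0)
            sd = means.std(axis=0, ddof=1)
        n_rep = len(reps)
        disp, kind = (sd, "SD") if n_rep == 2 else (sd / np.sqrt(n_rep), "SEM")
        return CompositeProfile(
            reps[0].coord, reps[0].segment, mean, disp, reps[0].n_contributions, kind
        )
    return _single_track_profile(data, features, schema, mode, None)


def gene_profile(
    data: ProbeTrack | SignalSet, genes: GeneAnnotation, schema: ProfileSchema = ProfileSchema()
) -> CompositeProfile:
    """Composite profile over gene structures: bp flanks + scaled gene body.

    For a SignalSet the profile is computed per replicate and averaged, with
    SEM (SD for two replicates) across replicate profiles as the dispersion;
    for a single track the dispersion is the SEM over bin contributions.
    """
    return _profile(data, genes, schema, "gene")


def point_profile(
    data: ProbeTrack | SignalSet, sites: SiteSet, schema: ProfileSchema = ProfileSchema()
) -> CompositeProfile:
    """Composite profile of signed distance to site midpoints (dedup across sites)."""
    return _profile(data, sites, schema, "point")


def stratify_by_expression(
    genes: GeneAnnotation,
    expression: dict[str, float] | None = None,
    low_quantile: float = 0.15,
) -> tuple[GeneAnnotation, GeneAnnotation]:
    """Split genes into the lowest-expression stratum and the remainder.

    Genes without an expression value are excluded from both strata.  Ties at
    the quantile cut all go to the low stratum.
    """
    if expression is not None:
        expr = np.array([expression.get(g, np.nan) for g in genes.gene_id])
        genes = GeneAnnotation(
            genes.chrom, genes.start, genes.end, genes.strand, genes.gene_id, expr
        )
    valid = np.isfinite(genes.expression)
    if not np.any(valid):
        raise ValueError("no genes with expression values")
    if np.sum(~valid):
        log.warning("%d genes without expression excluded from stratification", int(np.sum(~valid)))
    sub = genes.subset(valid)
    cut = np.quantile(sub.expression, low_quantile)
    low_mask = sub.expression <= cut
    return sub.subset(low_mask), sub.subset(~low_mask)


def random_features(
    layout: GenomeLayout,
    n: int,
    length_range: tuple[int, int],
    flank: int = 0,
    seed: int = 0,
    max_attempts_per_feature: int = 1000,
) -> GeneAnnotation:
    """n uniform-random non-overlapping stranded intervals (simulated ORFs)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    lo, hi = length_range
    lens = np.array([l for _, l in layout.chroms], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    chroms, starts, ends = [], [], []
    attempts = 0
    budget = max_attempts_per_feature * n
    while len(starts) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} random features after {budget} attempts"
            )
        attempts += 1
        ci = rng.choice(len(lens), p=lens / lens.sum())
        cname, clen = layout.chroms[ci]
        L = int(rng.integers(lo, hi + 1))
        if clen - L - 2 * flank <= 0:
            continue
        s = int(rng.integers(flank, clen - L - flank + 1))
        e = s + L
        if any(s < pe and ps < e for ps, pe in placed[cname]):
            continue
        placed[cname].append((s, e))
        chroms.append(cname)
        starts.append(s)
        ends.append(e)
    strands = np.where(rng.random(n) < 0.5, "+", "-").astype(object)
    return GeneAnnotation(
        np.asarray(chroms, dtype=object), starts, ends, strands,
        np.asarray([f"random_{i:05d}" for i in range(n)], dtype=object),
    )


@dataclass
class SiteLocalization:
    """Per-site position relative to its owning gene, plus class summaries."""

    gene_index: np.ndarray      # -1 when unattached
    rel_coord: np.ndarray       # bp (negative upstream / positive downstream) or body fraction
    region_class: np.ndarray    # 'upstream' | 'body' | 'downstream' | 'unattached'
    class_counts: dict[str, int]
    class_score_fractions: dict[str, float]

    @property
    def n_unattached(self) -> int:
        return int(np.sum(self.gene_index < 0))


def localize_sites(
    sites: SiteSet, genes: GeneAnnotation, schema: ProfileSchema = ProfileSchema()
) -> SiteLocalization:
    """Attach each site to one gene window (dedup rule) and classify it.

    The relative coordinate uses the same transform as gene profiles:
    negative bp upstream of the TSS, fractional position inside the ORF body,
    positive bp downstream of the TES.
    """
    pseudo = ProbeTrack(
        sites.chrom,
        np.floor(sites.midpoint).astype(np.int64),
        np.floor(sites.midpoint).astype(np.int64) + 1,
        sites.score,
    )
    # ProbeTrack sorts; recover mapping back to the sites order
    order = np.lexsort((np.floor(sites.midpoint).astype(np.int64),
                        _chrom_order_key(sites.chrom)))
    assignment = assign_probes(genes, pseudo, schema)
    gene_index = np.full(len(sites), -1, dtype=np.int64)
    gene_index[order] = assignment.feature_index
    rel = np.full(len(sites), np.nan)
    cls = np.full(len(sites), "unattached", dtype=object)
    for i in range(len(sites)):
        fi = gene_index[i]
        if fi < 0:
            continue
        m = sites.midpoint[i]
        s, e = float(genes.start[fi]), float(genes.end[fi])
        if genes.strand[fi] == "-":
            m = s + e - m
        if m < s:
            rel[i], cls[i] = m - s, "upstream"
        elif m < e:
            rel[i], cls[i] = (m - s) / (e - s), "body"
        else:
            rel[i], cls[i] = m - e, "downstream"
    counts = {c: int(np.sum(cls == c)) for c in ("upstream", "body", "downstream")}
    total_score = float(np.sum(sites.score[gene_index >= 0])) or 1.0
    fracs = {
        c: float(np.sum(sites.score[cls == c])) / total_score
        for c in ("upstream", "body", "downstream")
    }
    return SiteLocalization(gene_index, rel, cls, counts, fracs)


def _chrom_order_key(chrom: np.ndarray) -> np.ndarray:
    first_seen: dict[str, int] = {}
    key = np.empty(len(chrom), dtype=np.int64)
    for i, c in enumerate(chrom):
        if c not in first_seen:
            first_seen[c] = len(first_seen)
        key[i] = first_seen[c]
    return key


def flatness_check(profile: CompositeProfile, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Test a composite profile for flatness against its global mean.

    Each non-empty bin's deviation from the contribution-weighted global mean
    is scored in units of its standard error and compared against a
    per-bin Student-t quantile (df = contributions - 1; bins with few
    contributions have genuinely heavy-tailed statistics).  The per-bin level
    is Sidak-corrected so that a truly flat profile passes the whole check
    with probability 1 - ``alpha``, regardless of the number of bins.

    Returns (max of |z|/threshold over bins, 1.0, passed).
    """
    nz = profile.nonempty & (profile.n_contributions > 1)
    B = int(np.sum(nz))
    if B == 0:
        raise ValueError("profile has no testable bins")
    w = profile.n_contributions[profile.nonempty]
    global_mean = float(
        np.average(profile.mean[profile.nonempty], weights=w)
    )
    se = profile.dispersion[nz].copy()
    se[se == 0] = np.nan
    z = np.abs(profile.mean[nz] - global_mean) / se
    per_bin_alpha = 1.0 - (1.0 - alpha) ** (1.0 / B)
    df = profile.n_contributions[nz] - 1
    thr = t_dist.ppf(1.0 - per_bin_alpha / 2.0, df)
    ratio = float(np.nanmax(z / thr))
    return ratio, 1.0, ratio <= 1.0
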