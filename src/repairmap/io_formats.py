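"""Readers and writers for the standard genomic text formats the pipeline touches.

Internal convention is 0-based half-open everywhere; GFF3 (1-based inclusive)
is converted at the boundary. bedGraph is the probe-track interchange format,
one file per replicate; replicate grouping is declared in a YAML manifest,
never inferred from filenames.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import GeneAnnotation, GenomeLayout, ProbeTrack, SiteSet, TrackMeta

log = logging.getLogger(__name__)

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_wig_fixedstep",
    "read_gff3",
    "write_gff3",
    "read_bed_genes",
    "read_bed_sites",
    "write_bed_sites",
    "read_expression_table",
    "read_manifest",
    "write_manifest",
]


def read_bedgraph(path: str | Path, meta: TrackMeta | None = None) -> ProbeTrack:
    """Read a 4-column tab-separated bedGraph (0-based half-open) into a ProbeTrack.

    Probes out of order are sorted on load with a warning; overlapping probes
    or non-numeric values are errors (with the offending line reported).
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate or value") from exc
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            values.append(v)
    if len(starts) > 1:
        arr_s = np.asarray(starts)
        arr_c = np.asarray(chroms, dtype=object)
        same = arr_c[1:] == arr_c[:-1]
        if np.any(same & (arr_s[1:] < arr_s[:-1])):
            log.warning("%s: probes out of order; sorting on load", path)
    track = ProbeTrack(chroms, starts, ends, values, meta=meta)
    if not track.meta.label:
        track.meta.label = path.stem
    return track


def write_bedgraph(track: ProbeTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in zip(track.chrom, track.start, track.end, track.value):
            fh.write(f"{c}\t{s}\t{e}\t{v:.17g}\n")


def read_wig_fixedstep(path: str | Path, meta: TrackMeta | None = None) -> ProbeTrack:
    """Read a fixedStep WIG file (read-only support; 1-based starts per the format)."""
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    values: list[float] = []
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # WIG is 1-based
                step = int(fields.get("step", 1))
                span = int(fields.get("span", step))
                continue
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: data before fixedStep header")
            chroms.append(chrom)
            starts.append(pos)
            ends.append(pos + span)
            values.append(float(line))
            pos += step
    return ProbeTrack(chroms, starts, ends, values, meta=meta)


def read_gff3(
    path: str | Path,
    feature_types: tuple[str, ...] = ("gene", "ORF"),
) -> GeneAnnotation:
    """Read gene records from a GFF3 file (1-based inclusive -> 0-based half-open).

    Only records whose type is in ``feature_types`` are retained; the number
    of skipped records is logged.
    """
    chroms, starts, ends, strands, ids = [], [], [], [], []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] not in feature_types:
                skipped += 1
                continue
            start1, end1 = int(parts[3]), int(parts[4])
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end < start")
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID", attrs.get("Name", f"feature_{lineno}"))
            chroms.append(parts[0])
            starts.append(start1 - 1)
            ends.append(end1)
            strands.append(parts[6] if parts[6] in "+-" else "+")
            ids.append(gid)
    if skipped:
        log.info("%s: skipped %d non-gene records", path, skipped)
    return GeneAnnotation(
        np.asarray(chroms, dtype=object), starts, ends,
        np.asarray(strands, dtype=object), np.asarray(ids, dtype=object),
    )


def write_gff3(genes: GeneAnnotation, path: str | Path, source: str = "repairmap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i in range(len(genes)):
            fh.write(
                f"{genes.chrom[i]}\t{source}\tgene\t{genes.start[i] + 1}\t{genes.end[i]}"
                f"\t.\t{genes.strand[i]}\t.\tID={genes.gene_id[i]}\n"
            )


def read_bed_genes(path: str | Path) -> GeneAnnotation:
    """Read a BED4/BED6 file (0-based half-open) as a gene annotation."""
    chroms, starts, ends, strands, ids = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            s, e = int(parts[1]), int(parts[2])
            if e < s:
                raise ValueError(f"{path}:{lineno}: end < start")
            chroms.append(parts[0])
            starts.append(s)
            ends.append(e)
            ids.append(parts[3] if len(parts) > 3 else f"feature_{lineno}")
            strands.append(parts[5] if len(parts) > 5 and parts[5] in "+-" else "+")
    return GeneAnnotation(
        np.asarray(chroms, dtype=object), starts, ends,
        np.asarray(strands, dtype=object), np.asarray(ids, dtype=object),
    )


def read_bed_sites(path: str | Path) -> SiteSet:
    """Read a BED file of binding sites.

    Columns 7–8, when present, carry the source-region span (extended BED as
    written by :func:`write_bed_sites`); otherwise the BED interval itself is
    the source and the site midpoint is its center.
    """
    chroms, mids, scores, ss, se = [], [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            s, e = int(parts[1]), int(parts[2])
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            if len(parts) >= 8:
                src_s, src_e = int(parts[6]), int(parts[7])
                mid = (s + e) / 2.0
            else:
                src_s, src_e = s, e
                mid = (s + e) / 2.0
            chroms.append(parts[0])
            mids.append(mid)
            scores.append(score)
            ss.append(src_s)
            se.append(src_e)
    return SiteSet(np.asarray(chroms, dtype=object), mids, scores, ss, se)


def write_bed_sites(sites: SiteSet, path: str | Path) -> None:
    """Write sites as extended BED6+2: 1 bp midpoint interval, score, source span."""
    with open(path, "w") as fh:
        for i in range(len(sites)):
            m = int(round(sites.midpoint[i]))
            fh.write(
                f"{sites.chrom[i]}\t{m}\t{m + 1}\tsite_{i}\t{sites.score[i]:.6g}\t."
                f"\t{sites.source_start[i]}\t{sites.source_end[i]}\n"
            )


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV of gene id -> expression value.

    Duplicate ids are an error; an empty file yields an empty map with a warning.
    """
    path = Path(path)
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gid = parts[0]
            if gid in table:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            table[gid] = float(parts[1])
    if not table:
        log.warning("%s: empty expression table", path)
    return table


def attach_expression(genes: GeneAnnotation, table: dict[str, float]) -> GeneAnnotation:
    """Attach expression values to an annotation; unmatched table ids are reported."""
    ids = set(genes.gene_id.tolist())
    unmatched = [g for g in table if g not in ids]
    if unmatched:
        log.warning("%d expression ids not present in annotation", len(unmatched))
    expr = np.array([table.get(g, np.nan) for g in genes.gene_id], dtype=np.float64)
    return GeneAnnotation(genes.chrom, genes.start, genes.end, genes.strand, genes.gene_id, expr)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
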