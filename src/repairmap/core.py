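"""Core in-memory containers shared by every stage of the pipeline.

All coordinates are 0-based half-open; conversion to/from 1-based
conventions happens only at format boundaries (see :mod:`repairmap.io_formats`).
Signal values are on a log2 scale throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "TrackMeta",
    "ProbeTrack",
    "SignalSet",
    "GeneAnnotation",
    "SiteSet",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for name, length in self.chroms:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.chroms)


@dataclass
class TrackMeta:
    """Descriptive metadata carried by a probe track."""

    label: str = ""
    strain: str = ""
    factor: str = ""          # immunoprecipitated factor or mark ("CPD", "Abf1", "H3Ac", ...)
    uv_timepoint_min: int | None = None
    normalization: str = "none"

    def copy(self) -> "TrackMeta":
        return dataclasses.replace(self)


class ProbeTrack:
    """Sorted, non-overlapping probe intervals each carrying one log2 value.

    Parameters
    ----------
    chrom, start, end, value
        Parallel arrays. Probes are sorted by (chromosome order of first
        appearance, start) on construction; overlap within a chromosome is
        an error.
    """

    def __init__(
        self,
        chrom: Sequence[str] | np.ndarray,
        start: Sequence[int] | np.ndarray,
        end: Sequence[int] | np.ndarray,
        value: Sequence[float] | np.ndarray,
        meta: TrackMeta | None = None,
        *,
        _presorted: bool = False,
    ) -> None:
        chrom = np.asarray(chrom, dtype=object)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        value = np.asarray(value, dtype=np.float64)
        if not (len(chrom) == len(start) == len(end) == len(value)):
            raise ValueError("chrom/start/end/value must have equal length")
        if len(start) and np.any(end <= start):
            i = int(np.argmax(end <= start))
            raise ValueError(f"probe {i}: end <= start ({start[i]}..{end[i]})")
        if len(value) and not np.all(np.isfinite(value)):
            raise ValueError("probe values must be finite")
        if not _presorted and len(start):
            # stable sort: chromosomes keep first-appearance order
            _, chrom_codes = np.unique(chrom, return_inverse=True)
            first_seen: dict[str, int] = {}
            order_key = np.empty(len(chrom), dtype=np.int64)
            for i, c in enumerate(chrom):
                if c not in first_seen:
                    first_seen[c] = len(first_seen)
                order_key[i] = first_seen[c]
            order = np.lexsort((start, order_key))
            chrom, start, end, value = chrom[order], start[order], end[order], value[order]
        self.chrom = chrom
        self.start = start
        self.end = end
        self.value = value
        self.meta = meta if meta is not None else TrackMeta()
        self._check_overlap()

    def _check_overlap(self) -> None:
        if len(self.start) < 2:
            return
        same = self.chrom[1:] == self.chrom[:-1]
        bad = same & (self.start[1:] < self.end[:-1])
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                "overlapping probes: "
                f"({self.chrom[i]}:{self.start[i]}-{self.end[i]}) and "
                f"({self.chrom[i + 1]}:{self.start[i + 1]}-{self.end[i + 1]})"
            )

    def __len__(self) -> int:
        return len(self.start)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.end) / 2.0

    def same_grid(self, other: "ProbeTrack") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    def with_values(self, values: np.ndarray, meta: TrackMeta | None = None) -> "ProbeTrack":
        """New track on the same grid carrying ``values``."""
        return ProbeTrack(
            self.chrom, self.start, self.end, values,
            meta=meta if meta is not None else self.meta.copy(),
            _presorted=True,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "value": self.value}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeTrack):
            return NotImplemented
        return self.same_grid(other) and bool(np.array_equal(self.value, other.value))

    def __repr__(self) -> str:
        return f"ProbeTrack(n={len(self)}, label={self.meta.label!r})"


@dataclass
class SignalSet:
    """A replicate group of ProbeTracks sharing one probe grid."""

    tracks: list[ProbeTrack]
    strain: str = ""
    factor: str = ""
    uv_timepoint_min: int | None = None
    normalization: str = "none"

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("SignalSet needs at least one track")
        grid = self.tracks[0]
        for t in self.tracks[1:]:
            if not grid.same_grid(t):
                raise ValueError("replicate tracks are not on an identical probe grid")

    @property
    def n_replicates(self) -> int:
        return len(self.tracks)

    @property
    def grid(self) -> ProbeTrack:
        return self.tracks[0]

    def values_matrix(self) -> np.ndarray:
        """(n_replicates, n_probes) value matrix."""
        return np.stack([t.value for t in self.tracks])


@dataclass
class GeneAnnotation:
    """Stranded ORF intervals with ids and optional expression values."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray
    gene_id: np.ndarray
    expression: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.strand = np.asarray(self.strand, dtype=object)
        self.gene_id = np.asarray(self.gene_id, dtype=object)
        if self.expression is None:
            self.expression = np.full(len(self.start), np.nan)
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if len(self.start) and np.any(self.end <= self.start):
            raise ValueError("gene with end <= start")
        bad = set(self.strand) - {"+", "-"}
        if bad:
            raise ValueError(f"invalid strand symbols: {bad}")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def length(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, mask: np.ndarray) -> "GeneAnnotation":
        return GeneAnnotation(
            self.chrom[mask], self.start[mask], self.end[mask],
            self.strand[mask], self.gene_id[mask], self.expression[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom, "start": self.start, "end": self.end,
                "strand": self.strand, "gene_id": self.gene_id,
                "expression": self.expression,
            }
        )


@dataclass
class SiteSet:
    """Point features (binding sites) with scores and source intervals."""

    chrom: np.ndarray
    midpoint: np.ndarray
    score: np.ndarray
    source_start: np.ndarray
    source_end: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.midpoint = np.asarray(self.midpoint, dtype=np.float64)
        self.score = np.asarray(self.score, dtype=np.float64)
        self.source_start = np.asarray(self.source_start, dtype=np.int64)
        self.source_end = np.asarray(self.source_end, dtype=np.int64)
        n = len(self.midpoint)
        if not all(len(a) == n for a in (self.chrom, self.score, self.source_start, self.source_end)):
            raise ValueError("SiteSet arrays must have equal length")
        inside = (self.midpoint >= self.source_start) & (self.midpoint <= self.source_end)
        if n and not np.all(inside):
            raise ValueError("site midpoint outside its source interval")

    def __len__(self) -> int:
        return len(self.midpoint)

    @classmethod
    def empty(cls) -> "SiteSet":
        z = np.array([])
        return cls(z.astype(object), z, z, z.astype(np.int64), z.astype(np.int64))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom, "midpoint": self.midpoint, "score": self.score,
                "source_start": self.source_start, "source_end": self.source_end,
            }
        )
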