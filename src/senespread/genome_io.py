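"""Core genomic data model and readers/writers for BED12, GTF, bedGraph and TSV.

All coordinates are 0-based half-open internally (BED convention).  GTF input
(1-based closed) is converted on read.  The TSS of a minus-strand gene is
``gene.end`` (the half-open right edge), so that windows expressed relative to
the TSS are always in transcribed orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GenomicWindow",
    "CoverageTrack",
    "ParseError",
    "ValidationError",
    "read_gene_models",
    "write_gene_models",
    "read_coverage",
    "write_coverage",
    "resolve_window",
]


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when parsed data violates a model invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicWindow:
    """A strand-aware window relative to a gene anchor.

    ``rel_start``/``rel_end`` are signed offsets in transcribed orientation;
    negative values lie upstream of the anchor.
    """

    anchor: str  # "tss" | "tes" | "absolute"
    rel_start: int
    rel_end: int

    def __post_init__(self) -> None:
        if self.anchor not in ("tss", "tes", "absolute"):
            raise ValidationError(f"unknown anchor {self.anchor!r}")
        if not self.rel_start < self.rel_end:
            raise ValidationError(
                f"window rel_start {self.rel_start} must be < rel_end {self.rel_end}"
            )

    @property
    def length(self) -> int:
        return self.rel_end - self.rel_start


@dataclass(frozen=True)
class GeneModel:
    """One transcription unit: coordinate anchor for every window computation."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.end:
                raise ValidationError(f"{self.gene_id}: bad exon ({s}, {e})")
            prev_end = e
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def resolve_window(gene: GeneModel, window: GenomicWindow) -> tuple[str, int, int]:
    """Map a relative window onto absolute coordinates, clipped at 0.

    For a + strand gene the anchor offsets add directly; for a - strand gene
    they mirror, so upstream stays upstream in transcribed orientation.
    """
    if window.anchor == "absolute":
        a, b = window.rel_start, window.rel_end
    else:
        anchor = gene.tss if window.anchor == "tss" else gene.tes
        if gene.strand == "+":
            a, b = anchor + window.rel_start, anchor + window.rel_end
        else:
            a, b = anchor - window.rel_end, anchor - window.rel_start
    a = max(a, 0)
    b = max(b, 0)
    return gene.chrom, a, b


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Non-negative piecewise-constant signal over genomic intervals.

    Internally stored per chromosome as sorted, non-overlapping
    ``(starts, ends, values)`` arrays.  Overlapping input intervals are merged
    by summation.  ``library_size`` defaults to the total signal
    (sum of value x interval length) and is the normalizer for all densities.
    """

    def __init__(
        self,
        intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        library_size: float | None = None,
        label: str = "",
    ) -> None:
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._prefix: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, (s, e, v) in intervals.items():
                self._set_chrom(chrom, s, e, v)
        self.label = label
        total = self.total_signal()
        self.library_size = float(library_size) if library_size is not None else total
        if self.library_size < 0:
            raise ValidationError("library_size must be >= 0")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        records: Iterable[tuple[str, int, int, float]],
        library_size: float | None = None,
        label: str = "",
    ) -> "CoverageTrack":
        """Build a track from (chrom, start, end, value) tuples.

        Overlapping intervals are summed; zero-value stretches are dropped.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in records:
            if v < 0:
                raise ValidationError(f"negative coverage value {v} at {chrom}:{s}-{e}")
            if e <= s:
                raise ValidationError(f"empty interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((int(s), int(e), float(v)))
        track = cls(label=label)
        for chrom, ivs in by_chrom.items():
            s, e, v = _merge_summing(ivs)
            track._set_chrom(chrom, s, e, v)
        track.library_size = (
            float(library_size) if library_size is not None else track.total_signal()
        )
        return track

    def _set_chrom(self, chrom: str, s: np.ndarray, e: np.ndarray, v: np.ndarray) -> None:
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        v = np.asarray(v, dtype=np.float64)
        if np.any(v < 0):
            raise ValidationError(f"negative coverage value on {chrom}")
        if len(s) and (np.any(np.diff(s) < 0) or np.any(e[:-1] > s[1:]) or np.any(e <= s)):
            raise ValidationError(f"intervals on {chrom} not sorted/non-overlapping")
        self._chroms[chrom] = (s, e, v)
        # prefix[i] = total signal in intervals [0, i)
        self._prefix[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])

    # -- queries -----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def intervals(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._chroms.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    def total_signal(self) -> float:
        return float(sum(p[-1] for p in self._prefix.values())) if self._prefix else 0.0

    def _integral_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Cumulative per-base signal from -inf up to each (possibly fractional)
        position; linear within an interval, so fractional bin edges apportion
        signal by exact base overlap."""
        s, e, v = self.intervals(chrom)
        pref = self._prefix.get(chrom, np.array([0.0]))
        pos = np.asarray(pos, dtype=np.float64)
        idx = np.searchsorted(s, pos, side="right") - 1
        idx_c = np.clip(idx, 0, max(len(s) - 1, 0))
        out = pref[np.maximum(idx, 0)]
        if len(s):
            inside = np.clip(pos - s[idx_c], 0.0, (e - s)[idx_c].astype(float))
            out = out + np.where(idx >= 0, v[idx_c] * inside, 0.0)
        return out

    def window_sum(self, chrom: str, start: float, end: float) -> float:
        """Total per-base signal over [start, end)."""
        if end <= start:
            return 0.0
        lo, hi = self._integral_at(chrom, np.array([start, end]))
        return float(hi - lo)

    def binned_sums(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Per-bin signal for consecutive bins defined by monotone edges."""
        f = self._integral_at(chrom, np.asarray(edges, dtype=np.float64))
        return np.diff(f)

    def scaled(self, k: float) -> "CoverageTrack":
        out = CoverageTrack(label=self.label, library_size=self.library_size)
        for chrom, (s, e, v) in self._chroms.items():
            out._set_chrom(chrom, s, e, v * k)
        return out


def _merge_summing(
    ivs: list[tuple[int, int, float]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve possibly-overlapping intervals into disjoint ones, summing values."""
    starts = np.array([i[0] for i in ivs], dtype=np.int64)
    ends = np.array([i[1] for i in ivs], dtype=np.int64)
    vals = np.array([i[2] for i in ivs], dtype=np.float64)
    points = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(len(points), dtype=np.float64)
    np.add.at(delta, np.searchsorted(points, starts), vals)
    np.add.at(delta, np.searchsorted(points, ends), -vals)
    level = np.cumsum(delta)[:-1]
    seg_s, seg_e = points[:-1], points[1:]
    keep = level > 0
    s, e, v = seg_s[keep], seg_e[keep], level[keep]
    # coalesce adjacent segments with identical value
    if len(s):
        brk = np.concatenate([[True], (s[1:] != e[:-1]) | (v[1:] != v[:-1])])
        idx = np.flatnonzero(brk)
        out_s = s[idx]
        out_e = np.concatenate([e[idx[1:] - 1], [e[-1]]])
        out_v = v[idx]
        return out_s, out_e, out_v
    return s, e, v


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(
    path: str | Path, biotype_filter: str | None = None
) -> list[GeneModel]:
    """Read gene models from BED12 or GTF (dialect detected by extension, then
    content) and return them sorted by (chrom, start, gene_id).

    Duplicate gene_ids are rejected; records violating the coordinate
    invariants raise :class:`ValidationError` naming the gene.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff"):
        genes = _read_gtf(path)
    elif suffix == ".bed":
        genes = _read_bed12(path)
    else:
        with open(path) as fh:
            first = fh.readline()
        genes = _read_gtf(path) if first.count("\t") >= 8 and not _looks_bed(first) else _read_bed12(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    if biotype_filter is not None:
        genes = [g for g in genes if g.biotype == biotype_filter]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _looks_bed(line: str) -> bool:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 3:
        return False
    try:
        int(parts[1]), int(parts[2])
    except ValueError:
        return False
    return True


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name, strand = parts[3], parts[5]
                if len(parts) >= 12:
                    n_blocks = int(parts[9])
                    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                    if len(sizes) != n_blocks or len(offsets) != n_blocks:
                        raise ValueError("block count mismatch")
                    exons = tuple(
                        (start + o, start + o + sz) for o, sz in zip(offsets, sizes)
                    )
                else:
                    exons = ()
                biotype = parts[12] if len(parts) > 12 else "protein_coding"
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start for {name}")
            genes.append(
                GeneModel(
                    gene_id=name, chrom=chrom, strand=strand,
                    start=start, end=end, exons=exons, biotype=biotype,
                )
            )
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    spans: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon"):
                continue
            try:
                s, e = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if e <= s:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            attrd = dict(_GTF_ATTR.findall(attrs))
            gid = attrd.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            rec = spans.setdefault(
                gid,
                {"chrom": chrom, "strand": strand, "start": None, "end": None,
                 "exons": [], "biotype": attrd.get("gene_biotype", "protein_coding")},
            )
            if feature == "gene":
                rec["start"], rec["end"] = s, e
                if "gene_biotype" in attrd:
                    rec["biotype"] = attrd["gene_biotype"]
            else:
                rec["exons"].append((s, e))
    genes = []
    for gid, rec in spans.items():
        exons = tuple(sorted(rec["exons"]))
        start = rec["start"] if rec["start"] is not None else exons[0][0]
        end = rec["end"] if rec["end"] is not None else exons[-1][1]
        genes.append(
            GeneModel(
                gene_id=gid, chrom=rec["chrom"], strand=rec["strand"],
                start=start, end=end, exons=exons, biotype=rec["biotype"],
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write BED12 (+ a 13th biotype column), sorted by (chrom, start, gene_id)."""
    rows = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        offs = ",".join(str(s - g.start) for s, e in g.exons) + ","
        rows.append(
            "\t".join(
                [g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                 str(g.start), str(g.end), "0", str(len(g.exons)), sizes, offs,
                 g.biotype]
            )
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# Coverage I/O
# ---------------------------------------------------------------------------


def read_coverage(
    path: str | Path, library_size: float | None = None, label: str = ""
) -> CoverageTrack:
    """Read a 4-column bedGraph.  Overlapping intervals are merged by summation;
    default library size is the total signal."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if v < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {v}")
            records.append((chrom, s, e, v))
    return CoverageTrack.from_intervals(
        records, library_size=library_size, label=label or path.stem
    )


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.intervals(chrom)
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{chrom}\t{si}\t{ei}\t{vi:.12g}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV writer used by every stage."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
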