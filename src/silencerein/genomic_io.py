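"""Readers and writers for the genomic text formats the pipeline consumes.

Every coordinate inside the package is 0-based, half-open ``[start, end)``
(the native BED/BEDPE convention).  Any reader for a 1-based dialect must
convert at this boundary so the rest of the package never sees another
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "GenomicInterval",
    "ChromatinLoop",
    "ElementClass",
    "RegulatoryElement",
    "SignalTrack",
    "BedParseError",
    "read_bedpe",
    "write_bedpe",
    "read_bed_elements",
    "write_bed_elements",
    "read_bedgraph",
    "GenomeSequence",
]


class BedParseError(ValueError):
    """Raised when a BED-family file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` in nucleotides."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap(other) > 0


@dataclass(frozen=True)
class ChromatinLoop:
    """A chromatin loop joining two anchors, with optional PET support count."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    support: int = 0

    def __post_init__(self) -> None:
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError(
                "inter-chromosomal loop: "
                f"{self.anchor_a.chrom} vs {self.anchor_b.chrom}"
            )
        if self.support < 0:
            raise ValueError(f"negative support {self.support}")


class ElementClass(str, Enum):
    """Regulatory-element classes recognised by the pipeline."""

    SILENCER = "silencer"
    NON_SILENCER = "non_silencer"
    ENHANCER = "enhancer"
    PROMOTER = "promoter"


#: Labelling priority when one anchor carries several element classes.
LABEL_PRIORITY: tuple[ElementClass, ...] = (
    ElementClass.SILENCER,
    ElementClass.NON_SILENCER,
    ElementClass.ENHANCER,
    ElementClass.PROMOTER,
)


@dataclass(frozen=True)
class RegulatoryElement:
    interval: GenomicInterval
    element_class: ElementClass


@dataclass
class SignalTrack:
    """Sparse per-base signal: non-overlapping intervals, 0.0 elsewhere.

    Stored per chromosome as parallel sorted arrays of starts / ends / values
    so that window extraction is a pair of ``searchsorted`` calls.
    """

    track_name: str
    _chroms: dict = field(default_factory=dict, repr=False)

    def add_records(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(ends[:-1] > starts[1:]):
            i = int(np.argmax(ends[:-1] > starts[1:]))
            raise ValueError(
                f"overlapping records in track '{self.track_name}' on {chrom} "
                f"near [{starts[i]}, {ends[i]}) / [{starts[i + 1]}, {ends[i + 1]})"
            )
        self._chroms[chrom] = (starts, ends, values)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal value at a single base; uncovered bases read as 0.0."""
        entry = self._chroms.get(chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def values(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base values over ``interval`` as a float array of its length."""
        out = np.zeros(interval.length(), dtype=np.float64)
        entry = self._chroms.get(interval.chrom)
        if entry is None:
            return out
        starts, ends, values = entry
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        hi = int(np.searchsorted(starts, interval.end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a = max(int(s), interval.start) - interval.start
            b = min(int(e), interval.end) - interval.start
            if b > a:
                out[a:b] = v
        return out


def _split_line(line: str, path: str, lineno: int, min_cols: int) -> list[str]:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < min_cols:
        raise BedParseError(
            f"{path}:{lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(cols)}"
        )
    return cols


def _parse_interval(
    chrom: str, start: str, end: str, path: str, lineno: int
) -> GenomicInterval:
    try:
        s, e = int(start), int(end)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    try:
        return GenomicInterval(chrom, s, e)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_bedpe(path: str | Path, strict: bool = True) -> list[ChromatinLoop]:
    """Read chromatin loops from a BEDPE file (>= 6 columns).

    Column 8, when present and numeric, is taken as the PET support count.
    Inter-chromosomal pairs raise (``strict=True``) or are skipped with a
    warning (``strict=False``); loops connect anchors on one chromosome only.
    """
    path = Path(path)
    loops: list[ChromatinLoop] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = _split_line(line, str(path), lineno, 6)
            a = _parse_interval(cols[0], cols[1], cols[2], str(path), lineno)
            b = _parse_interval(cols[3], cols[4], cols[5], str(path), lineno)
            if a.chrom != b.chrom:
                if strict:
                    raise BedParseError(
                        f"{path}:{lineno}: inter-chromosomal pair "
                        f"{a.chrom}/{b.chrom} (loops must be intra-chromosomal)"
                    )
                warnings.warn(
                    f"{path}:{lineno}: skipping inter-chromosomal pair",
                    stacklevel=2,
                )
                continue
            support = 0
            if len(cols) >= 8:
                try:
                    support = int(float(cols[7]))
                except ValueError:
                    support = 0
            loops.append(ChromatinLoop(a, b, support))
    return loops


def write_bedpe(loops: Iterable[ChromatinLoop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchor_a.chrom}\t{lp.anchor_a.start}\t{lp.anchor_a.end}\t"
                f"{lp.anchor_b.chrom}\t{lp.anchor_b.start}\t{lp.anchor_b.end}\t"
                f".\t{lp.support}\n"
            )


def read_bed_elements(
    path: str | Path, class_map: str | ElementClass | None = None
) -> list[RegulatoryElement]:
    """Read regulatory elements from BED3+.

    The class token is taken from column 4 unless ``class_map`` forces a single
    class for the whole file.  Unknown tokens raise, listing the allowed ones.
    """
    path = Path(path)
    forced: ElementClass | None = None
    if class_map is not None:
        forced = ElementClass(class_map)
    allowed = ", ".join(c.value for c in ElementClass)
    elements: list[RegulatoryElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = _split_line(line, str(path), lineno, 3)
            iv = _parse_interval(cols[0], cols[1], cols[2], str(path), lineno)
            if forced is not None:
                cls = forced
            else:
                if len(cols) < 4:
                    raise BedParseError(
                        f"{path}:{lineno}: no class column and no class_map given"
                    )
                try:
                    cls = ElementClass(cols[3])
                except ValueError as exc:
                    raise BedParseError(
                        f"{path}:{lineno}: unknown element class '{cols[3]}' "
                        f"(allowed: {allowed})"
                    ) from exc
            elements.append(RegulatoryElement(iv, cls))
    return elements


def write_bed_elements(
    elements: Iterable[RegulatoryElement], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for el in elements:
            fh.write(
                f"{el.interval.chrom}\t{el.interval.start}\t{el.interval.end}\t"
                f"{el.element_class.value}\n"
            )


def read_bedgraph(path: str | Path, track_name: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a sparse :class:`SignalTrack`.

    Overlapping records are ambiguous signal and raise.
    """
    path = Path(path)
    name = track_name if track_name is not None else path.stem
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = _split_line(line, str(path), lineno, 4)
            iv = _parse_interval(cols[0], cols[1], cols[2], str(path), lineno)
            try:
                value = float(cols[3])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-numeric value '{cols[3]}'"
                ) from exc
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, value))
    track = SignalTrack(name)
    for chrom, recs in per_chrom.items():
        arr = np.array(recs, dtype=np.float64)
        track.add_records(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    return track


def read_bigwig(path: str | Path, track_name: str | None = None) -> SignalTrack:
    """Optional bigWig reader behind the same :class:`SignalTrack` contract."""
    try:
        import pyBigWig  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading bigWig requires the pyBigWig package") from exc
    path = Path(path)
    name = track_name if track_name is not None else path.stem
    track = SignalTrack(name)
    bw = pyBigWig.open(str(path))
    try:
        for chrom in bw.chroms():
            ivs = bw.intervals(chrom)
            if not ivs:
                continue
            arr = np.array(ivs, dtype=np.float64)
            track.add_records(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    finally:
        bw.close()
    return track


class GenomeSequence:
    """Indexed FASTA accessor returning uppercase sequence, 'N' for gaps.

    Out-of-range bases (an interval clipped at a chromosome edge) are returned
    as 'N' so downstream windows keep their nominal length.
    """

    def __init__(self, fasta_path: str | Path):
        self._fasta = Fasta(str(fasta_path), sequence_always_upper=True)

    def fetch(self, interval: GenomicInterval, pad_to: int | None = None) -> str:
        chrom = self._fasta[interval.chrom]
        end = min(interval.end, len(chrom))
        seq = str(chrom[interval.start : end]) if end > interval.start else ""
        seq = seq.replace("-", "N")
        target = pad_to if pad_to is not None else interval.length()
        if len(seq) < target:
            seq = seq + "N" * (target - len(seq))
        return seq

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def chroms(self) -> list[str]:
        return list(self._fasta.keys())


def load_tracks(
    track_paths: Mapping[str, str | Path | None],
) -> dict[str, SignalTrack]:
    """Load a name -> path mapping into SignalTracks; ``None`` paths give empty
    (all-zero) tracks, mirroring the zero-fill convention for missing assays."""
    tracks: dict[str, SignalTrack] = {}
    for name, p in track_paths.items():
        if p is None:
            tracks[name] = SignalTrack(name)
        else:
            suffix = str(p).lower()
            if suffix.endswith((".bw", ".bigwig")):
                tracks[name] = read_bigwig(p, name)
            else:
                tracks[name] = read_bedgraph(p, name)
    return tracks
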