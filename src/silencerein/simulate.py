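"""Fully synthetic inputs with planted, parameterized class structure.

The generator emulates the shapes of the real inputs — significant-loop
BEDPE whose anchors cluster and overlap, regulatory elements sitting on
anchors, class-conditional per-base assay tracks over Gaussian noise, and
random DNA — so that graph construction, featurization, training and
evaluation are all testable without any download.  Planted effects act on
the normalized 600-nt windows (exactly where featurization looks), so the
configured mean shifts are what the classifier can recover.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .features import TRACK_NAMES
from .genomic_io import GenomicInterval

__all__ = ["FixtureSpec", "generate_fixture", "DEFAULT_CLASS_EFFECTS"]

#: Class-conditional per-track mean shifts (in noise-SD units when
#: ``noise_sd=1``).  Silencer windows gain repressive / architectural marks,
#: enhancer and promoter windows gain active marks — a cartoon of the real
#: class-conditional epigenome.
DEFAULT_CLASS_EFFECTS: dict[str, dict[str, float]] = {
    "silencer": {"H3K27me3": 2.0, "H3K9me3": 2.0, "CTCF": 2.0},
    "enhancer": {"H3K27ac": 2.0, "H3K4me1": 1.0},
    "promoter": {"H3K4me3": 2.0, "POLR2A": 1.5},
    "non_silencer": {},
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic dataset; the defaults are the study
    conditions used throughout the suite (2 chromosomes x 2 Mb, 1500 loops,
    150 silencers, ~150 mixed negatives)."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_loops: int = 1500
    n_anchor_sites: int = 1200
    anchor_len_range: tuple[int, int] = (200, 900)
    overlap_rate: float = 0.15
    long_anchor_rate: float = 0.0
    n_silencers: int = 150
    n_non_silencers: int = 50
    n_enhancers: int = 50
    n_promoters: int = 500
    element_len_range: tuple[int, int] = (320, 900)
    class_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_EFFECTS.items()}
    )
    effect_scale: float = 1.0
    noise_sd: float = 1.0
    bin_size: int = 20
    motif_rate: float = 0.0
    motif: str = "CAGGCCTTGG"
    silencer_degree_boost: float = 0.0
    seed: int = 0

    def n_elements(self) -> int:
        return (
            self.n_silencers
            + self.n_non_silencers
            + self.n_enhancers
            + self.n_promoters
        )

    def validate(self) -> None:
        if self.n_elements() > self.n_anchor_sites:
            raise ValueError(
                f"infeasible spec: {self.n_elements()} elements but only "
                f"{self.n_anchor_sites} anchor sites"
            )
        for p in (self.overlap_rate, self.long_anchor_rate, self.motif_rate,
                  self.silencer_degree_boost):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if min(
            self.n_chroms, self.chrom_length, self.n_loops, self.n_anchor_sites
        ) <= 0:
            raise ValueError("counts must be positive")
        if self.element_len_range[0] <= 300:
            raise ValueError(
                "element lengths must exceed 300 nt so planted labels can "
                "clear the overlap threshold"
            )


_MARGIN = 3000
_MIN_CLEAN_GAP = 1300  # keeps element windows disjoint


def _place_sites(spec: FixtureSpec, rng: np.random.Generator):
    """Place anchor sites per chromosome.

    Element-bearing ("clean") sites are laid out with jittered even spacing so
    their 600-nt windows never overlap; the remaining sites are random, a
    fraction of them deliberately overlapping another non-clean site to
    exercise anchor merging.
    """
    chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    n_clean = spec.n_elements()
    clean_per_chrom = [n_clean // spec.n_chroms] * spec.n_chroms
    for i in range(n_clean % spec.n_chroms):
        clean_per_chrom[i] += 1
    n_extra = spec.n_anchor_sites - n_clean
    extra_per_chrom = [n_extra // spec.n_chroms] * spec.n_chroms
    for i in range(n_extra % spec.n_chroms):
        extra_per_chrom[i] += 1

    clean_sites: list[GenomicInterval] = []
    extra_sites: list[GenomicInterval] = []
    lo, hi = spec.anchor_len_range
    for ci, chrom in enumerate(chroms):
        nc = clean_per_chrom[ci]
        spacing = (spec.chrom_length - 2 * _MARGIN) / max(nc, 1)
        if spacing < _MIN_CLEAN_GAP:
            raise ValueError("chromosome too short for the requested element count")
        jitter = min(spacing / 4, 500)
        for i in range(nc):
            center = int(_MARGIN + (i + 0.5) * spacing + rng.uniform(-jitter, jitter))
            length = int(rng.integers(max(320, lo), max(hi, 321)))
            clean_sites.append(
                GenomicInterval(chrom, center - length // 2, center - length // 2 + length)
            )
        chrom_clean = [s for s in clean_sites if s.chrom == chrom]
        chrom_extras: list[GenomicInterval] = []
        occupied = sorted((s.start, s.end) for s in chrom_clean)

        def _collides(start: int, end: int) -> bool:
            i = bisect.bisect_right(occupied, (start, end))
            if i > 0 and occupied[i - 1][1] > start:
                return True
            return i < len(occupied) and occupied[i][0] < end

        for _ in range(extra_per_chrom[ci]):
            length = int(rng.integers(lo, hi + 1))
            if chrom_extras and rng.random() < spec.overlap_rate:
                # deliberately overlap an existing extra site (never an
                # element-bearing one) to exercise anchor merging
                base = chrom_extras[int(rng.integers(len(chrom_extras)))]
                shift = int(rng.integers(1, max(base.length(), 2)))
                start = base.start + shift
            else:
                # rejection-sample a non-overlapping placement so that
                # overlap_rate really is the overlap fraction
                for _try in range(200):
                    start = int(
                        rng.integers(_MARGIN, spec.chrom_length - _MARGIN - length)
                    )
                    if not _collides(start, start + length):
                        break
                else:
                    raise ValueError(
                        "could not place anchor sites without overlap; "
                        "chromosome too crowded"
                    )
                bisect.insort(occupied, (start, start + length))
            chrom_extras.append(GenomicInterval(chrom, start, start + length))
        extra_sites.extend(chrom_extras)
    return chroms, clean_sites, extra_sites


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a complete synthetic dataset under ``out_dir``.

    Writes ``genome.fa``, ``loops.bedpe``, ``elements.bed``,
    ``tracks/<name>.bedGraph`` for each of the 17 assay tracks, and
    ``truth.json`` recording every planted label and the spec.  Byte-identical
    for identical specs (seed included).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    (out / "tracks").mkdir(parents=True, exist_ok=True)

    chroms, clean_sites, extra_sites = _place_sites(spec, rng)
    classes = (
        ["silencer"] * spec.n_silencers
        + ["non_silencer"] * spec.n_non_silencers
        + ["enhancer"] * spec.n_enhancers
        + ["promoter"] * spec.n_promoters
    )
    perm = rng.permutation(len(classes))
    site_class = {i: classes[perm[i]] for i in range(len(clean_sites))}

    # elements: centred on their clean site so the normalized window re-centres
    # to the same midpoint
    elo, ehi = spec.element_len_range
    elements: list[tuple[GenomicInterval, str]] = []
    for i, site in enumerate(clean_sites):
        c = (site.start + site.end) // 2
        max_len = min(ehi, site.length())
        length = int(rng.integers(elo, max(max_len, elo) + 1))
        iv = GenomicInterval(site.chrom, c - length // 2, c - length // 2 + length)
        elements.append((iv, site_class[i]))

    # loops over the site pool
    sites = clean_sites + extra_sites
    by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for i, s in enumerate(sites):
        by_chrom[s.chrom].append(i)
    silencers_by_chrom = {
        c: [i for i in by_chrom[c] if i < len(clean_sites) and site_class[i] == "silencer"]
        for c in chroms
    }
    loop_lines = []
    for _ in range(spec.n_loops):
        chrom = chroms[int(rng.integers(len(chroms)))]
        pool = by_chrom[chrom]
        i = pool[int(rng.integers(len(pool)))]
        boost = silencers_by_chrom[chrom]
        if boost and rng.random() < spec.silencer_degree_boost:
            j = boost[int(rng.integers(len(boost)))]
        else:
            j = pool[int(rng.integers(len(pool)))]
        if i == j:
            j = pool[(pool.index(i) + 1) % len(pool)]
        a, b = sites[i], sites[j]
        if rng.random() < spec.long_anchor_rate:
            a = GenomicInterval(a.chrom, a.start, a.start + 1000 + int(rng.integers(500)))
        support = int(rng.poisson(5)) + 1
        loop_lines.append(
            f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t.\t{support}"
        )

    loops_path = out / "loops.bedpe"
    loops_path.write_text("\n".join(loop_lines) + "\n")

    elements_path = out / "elements.bed"
    with open(elements_path, "w") as fh:
        for iv, cls in elements:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\n")

    # tracks: element windows carry class-conditional mean shifts; every other
    # site window carries pure noise, so coverage does not betray labels
    windows: list[tuple[GenomicInterval, str]] = []
    for i, site in enumerate(clean_sites):
        c = (site.start + site.end) // 2
        windows.append((GenomicInterval(site.chrom, c - 300, c + 300), site_class[i]))
    for site in extra_sites:
        c = (site.start + site.end) // 2
        windows.append((GenomicInterval(site.chrom, c - 300, c + 300), "background"))

    track_paths: dict[str, Path] = {}
    for name in TRACK_NAMES:
        per_chrom_bins: dict[str, dict[int, float]] = {c: {} for c in chroms}
        for win, cls in windows:
            shift = (
                spec.class_effects.get(cls, {}).get(name, 0.0) * spec.effect_scale
            )
            bins = per_chrom_bins[win.chrom]
            # bins snap to a global grid so windows can never half-overlap
            first = (win.start // spec.bin_size) * spec.bin_size
            for b in range(first, win.end, spec.bin_size):
                if b in bins:
                    continue
                bins[b] = shift + rng.normal(0.0, spec.noise_sd)
        path = out / "tracks" / f"{name}.bedGraph"
        with open(path, "w") as fh:
            for chrom in chroms:
                for b in sorted(per_chrom_bins[chrom]):
                    e = b + spec.bin_size
                    fh.write(f"{chrom}\t{b}\t{e}\t{per_chrom_bins[chrom][b]:.4f}\n")
        track_paths[name] = path

    # genome: random DNA, optional motif planted in silencer windows
    fasta_path = out / "genome.fa"
    bases = np.array(list("ACGT"))
    with open(fasta_path, "w") as fh:
        for chrom in chroms:
            seq = bases[rng.integers(0, 4, size=spec.chrom_length)]
            for win, cls in windows:
                if (
                    win.chrom == chrom
                    and cls == "silencer"
                    and spec.motif_rate > 0
                    and rng.random() < spec.motif_rate
                ):
                    off = int(rng.integers(0, 600 - len(spec.motif)))
                    seq[win.start + off : win.start + off + len(spec.motif)] = list(
                        spec.motif
                    )
            fh.write(f">{chrom}\n")
            text = "".join(seq)
            for i in range(0, len(text), 80):
                fh.write(text[i : i + 80] + "\n")

    truth = {
        "spec": asdict(spec),
        "elements": [
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "class": cls}
            for iv, cls in elements
        ],
        "class_counts": {
            "silencer": spec.n_silencers,
            "non_silencer": spec.n_non_silencers,
            "enhancer": spec.n_enhancers,
            "promoter": spec.n_promoters,
        },
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))

    return {
        "fasta": fasta_path,
        "loops": loops_path,
        "elements": elements_path,
        "tracks": {n: p for n, p in track_paths.items()},
        "truth": truth_path,
    }
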