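"""Linear sequence/signal features and the per-node topology descriptor.

Each node window (600 nt, re-centred by the element normalization rule)
yields a 21 x 600 matrix: 4 one-hot DNA rows followed by 17 per-base assay
signal rows in the fixed :data:`TRACK_NAMES` order, flattening to 12 600
values.  The graph branch consumes a 10-dimensional structural descriptor
per node instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genomic_io import GenomicInterval, GenomeSequence, SignalTrack
from .network import REINGraph, normalize_element

__all__ = [
    "TRACK_NAMES",
    "DESCRIPTOR_TRACKS",
    "WINDOW_SIZE",
    "LinearFeatures",
    "one_hot_encode",
    "extract_signal_window",
    "build_linear_features",
    "build_node_descriptor",
]

#: The 17 assay tracks (12 histone modifications + 5 TF-binding signals),
#: in the fixed channel order used throughout the package.
TRACK_NAMES: tuple[str, ...] = (
    "H3K9me3",
    "H3K27me3",
    "H3K27ac",
    "H3K36me3",
    "H3K4me3",
    "H3K4me1",
    "H3K79me2",
    "H2AFZ",
    "H4K20me1",
    "H3K4me2",
    "H3K9ac",
    "H3K9me1",
    "RAD21",
    "POLR2A",
    "SMC3",
    "ZNF143",
    "CTCF",
)

#: Tracks whose window means enter the 10-d node descriptor (7 of them).
DESCRIPTOR_TRACKS: tuple[str, ...] = (
    "CTCF",
    "POLR2A",
    "RAD21",
    "SMC3",
    "H3K27me3",
    "H3K27ac",
    "H3K4me3",
)

WINDOW_SIZE = 600

_BASE_ROW = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass
class LinearFeatures:
    """21 x 600 per-node linear feature matrix (one-hot block then signals)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        if self.matrix.shape != (4 + len(TRACK_NAMES), WINDOW_SIZE):
            raise ValueError(f"expected shape (21, 600), got {self.matrix.shape}")

    def flatten(self) -> np.ndarray:
        return self.matrix.ravel()

    @property
    def one_hot(self) -> np.ndarray:
        return self.matrix[:4]

    @property
    def signals(self) -> np.ndarray:
        return self.matrix[4:]


def one_hot_encode(sequence: str) -> np.ndarray:
    """One-hot encode DNA as a 4 x L 0/1 matrix.

    Row order is A, T, C, G; the undetermined base N encodes as an all-zero
    column.  Case-insensitive; any other symbol raises, naming it and its
    position.
    """
    seq = sequence.upper()
    out = np.zeros((4, len(seq)), dtype=np.float64)
    for i, base in enumerate(seq):
        if base == "N":
            continue
        row = _BASE_ROW.get(base)
        if row is None:
            raise ValueError(f"invalid base '{base}' at position {i}")
        out[row, i] = 1.0
    return out


def extract_signal_window(
    track: SignalTrack, interval: GenomicInterval, window: int = WINDOW_SIZE
) -> np.ndarray:
    """Per-base signal over a window interval; uncovered bases are 0.0."""
    if interval.length() != window:
        raise ValueError(
            f"window must be exactly {window} nt, got {interval.length()}"
        )
    return track.values(interval)


def build_linear_features(
    window: GenomicInterval,
    fasta: GenomeSequence,
    tracks: Mapping[str, SignalTrack],
) -> LinearFeatures:
    """Assemble the 21 x 600 feature matrix for one node window.

    ``tracks`` must cover every name in :data:`TRACK_NAMES` (a missing assay
    may be an empty track, which reads as zeros, but the name must be
    present).  Windows clipped at a chromosome edge are padded with N / 0.
    """
    missing = [name for name in TRACK_NAMES if name not in tracks]
    if missing:
        raise KeyError(
            f"missing track(s) {missing}; expected all of {list(TRACK_NAMES)}"
        )
    n_signal = len(TRACK_NAMES)
    mat = np.zeros((4 + n_signal, WINDOW_SIZE), dtype=np.float64)
    seq = fasta.fetch(window, pad_to=WINDOW_SIZE)
    mat[:4] = one_hot_encode(seq[:WINDOW_SIZE])
    length = window.length()
    for j, name in enumerate(TRACK_NAMES):
        vals = tracks[name].values(window)
        mat[4 + j, :length] = vals[:WINDOW_SIZE]
    return LinearFeatures(mat)


def node_window(graph: REINGraph, node: int) -> GenomicInterval:
    """The 600-nt feature window of a node: its anchor re-centred to 600 nt."""
    return normalize_element(graph.nodes[node])


def build_node_descriptor(
    graph: REINGraph,
    node: int,
    tracks: Mapping[str, SignalTrack],
    descriptor_tracks: Sequence[str] = DESCRIPTOR_TRACKS,
) -> np.ndarray:
    """The 10-d structural descriptor feeding the graph branch.

    ``[log1p(degree), self_loop_flag, log1p(anchor length),
    mean window signal of the 7 descriptor tracks]`` — all quantities
    available for unlabeled nodes, so no label leakage.
    """
    iv = graph.nodes[node]
    window = node_window(graph, node)
    vec = np.zeros(3 + len(descriptor_tracks), dtype=np.float64)
    vec[0] = np.log1p(graph.degree(node))
    vec[1] = 1.0 if graph.has_self_loop(node) else 0.0
    vec[2] = np.log1p(iv.length())
    for j, name in enumerate(descriptor_tracks):
        track = tracks.get(name)
        if track is None:
            continue
        vals = track.values(window)
        vec[3 + j] = float(vals.mean()) if vals.size else 0.0
    return vec
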