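"""Prediction-window geometry shared by every stage of the pipeline.

The contact-map predictor consumes a fixed-length DNA sequence of
``L_IN`` = 2**20 = 1,048,576 bp and emits a map over the central
``N_BINS`` = 448 bins of ``BIN_SIZE`` = 2,048 bp (917,504 bp visible);
the outer 32 bins on each side are cropped margin.
"""

from __future__ import annotations

from dataclasses import dataclass

L_IN: int = 1 << 20          # model input length, bp
N_BINS: int = 448            # visible bins per side of the map
BIN_SIZE: int = 2048         # bp per visible bin
VISIBLE: int = N_BINS * BIN_SIZE          # 917,504 bp
MARGIN: int = (L_IN - VISIBLE) // 2       # 65,536 bp cropped per side


class ContigTooShortError(ValueError):
    """Raised when a contig cannot host a full prediction window."""


@dataclass(frozen=True)
class PredictionWindow:
    """A model input window anchored on the genome.

    ``input_start``/``input_end`` span ``L_IN`` bp; the visible span (the
    region the contact map covers) is the central ``VISIBLE`` bp.
    Coordinates are 0-based half-open.
    """

    chrom: str
    input_start: int
    input_end: int

    def __post_init__(self) -> None:
        if self.input_end - self.input_start != L_IN:
            raise ValueError(
                f"window span {self.input_end - self.input_start} != {L_IN}"
            )
        if self.input_start < 0:
            raise ValueError("window extends past contig start")

    @property
    def visible_start(self) -> int:
        return self.input_start + MARGIN

    @property
    def visible_end(self) -> int:
        return self.input_end - MARGIN

    @property
    def bin_size(self) -> int:
        return BIN_SIZE

    @property
    def n_bins(self) -> int:
        return N_BINS

    def bin_of(self, pos: int) -> int | None:
        """Visible bin index containing genomic position ``pos``, or None."""
        if not self.visible_start <= pos < self.visible_end:
            return None
        return (pos - self.visible_start) // BIN_SIZE

    def bins_overlapping(self, start: int, end: int) -> set[int]:
        """Visible bins intersecting the half-open genomic interval."""
        lo = max(start, self.visible_start)
        hi = min(end, self.visible_end)
        if lo >= hi:
            return set()
        first = (lo - self.visible_start) // BIN_SIZE
        last = (hi - 1 - self.visible_start) // BIN_SIZE
        return set(range(first, last + 1))

    def bin_interval(self, i: int) -> tuple[int, int]:
        """Genomic (start, end) of visible bin ``i``."""
        s = self.visible_start + i * BIN_SIZE
        return s, s + BIN_SIZE


def centered_window(chrom: str, center: int, contig_length: int) -> PredictionWindow:
    """Window centered on ``center``, clamped to the contig.

    Clamping shifts the window (and therefore the center) rather than
    truncating it; a contig shorter than ``L_IN`` cannot host a window.
    """
    if contig_length < L_IN:
        raise ContigTooShortError(
            f"contig {chrom} ({contig_length} bp) shorter than {L_IN} bp"
        )
    start = center - L_IN // 2
    start = min(max(start, 0), contig_length - L_IN)
    return PredictionWindow(chrom, start, start + L_IN)
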