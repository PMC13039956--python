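"""Length-matched REF/ALT sequence construction for in-silico mutagenesis.

For every variant a prediction window is centered on the SV midpoint and a
pair of equal-length sequences is built: the reference window and an
alternate carrying the variant.  Length changes (DEL/DUP/INS) are
compensated by symmetric flank extension or trimming, so both sequences
are always exactly ``L_IN`` bp.  Each variant is additionally scored
under three augmentations (window shifted by -1/+1 bp, reverse
complement).  Breakends get two half-window fusion pairs, one per
breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .geometry import (
    L_IN,
    N_BINS,
    ContigTooShortError,
    PredictionWindow,
    centered_window,
)
from .predictor import revcomp
from .sv_io import StructuralVariant

AUGMENTATIONS: tuple[str, ...] = ("none", "shift_minus1", "shift_plus1", "revcomp")

_HALF = L_IN // 2
_JUNCTION_BINS = frozenset({N_BINS // 2 - 1, N_BINS // 2})  # bins flanking center
_LEFT_HALF = frozenset(range(N_BINS // 2))
_RIGHT_HALF = frozenset(range(N_BINS // 2, N_BINS))


class FlankExtensionError(ValueError):
    """Flank extension or window shift would run past the contig."""


@dataclass
class SequencePair:
    """One REF/ALT sequence pair ready for prediction.

    ``mask_bins`` are in *map* coordinates (mirrored for the revcomp
    augmentation) and cover the SV span plus, for length-changing variants,
    the ALT junction bin; for BND pairs they additionally blank out the
    half of the map belonging to the partner breakpoint.
    """

    ref_seq: str
    alt_seq: str
    window: PredictionWindow
    mask_bins: set[int]
    augmentation: str = "none"
    flags: set[str] = dc_field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.ref_seq) != L_IN or len(self.alt_seq) != L_IN:
            raise ValueError("ref and alt sequences must both be L_IN bp")


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract genome[chrom][start:end) as a string.

    Accepts a pyfaidx.Fasta or any mapping of contig name to string; the
    genome is expected to hold uppercase sequence (open FASTA files with
    ``pyfaidx.Fasta(path, sequence_always_upper=True)``).  Raises
    :class:`FlankExtensionError` when the span leaves the contig.
    """
    n = contig_length(genome, chrom)
    if start < 0 or end > n:
        raise FlankExtensionError(
            f"span {chrom}:{start}-{end} outside contig of length {n}"
        )
    seg = genome[chrom][start:end]
    return seg if isinstance(seg, str) else str(seg)


def contig_length(genome, chrom: str) -> int:
    try:
        return len(genome[chrom])
    except KeyError as exc:
        raise KeyError(f"contig {chrom!r} not in genome") from exc


def build_window(sv: StructuralVariant, genome) -> PredictionWindow:
    """Prediction window centered on the SV midpoint, clamped to the contig."""
    center = (sv.start + sv.end) // 2
    return centered_window(sv.chrom, center, contig_length(genome, sv.chrom))


def _shifted(window: PredictionWindow, shift: int, contig_len: int) -> PredictionWindow:
    start = window.input_start + shift
    if start < 0 or start + L_IN > contig_len:
        raise FlankExtensionError("augmentation shift leaves the contig")
    return PredictionWindow(window.chrom, start, start + L_IN)


def _n_fraction_flags(ref: str, cap: float) -> set[str]:
    if ref.count("N") / len(ref) > cap:
        return {"high_N"}
    return set()


def build_sequence_pair(
    sv: StructuralVariant,
    genome,
    augmentation: str = "none",
    n_cap: float = 0.05,
) -> SequencePair:
    """REF/ALT pair for a non-BND variant under one augmentation.

    DEL: the deleted span is removed and the window flanks are extended by
    ceil(l/2) left / floor(l/2) right to restore the input length.  DUP: a
    tandem copy is inserted after the span and the two window ends trimmed
    symmetrically.  INS: the inserted sequence is placed at ``start`` with
    symmetric trimming.  INV: in-place reverse complement (no length
    change).
    """
    if sv.svtype == "BND":
        raise ValueError("use build_bnd_pairs for breakends")
    if augmentation not in AUGMENTATIONS:
        raise ValueError(f"unknown augmentation {augmentation!r}")
    length = sv.end - sv.start if sv.svtype != "INS" else len(sv.inserted_seq)
    if sv.svtype != "INS" and length > 500_000:
        raise ValueError("variant longer than 500 kb cannot be scored")

    clen = contig_length(genome, sv.chrom)
    window = build_window(sv, genome)
    flags: set[str] = set()
    if window.input_start != (sv.start + sv.end) // 2 - _HALF:
        flags.add("clamped_window")
    if augmentation == "shift_minus1":
        window = _shifted(window, -1, clen)
    elif augmentation == "shift_plus1":
        window = _shifted(window, +1, clen)

    ws, we = window.input_start, window.input_end
    ref = fetch(genome, sv.chrom, ws, we)
    left_ext = (length + 1) // 2
    right_ext = length // 2

    if sv.svtype == "DEL":
        alt = fetch(genome, sv.chrom, ws - left_ext, sv.start) + fetch(
            genome, sv.chrom, sv.end, we + right_ext
        )
    elif sv.svtype == "DUP":
        full = (
            fetch(genome, sv.chrom, ws, sv.end)
            + fetch(genome, sv.chrom, sv.start, sv.end)
            + fetch(genome, sv.chrom, sv.end, we)
        )
        alt = full[left_ext : left_ext + L_IN]
    elif sv.svtype == "INS":
        full = (
            fetch(genome, sv.chrom, ws, sv.start)
            + sv.inserted_seq.upper()
            + fetch(genome, sv.chrom, sv.start, we)
        )
        alt = full[left_ext : left_ext + L_IN]
    else:  # INV
        rel_s, rel_e = sv.start - ws, sv.end - ws
        if rel_s < 0 or rel_e > L_IN:
            raise FlankExtensionError("inversion extends past the input window")
        alt = ref[:rel_s] + revcomp(ref[rel_s:rel_e]) + ref[rel_e:]
    if len(alt) != L_IN:
        raise FlankExtensionError("alternate sequence could not be length-matched")

    mask = window.bins_overlapping(sv.start, sv.end)
    if sv.svtype in ("DEL", "INS"):
        j = window.bin_of(sv.start)
        if j is not None:
            mask.add(j)
    flags |= _n_fraction_flags(ref, n_cap)

    if augmentation == "revcomp":
        ref, alt = revcomp(ref), revcomp(alt)
        mask = {N_BINS - 1 - b for b in mask}
    return SequencePair(ref, alt, window, mask, augmentation, flags)


def _bnd_arms(sv: StructuralVariant, genome, shift: int):
    """Fusion sequence and per-breakpoint geometry for a breakend.

    Returns ``(fusion, a_side, b_side, ref_a_start, ref_b_start)`` where the
    sides are "left"/"right" halves of the map occupied by each breakpoint's
    own sequence.  The fusion is ``L_IN/2`` bp ending at breakpoint A joined
    to ``L_IN/2`` bp from breakpoint B, with the mate arm
    reverse-complemented when the junction joins like strands.
    """
    a = sv.start + shift
    b = sv.mate_pos + shift
    orient = sv.junction_orientation
    A, B = sv.chrom, sv.mate_chrom

    if orient in ("t[p[", "t]p]"):
        a_arm = fetch(genome, A, a + 1 - _HALF, a + 1)  # left arm, ends at a
        a_side = "left"
        ref_a_start = a + 1 - _HALF
    else:
        a_arm = fetch(genome, A, a, a + _HALF)  # right arm, starts at a
        a_side = "right"
        ref_a_start = a - _HALF

    if orient == "t[p[":
        b_arm = fetch(genome, B, b, b + _HALF)
        fusion = a_arm + b_arm
        b_side, ref_b_start = "right", b - _HALF
    elif orient == "t]p]":
        b_arm = revcomp(fetch(genome, B, b + 1 - _HALF, b + 1))
        fusion = a_arm + b_arm
        b_side, ref_b_start = "left", b + 1 - _HALF
    elif orient == "]p]t":
        b_arm = fetch(genome, B, b + 1 - _HALF, b + 1)
        fusion = b_arm + a_arm
        b_side, ref_b_start = "left", b + 1 - _HALF
    else:  # "[p[t"
        b_arm = revcomp(fetch(genome, B, b, b + _HALF))
        fusion = b_arm + a_arm
        b_side, ref_b_start = "right", b - _HALF
    return fusion, a_side, b_side, ref_a_start, ref_b_start


def build_bnd_pairs(
    sv: StructuralVariant,
    genome,
    augmentation: str = "none",
    n_cap: float = 0.05,
) -> list[SequencePair]:
    """Two REF/ALT pairs for a breakend, one per breakpoint.

    Each pair compares the fusion sequence against the reference window
    centered on that breakpoint; the half of the map contributed by the
    partner locus is masked, so only same-side contacts are scored,
    together with the two bins flanking the junction.
    """
    if sv.svtype != "BND":
        raise ValueError("build_bnd_pairs requires a BND variant")
    if not sv.mate_resolved or sv.mate_chrom is None:
        raise ValueError("unresolved mate: cannot build fusion sequence")
    if augmentation not in AUGMENTATIONS:
        raise ValueError(f"unknown augmentation {augmentation!r}")

    shift = {"shift_minus1": -1, "shift_plus1": +1}.get(augmentation, 0)
    fusion, a_side, b_side, ref_a_start, ref_b_start = _bnd_arms(sv, genome, shift)

    pairs = []
    for chrom, side, ref_start, needs_rc in (
        (sv.chrom, a_side, ref_a_start, False),
        (sv.mate_chrom, b_side, ref_b_start, _mate_arm_flipped(sv)),
    ):
        ref = fetch(genome, chrom, ref_start, ref_start + L_IN)
        alt = revcomp(fusion) if needs_rc else fusion
        window = PredictionWindow(chrom, ref_start, ref_start + L_IN)
        other = _RIGHT_HALF if side == "left" else _LEFT_HALF
        mask = set(_JUNCTION_BINS) | set(other)
        flags = _n_fraction_flags(ref, n_cap)
        if augmentation == "revcomp":
            ref, alt = revcomp(ref), revcomp(alt)
            mask = {N_BINS - 1 - m for m in mask}
        pairs.append(SequencePair(ref, alt, window, mask, augmentation, flags))
    return pairs


def _mate_arm_flipped(sv: StructuralVariant) -> bool:
    """True when the mate arm enters the fusion reverse-complemented."""
    return sv.junction_orientation in ("t]p]", "[p[t")
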