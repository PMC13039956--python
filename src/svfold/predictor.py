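"""Contact-map predictors.

Defines the predictor contract (a fixed-length DNA sequence in, a
448x448 normalized contact map out) and a deterministic mechanistic toy
predictor whose folding grammar is motif-encoded: boundary motifs
partition the visible window into self-interacting blocks (TADs) and
convergent anchor-motif pairs add loop contacts.  The toy model makes
the whole pipeline exercisable and testable without trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BIN_SIZE, L_IN, MARGIN, N_BINS, VISIBLE, PredictionWindow

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PredictorUnavailableError(RuntimeError):
    """Raised by adapters whose backing model is not installed."""


@dataclass
class ContactMap:
    """A 448x448 symmetric matrix of normalized (log-scale) contact scores.

    Cells with ``|i - j| < 2`` (the near-diagonal band) are set to zero and
    excluded from all scoring.
    """

    values: np.ndarray
    window: PredictionWindow | None = None

    DIAG_BAND: int = 2

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_BINS, N_BINS):
            raise ValueError(f"contact map must be {N_BINS}x{N_BINS}, got {v.shape}")
        self.values = v

    def check_symmetric(self, atol: float = 0.0) -> bool:
        return np.allclose(self.values, self.values.T, atol=atol, rtol=0.0)


class Predictor:
    """Abstract contact-map predictor.

    Implementations must be deterministic: the same input sequence yields a
    bitwise-identical map.
    """

    def predict(self, seq: str, window: PredictionWindow | None = None) -> ContactMap:
        raise NotImplementedError

    @staticmethod
    def _check_length(seq: str) -> None:
        if len(seq) != L_IN:
            raise ValueError(f"predictor input must be {L_IN} bp, got {len(seq)}")


@dataclass
class ToyPredictorParams:
    """Parameters of the mechanistic toy predictor.

    ``boundary_motif`` instances delimit self-interacting blocks;
    ``anchor_motif`` instances in convergent orientation (forward hit
    upstream of a reverse-strand hit) add a loop bonus.  ``gamma`` sets the
    log10 distance decay, ``c_in``/``c_out`` the within/between-block
    contact levels.  All values are on the predictor's arbitrary log scale;
    downstream scores are REF-ALT contrasts, so the absolute scale cancels.
    """

    boundary_motif: str = "GCCACCAGGTGG"
    anchor_motif: str = "TTACGCGTAACC"
    gamma: float = 1.0
    c_in: float = 0.6
    c_out: float = 0.0
    loop_bonus: float = 0.8
    loop_max_dist: int = 200

    def __post_init__(self) -> None:
        for name in ("boundary_motif", "anchor_motif"):
            motif = getattr(self, name)
            if len(motif) < 6:
                raise ValueError(f"{name} too short")
            if motif == revcomp(motif):
                raise ValueError(f"{name} must not be palindromic")
        pool = {
            self.boundary_motif,
            revcomp(self.boundary_motif),
            self.anchor_motif,
            revcomp(self.anchor_motif),
        }
        if len(pool) != 4:
            raise ValueError("boundary and anchor motifs must be strand-disjoint")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


def _find_all(haystack: bytes, needle: bytes) -> list[int]:
    """All (possibly overlapping) match start offsets of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


_scan_buffers: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _scan_hits(arr: np.ndarray, motif: str) -> np.ndarray:
    """Match start offsets of ``motif`` in a uint8 sequence view."""
    return _scan_many(arr, [motif])[0]


def _scan_many(arr: np.ndarray, motifs: list[str]) -> list[np.ndarray]:
    """Exhaustive multi-pattern scan (vectorized candidate prefilter).

    For each motif, candidate positions matching three probe bases are
    collected in one shared pass, then verified base-by-base; the result
    is identical to a naive full scan.
    """
    widths = {len(m) for m in motifs}
    if len(widths) != 1:
        return [_scan_many(arr, [m])[0] for m in motifs]
    w = widths.pop()
    n = arr.size - w + 1
    if n <= 0:
        return [np.empty(0, dtype=np.intp) for _ in motifs]
    bufs = _scan_buffers.get(n)
    if bufs is None:
        bufs = (np.empty(n, dtype=bool), np.empty(n, dtype=bool))
        _scan_buffers[n] = bufs
    cand, tmp = bufs
    probe = (0, w // 2, w - 1)
    encoded = [np.frombuffer(m.encode(), dtype=np.uint8) for m in motifs]

    out = []
    for m in encoded:
        np.equal(arr[probe[0] : probe[0] + n], m[probe[0]], out=cand)
        for p in probe[1:]:
            np.equal(arr[p : p + n], m[p], out=tmp)
            cand &= tmp
        starts = np.flatnonzero(cand)
        if starts.size:
            ok = np.ones(starts.size, dtype=bool)
            for k in range(w):
                if k in probe:
                    continue
                ok &= arr[starts + k] == m[k]
            starts = starts[ok]
        out.append(starts)
    return out


def _bins_from_hits(starts: np.ndarray, w: int) -> np.ndarray:
    """Boolean mask over bins touched by any motif match.

    A match is credited to every bin its span overlaps, which makes the
    bin assignment exactly mirror-symmetric under reverse complement.
    """
    mask = np.zeros(N_BINS, dtype=bool)
    for s in starts:
        mask[s // BIN_SIZE : (s + w - 1) // BIN_SIZE + 1] = True
    return mask


def _hit_bins(visible: np.ndarray, motif: str) -> np.ndarray:
    return _bins_from_hits(_scan_hits(visible, motif), len(motif))


# distance-decay lookups shared by every toy prediction
_DIST = np.abs(np.subtract.outer(np.arange(N_BINS), np.arange(N_BINS)))
_LOG_DECAY = np.log10(_DIST + 1.0)
_DIAG_MASK = _DIST < ContactMap.DIAG_BAND
_UPPER = np.triu(np.ones((N_BINS, N_BINS), dtype=bool), k=1)

_decay_cache: dict[float, np.ndarray] = {}


def _decay(gamma: float) -> np.ndarray:
    base = _decay_cache.get(gamma)
    if base is None:
        base = -gamma * _LOG_DECAY
        _decay_cache[gamma] = base
    return base


@dataclass
class ToyPredictor(Predictor):
    """Deterministic motif-grammar contact-map predictor.

    The visible window is scanned on both strands for the boundary motif;
    bins containing at least one hit are boundary bins, and maximal runs of
    bins between boundary bins form blocks.  The map is a log10 distance
    decay plus a within-block elevation, plus a loop bonus for convergent
    anchor pairs within ``loop_max_dist`` bins.
    """

    params: ToyPredictorParams = field(default_factory=ToyPredictorParams)

    def predict(self, seq: str, window: PredictionWindow | None = None) -> ContactMap:
        """Predict the contact map (sequence must be uppercase A/C/G/T/N)."""
        self._check_length(seq)
        p = self.params
        visible = np.frombuffer(
            seq[MARGIN : MARGIN + VISIBLE].encode(), dtype=np.uint8
        )

        motifs = [
            p.boundary_motif,
            revcomp(p.boundary_motif),
            p.anchor_motif,
            revcomp(p.anchor_motif),
        ]
        b_fwd, b_rev, a_fwd, a_rev = _scan_many(visible, motifs)
        w = len(p.boundary_motif)
        boundary = _bins_from_hits(b_fwd, w) | _bins_from_hits(b_rev, w)
        wa = len(p.anchor_motif)
        anchor_fwd = _bins_from_hits(a_fwd, wa)
        anchor_rev = _bins_from_hits(a_rev, wa)

        values = _decay(p.gamma).copy()
        if p.c_out != 0.0:
            values += p.c_out
        if boundary.any():
            # block id per bin: increments at every boundary bin; boundary
            # bins belong to no block (id -1) so they never share a block.
            # A window without any boundary has no TAD structure at all
            # (pure decay), not one giant block.
            block = np.cumsum(boundary)
            block = np.where(boundary, -1, block)
            same_block = (block[:, None] == block[None, :]) & (block[:, None] >= 0)
            np.add(values, p.c_in - p.c_out, out=values, where=same_block)

        if anchor_fwd.any() and anchor_rev.any():
            loop = (
                anchor_fwd[:, None]
                & anchor_rev[None, :]
                & _UPPER
                & (_DIST <= p.loop_max_dist)
            )
            loop = loop | loop.T
            values[loop] += p.loop_bonus

        values[_DIAG_MASK] = 0.0
        return ContactMap(values, window=window)


class AkitaAdapter(Predictor):
    """Adapter stub for a trained contact-map model.

    The pipeline is predictor-agnostic; plugging in a trained model means
    implementing :meth:`predict` around its inference call.  This stub
    documents the contract and fails loudly when no model is supplied.
    """

    def __init__(self, model=None):
        self.model = model

    def predict(self, seq: str, window: PredictionWindow | None = None) -> ContactMap:
        self._check_length(seq)
        if self.model is None:
            raise PredictorUnavailableError(
                "predictor_unavailable: no trained model was supplied"
            )
        values = np.asarray(self.model(seq), dtype=float)
        return ContactMap(values, window=window)


def get_predictor(name: str, **kwargs) -> Predictor:
    """Predictor registry used by the pipeline config (toy | akita_adapter)."""
    if name == "toy":
        params = kwargs.pop("params", None) or ToyPredictorParams(**kwargs)
        return ToyPredictor(params)
    if name == "akita_adapter":
        return AkitaAdapter(**kwargs)
    raise ValueError(f"unknown predictor {name!r}")
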