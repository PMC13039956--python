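"""REF-vs-ALT contact-map comparison and per-variant disruption scoring.

Two headline scores quantify how much a variant perturbs predicted
contacts: MSE (mean squared difference) and CORR (1 - Pearson r), both
computed over upper-triangle cells at least two bins off the diagonal
with the variant's own bins masked out, so scores reflect changes to
contacts *outside* the SV.  Each variant is scored under four input
augmentations (none, -1 bp shift, +1 bp shift, reverse complement) and
the per-augmentation scores are aggregated by median (or mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .geometry import N_BINS, PredictionWindow
from .mutagenesis import (
    AUGMENTATIONS,
    SequencePair,
    build_bnd_pairs,
    build_sequence_pair,
)
from .predictor import ContactMap, Predictor
from .sv_io import StructuralVariant

log = logging.getLogger(__name__)

_DIST = np.abs(np.subtract.outer(np.arange(N_BINS), np.arange(N_BINS)))
_UPPER_OFFDIAG = np.triu(_DIST >= ContactMap.DIAG_BAND)


class MapComparison(NamedTuple):
    mse: float
    corr: float
    zero_variance: bool


def _evaluation_mask(mask_bins: Iterable[int]) -> np.ndarray:
    keep = np.ones(N_BINS, dtype=bool)
    idx = list(mask_bins)
    if idx:
        keep[idx] = False
    return _UPPER_OFFDIAG & keep[:, None] & keep[None, :]


def compare_maps(
    ref: ContactMap, alt: ContactMap, mask_bins: Iterable[int] = ()
) -> MapComparison:
    """Overall MSE and CORR (1 - Pearson r) between two contact maps.

    The evaluation set is the upper-triangle cells with ``|i-j| >= 2`` and
    neither index in ``mask_bins``.  If either map has zero variance over
    that set, CORR is undefined; it is reported as 0 with the
    ``zero_variance`` flag set.
    """
    mask = _evaluation_mask(mask_bins)
    if not mask.any():
        raise ValueError("evaluation set is empty")
    a = ref.values[mask]
    b = alt.values[mask]
    mse = float(np.mean((a - b) ** 2))
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return MapComparison(mse, 0.0, True)
    r = float(np.corrcoef(a, b)[0, 1])
    return MapComparison(mse, 1.0 - r, False)


def disruption_track(
    ref: ContactMap, alt: ContactMap, mask_bins: Iterable[int] = ()
) -> np.ndarray:
    """Per-bin disruption: mean squared REF-ALT difference along each row.

    ``track[i]`` is the mean of ``(ref[i,j] - alt[i,j])**2`` over unmasked
    ``j`` with ``|i-j| >= 2``; masked bins get 0.
    """
    keep = np.ones(N_BINS, dtype=bool)
    idx = list(mask_bins)
    if idx:
        keep[idx] = False
    valid = (_DIST >= ContactMap.DIAG_BAND) & keep[None, :]
    if not (valid & keep[:, None]).any():
        raise ValueError("evaluation set is empty")
    sq = (ref.values - alt.values) ** 2
    counts = valid.sum(axis=1)
    track = np.where(counts > 0, (sq * valid).sum(axis=1) / np.maximum(counts, 1), 0.0)
    track[~keep] = 0.0
    return track


@dataclass
class DisruptionResult:
    """Disruption scores for one variant.

    ``per_augmentation`` maps augmentation name to (mse, corr); the
    aggregate fields are the median and mean of the four augmentation
    scores.  ``tracks`` holds one 448-bin MSE track per prediction window
    (one window for non-BND variants, two for BNDs), averaged across
    augmentations and aligned to genomic orientation.
    """

    sv_id: str
    svtype: str
    sample_id: str = ""
    per_augmentation: dict[str, MapComparison] = field(default_factory=dict)
    mse_median: float = 0.0
    mse_mean: float = 0.0
    corr_median: float = 0.0
    corr_mean: float = 0.0
    tracks: list[np.ndarray] = field(default_factory=list)
    windows: list[PredictionWindow] = field(default_factory=list)
    masked_bins: list[set[int]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def score(self, metric: str = "mse", aggregate: str = "median") -> float:
        return getattr(self, f"{metric}_{aggregate}")


def _unflip(track: np.ndarray, pair: SequencePair) -> np.ndarray:
    """Return the track in genomic orientation (revcomp maps are mirrored)."""
    return track[::-1] if pair.augmentation == "revcomp" else track


def _score_pair(pair: SequencePair, predictor: Predictor, compute_track: bool = True):
    """Predict both maps and compute comparison (+ optional track) in one pass."""
    ref_map = predictor.predict(pair.ref_seq, window=pair.window)
    alt_map = predictor.predict(pair.alt_seq, window=pair.window)

    keep = np.ones(N_BINS, dtype=bool)
    idx = list(pair.mask_bins)
    if idx:
        keep[idx] = False
    sq = (ref_map.values - alt_map.values) ** 2
    eval_mask = _UPPER_OFFDIAG & keep[:, None] & keep[None, :]
    if not eval_mask.any():
        raise ValueError("evaluation set is empty")
    a = ref_map.values[eval_mask]
    b = alt_map.values[eval_mask]
    mse = float(sq[eval_mask].mean())
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        cmp_ = MapComparison(mse, 0.0, True)
    else:
        cov = float(np.mean(a * b) - a.mean() * b.mean())
        cmp_ = MapComparison(mse, 1.0 - cov / (sa * sb), False)

    if not compute_track:
        return cmp_, None
    valid = (_DIST >= ContactMap.DIAG_BAND) & keep[None, :]
    counts = valid.sum(axis=1)
    track = np.where(counts > 0, (sq * valid).sum(axis=1) / np.maximum(counts, 1), 0.0)
    track[~keep] = 0.0
    return cmp_, _unflip(track, pair)


def score_variant(
    sv: StructuralVariant,
    genome,
    predictor: Predictor,
    aggregate: str = "median",
    augmentations: tuple[str, ...] = AUGMENTATIONS,
    compute_tracks: bool = True,
) -> DisruptionResult:
    """Score one variant: build augmented REF/ALT pairs, predict, compare.

    For BNDs each augmentation scores two half-window comparisons (one per
    breakpoint) and records their mean; the per-breakpoint tracks are kept
    separately for downstream activity weighting.  ``compute_tracks=False``
    skips the per-bin tracks (cohort-scale runs that only need the overall
    scores).
    """
    result = DisruptionResult(sv_id=sv.id, svtype=sv.svtype, sample_id=sv.sample_id)
    mses, corrs = [], []
    track_sums: list[np.ndarray] = []

    for aug in augmentations:
        if sv.svtype == "BND":
            pairs = build_bnd_pairs(sv, genome, aug)
        else:
            pairs = [build_sequence_pair(sv, genome, aug)]
        pair_scores = []
        for k, pair in enumerate(pairs):
            cmp_, track = _score_pair(pair, predictor, compute_tracks)
            pair_scores.append(cmp_)
            if len(track_sums) <= k:
                track_sums.append(np.zeros(N_BINS))
                result.windows.append(pair.window)
                result.masked_bins.append(set(pair.mask_bins))
            if track is not None:
                track_sums[k] += track
            if pair.flags:
                result.flags |= pair.flags
            if cmp_.zero_variance:
                result.flags.add("zero_variance")
        mse = float(np.mean([s.mse for s in pair_scores]))
        corr = float(np.mean([s.corr for s in pair_scores]))
        result.per_augmentation[aug] = MapComparison(
            mse, corr, any(s.zero_variance for s in pair_scores)
        )
        mses.append(mse)
        corrs.append(corr)

    result.mse_median = float(np.median(mses))
    result.mse_mean = float(np.mean(mses))
    result.corr_median = float(np.median(corrs))
    result.corr_mean = float(np.mean(corrs))
    result.tracks = (
        [t / len(augmentations) for t in track_sums] if compute_tracks else []
    )
    if aggregate not in ("median", "mean"):
        raise ValueError("aggregate must be 'median' or 'mean'")
    return result


def results_to_frame(results: list[DisruptionResult], svs=None):
    """Tabulate scored variants (one row per variant) for cohort analyses."""
    import pandas as pd

    from .sv_io import sv_length

    sv_by_id = {sv.id: sv for sv in svs} if svs is not None else {}
    rows = []
    for r in results:
        sv = sv_by_id.get(r.sv_id)
        rows.append(
            {
                "sv_id": r.sv_id,
                "svtype": r.svtype,
                "sample_id": r.sample_id,
                "chrom": sv.chrom if sv else None,
                "start": sv.start if sv else None,
                "end": sv.end if sv else None,
                "mate_chrom": sv.mate_chrom if sv else None,
                "mate_pos": sv.mate_pos if sv else None,
                "length": sv_length(sv) if sv else None,
                "mse_median": r.mse_median,
                "mse_mean": r.mse_mean,
                "corr_median": r.corr_median,
                "corr_mean": r.corr_mean,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    return pd.DataFrame(rows)
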