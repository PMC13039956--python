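"""Cohort-level analyses over scored structural variants.

All functions operate on the scored-variants table (one row per variant:
sample_id, chrom, start, end, svtype, length, score columns) plus the
sample metadata table, and return plain DataFrames ready to serialize.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

FLANK_DEFAULT = 300_000


# ---------------------------------------------------------------- summaries


def summarize_categories(
    scored: pd.DataFrame,
    meta: pd.DataFrame,
    metric_col: str = "corr_median",
    high_percentile: float = 90.0,
) -> pd.DataFrame:
    """Per-tumor-category cohort summary.

    Reports sample count, median SVs per sample, SV-type and stage
    fractions, the median across samples of per-sample median scores, and
    the fraction of the category's variants above the cohort-wide
    ``high_percentile`` score threshold.
    """
    known = set(meta.sample_id)
    unknown = set(scored.sample_id) - known
    if unknown:
        log.warning("excluding %d variants from unknown samples", len(unknown))
        scored = scored[scored.sample_id.isin(known)]
    merged = scored.merge(meta, on="sample_id", how="left")
    cohort_thr = float(np.percentile(merged[metric_col], high_percentile))

    rows = []
    for category, grp in merged.groupby("tumor_category"):
        cat_meta = meta[meta.tumor_category == category]
        per_sample = grp.groupby("sample_id")
        type_frac = (grp.svtype.value_counts(normalize=True)).to_dict()
        stage_frac = (cat_meta.stage.value_counts(normalize=True)).to_dict()
        rows.append(
            {
                "tumor_category": category,
                "n_samples": len(cat_meta),
                "median_svs_per_sample": float(per_sample.size().median()),
                **{f"frac_{t}": type_frac.get(t, 0.0)
                   for t in ("DEL", "DUP", "INV", "INS", "BND")},
                "frac_initial": stage_frac.get("initial", 0.0),
                "frac_progressive": stage_frac.get("progressive", 0.0),
                "median_sample_score": float(
                    per_sample[metric_col].median().median()
                ),
                "frac_above_cohort_p90": float((grp[metric_col] > cohort_thr).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("tumor_category")


# ------------------------------------------------- initial vs progressive


def progressive_vs_initial(
    scored: pd.DataFrame,
    meta: pd.DataFrame,
    metric_col: str = "corr_median",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant comparison of initial vs progressive variant scores.

    For every participant with at least one sample of each stage, one
    sample per stage is chosen uniformly at random (seeded; the chosen ids
    are reported so downstream analyses reuse them).  SVs of the
    progressive sample that exactly match an initial SV on
    (chrom, start, end, svtype) are removed; a Welch t-test then compares
    the remaining progressive scores against the initial scores (positive
    statistic = progressive more disruptive).  The count log fold change
    uses the full, unsubtracted callsets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pid, samples in meta.groupby("participant_id"):
        init = samples[samples.stage == "initial"].sample_id.tolist()
        prog = samples[samples.stage == "progressive"].sample_id.tolist()
        if not init or not prog:
            continue
        s_init = init[int(rng.integers(len(init)))]
        s_prog = prog[int(rng.integers(len(prog)))]
        sv_i = scored[scored.sample_id == s_init]
        sv_p = scored[scored.sample_id == s_prog]
        key = ["chrom", "start", "end", "svtype"]
        init_keys = set(map(tuple, sv_i[key].itertuples(index=False)))
        keep = [tuple(r) not in init_keys
                for r in sv_p[key].itertuples(index=False)]
        sv_p_new = sv_p[np.asarray(keep, dtype=bool)] if len(sv_p) else sv_p

        row = {
            "participant_id": pid,
            "initial_sample": s_init,
            "progressive_sample": s_prog,
            "n_initial": len(sv_i),
            "n_progressive": len(sv_p),
            "n_progressive_private": len(sv_p_new),
            "logfc_count": (
                float(np.log2(len(sv_p) / len(sv_i)))
                if len(sv_i) and len(sv_p)
                else np.nan
            ),
            "t_statistic": np.nan,
            "p_value": np.nan,
            "flag": "",
        }
        if len(sv_p_new) >= 2 and len(sv_i) >= 2:
            t = stats.ttest_ind(
                sv_p_new[metric_col], sv_i[metric_col], equal_var=False
            )
            row["t_statistic"] = float(t.statistic)
            row["p_value"] = float(t.pvalue)
        else:
            row["flag"] = "too_few_scores"
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------ cutoff calibration


@dataclass
class CutoffCalibration:
    """Percentile-grid calibration of the "highly disruptive" cutoff.

    ``thresholds`` has one row per grid percentile and one column per
    metric; ``review`` maps (percentile, metric) to the 5 lowest-scoring
    variants above that threshold (the candidates one would inspect
    visually).  ``selected`` lists variants at or above the chosen
    percentile on any configured metric.
    """

    chosen_percentile: float
    thresholds: pd.DataFrame
    chosen_thresholds: dict[str, float]
    review: dict[tuple[float, str], list[str]] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)


def calibrate_cutoff(
    scores: pd.DataFrame,
    coarse: tuple[float, float, float] = (90.0, 99.0, 1.0),
    fine: tuple[float, float, float] = (98.5, 99.9, 0.1),
    chosen: float = 98.8,
    metrics: tuple[str, ...] | None = None,
    rule: str = "either",
    strict: bool = True,
    review_size: int = 5,
) -> CutoffCalibration:
    """Evaluate the percentile grid and fix the disruption cutoff.

    ``scores`` is indexed by sv_id with one column per metric.  The grid
    is coarse percentiles (default 90-99 by 1) refined by fine ones
    (default 98.5-99.9 by 0.1); for each grid point and metric the
    empirical percentile threshold and a review list of the lowest-scoring
    variants above it are recorded.  ``selected`` applies the chosen
    percentile: with ``rule="either"`` a variant qualifies when any metric
    exceeds its own threshold (strict > by default).
    """
    if scores.empty:
        raise ValueError("no scores to calibrate on")
    if len(scores) < 1000:
        log.warning("only %d scores: percentile estimates unstable", len(scores))
    metrics = tuple(metrics or scores.columns)
    grid = sorted(
        {round(p, 10) for p in np.arange(*_inclusive(coarse))}
        | {round(p, 10) for p in np.arange(*_inclusive(fine))}
        | {chosen}
    )
    thr = pd.DataFrame(
        {m: [float(np.percentile(scores[m], p)) for p in grid] for m in metrics},
        index=pd.Index(grid, name="percentile"),
    )
    review: dict[tuple[float, str], list[str]] = {}
    for p in grid:
        for m in metrics:
            above = scores[scores[m] > thr.loc[p, m]] if strict else scores[
                scores[m] >= thr.loc[p, m]
            ]
            review[(p, m)] = above[m].nsmallest(review_size).index.tolist()

    chosen_thr = {m: float(thr.loc[chosen, m]) for m in metrics}
    if rule == "either":
        mask = np.zeros(len(scores), dtype=bool)
        for m in metrics:
            mask |= (
                scores[m] > chosen_thr[m] if strict else scores[m] >= chosen_thr[m]
            ).to_numpy()
    elif rule in metrics:
        mask = (
            scores[rule] > chosen_thr[rule]
            if strict
            else scores[rule] >= chosen_thr[rule]
        ).to_numpy()
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return CutoffCalibration(
        chosen_percentile=chosen,
        thresholds=thr,
        chosen_thresholds=chosen_thr,
        review=review,
        selected=scores.index[mask].tolist(),
    )


def _inclusive(grid: tuple[float, float, float]) -> tuple[float, float, float]:
    lo, hi, step = grid
    return lo, hi + step / 2, step


# --------------------------------------------------------- disrupted genes


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def disrupted_genes(
    svs: pd.DataFrame,
    genes: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    flank: int = FLANK_DEFAULT,
    criterion: str = "span",
) -> pd.DataFrame:
    """Protein-coding genes near, but not overlapped by, disruptive SVs.

    A gene qualifies for an SV when its span intersects the ``flank``
    regions on either side of the variant and does not intersect the
    variant itself.  ``criterion="span"`` excludes genes whose span
    overlaps the SV; ``criterion="exon"`` only excludes genes with an
    *exon* overlapping the SV (an intron-only overlap then still
    qualifies).  A ``recurrent`` column marks genes hit in >= 2 tumor
    types (requires ``meta``).
    """
    if criterion not in ("span", "exon"):
        raise ValueError("criterion must be 'span' or 'exon'")
    coding = genes[genes.protein_coding].copy() if "protein_coding" in genes else genes
    rows = []
    for sv in svs.itertuples():
        if sv.svtype == "BND":
            loci = [(sv.chrom, sv.start, sv.end)]
            if getattr(sv, "mate_chrom", None) is not None and not pd.isna(
                sv.mate_pos
            ):
                loci.append((sv.mate_chrom, int(sv.mate_pos), int(sv.mate_pos) + 1))
        else:
            loci = [(sv.chrom, int(sv.start), int(sv.end))]
        for chrom, start, end in loci:
            sub = coding[coding.chrom == chrom]
            for g in sub.itertuples():
                near = _overlaps(g.start, g.end, start - flank, start) or _overlaps(
                    g.start, g.end, end, end + flank
                )
                if not near:
                    continue
                if criterion == "span":
                    if _overlaps(g.start, g.end, start, end):
                        continue
                else:
                    if any(
                        _overlaps(es, ee, start, end) for es, ee in g.exons
                    ):
                        continue
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "sv_id": sv.sv_id,
                        "sample_id": sv.sample_id,
                        "chrom": chrom,
                    }
                )
    pairs = pd.DataFrame(rows, columns=["gene_id", "sv_id", "sample_id", "chrom"])
    pairs = pairs.drop_duplicates(["gene_id", "sv_id"])
    if meta is not None and len(pairs):
        types = meta.set_index("sample_id").tumor_type
        pairs["tumor_type"] = pairs.sample_id.map(types)
        n_types = pairs.groupby("gene_id").tumor_type.nunique()
        pairs["recurrent"] = pairs.gene_id.map(n_types >= 2)
    return pairs


# --------------------------------------------------- peak overlap analysis


def _coverage_fraction(start: int, end: int, peaks: pd.DataFrame) -> float:
    """Fraction of [start, end) covered by the (merged) peak set."""
    if end <= start:
        return 0.0
    sub = peaks[(peaks.end > start) & (peaks.start < end)]
    if sub.empty:
        return 0.0
    covered, last = 0, start
    for ps, pe in sorted(zip(sub.start, sub.end)):
        lo, hi = max(ps, last), min(pe, end)
        if hi > lo:
            covered += hi - lo
            last = hi
    return covered / (end - start)


def peak_overlap_enrichment(
    svs: pd.DataFrame,
    peaks: pd.DataFrame,
    length_bins: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disruptive-vs-other peak overlap, stratified by SV length.

    ``svs`` needs chrom/start/end/length and a ``label`` column with
    values "disruptive"/"other" (BNDs, having no interval, are skipped).
    Returns (per-variant overlap fractions, per-length-bin Mann-Whitney U
    table); bins with fewer than 2 variants in either group are skipped.
    """
    if length_bins is None:
        length_bins = [0, 1e2, 1e3, 1e4, 1e5, 1e6]
    sub = svs[svs.svtype != "BND"].copy()
    peaks_by_chrom = {c: g.sort_values("start") for c, g in peaks.groupby("chrom")} \
        if len(peaks) else {}
    fracs = []
    for sv in sub.itertuples():
        chrom_peaks = peaks_by_chrom.get(sv.chrom)
        fracs.append(
            0.0
            if chrom_peaks is None
            else _coverage_fraction(int(sv.start), int(sv.end), chrom_peaks)
        )
    sub["peak_overlap"] = fracs
    sub["length_bin"] = pd.cut(sub.length, bins=length_bins)

    rows = []
    for lb, grp in sub.groupby("length_bin", observed=True):
        a = grp.loc[grp.label == "disruptive", "peak_overlap"]
        b = grp.loc[grp.label == "other", "peak_overlap"]
        if len(a) < 2 or len(b) < 2:
            continue
        try:
            u = stats.mannwhitneyu(a, b, alternative="two-sided")
            pval, ustat = float(u.pvalue), float(u.statistic)
        except ValueError:  # identical constant groups
            pval, ustat = 1.0, np.nan
        rows.append(
            {
                "length_bin": str(lb),
                "n_disruptive": len(a),
                "n_other": len(b),
                "median_disruptive": float(a.median()),
                "median_other": float(b.median()),
                "u_statistic": ustat,
                "p_value": pval,
            }
        )
    return sub, pd.DataFrame(rows)


# ----------------------------------------------------- expression extremity


@dataclass
class ExtremityResult:
    """How extreme a focal sample's expression is among its comparators."""

    gene_id: str
    focal_sample: str
    direction: str  # "higher" | "lower"
    k: int  # comparison samples the focal sample is beyond
    n: int  # comparison set size
    ties: int
    flags: set[str] = field(default_factory=set)

    def __str__(self) -> str:  # e.g. "higher than 27/28 samples"
        return f"{self.direction} than {self.k}/{self.n} samples"


def expression_extremity(
    gene_id: str,
    focal_sample: str,
    tpm: pd.DataFrame,
    svs: pd.DataFrame,
    meta: pd.DataFrame,
    genes: pd.DataFrame,
    flank: int = FLANK_DEFAULT,
) -> ExtremityResult:
    """Rank the focal sample's TPM against same-type, variant-free samples.

    The comparison set is samples of the focal sample's tumor type with no
    SV within ``flank`` of the gene.  Counts use strict inequalities; ties
    are reported separately and counted on neither side.
    """
    gene = genes[genes.gene_id == gene_id].iloc[0]
    types = meta.set_index("sample_id").tumor_type
    same_type = [
        s
        for s in meta[meta.tumor_type == types[focal_sample]].sample_id
        if s != focal_sample and s in tpm.columns
    ]
    near = svs[
        (svs.chrom == gene.chrom)
        & (svs.end > gene.start - flank)
        & (svs.start < gene.end + flank)
    ]
    has_sv = set(near.sample_id)
    comparators = [s for s in same_type if s not in has_sv]
    flags = set()
    if not comparators:
        flags.add("empty_comparison_set")
        return ExtremityResult(gene_id, focal_sample, "higher", 0, 0, 0, flags)
    focal = float(tpm.loc[gene_id, focal_sample])
    vals = tpm.loc[gene_id, comparators].astype(float)
    below = int((vals < focal).sum())
    above = int((vals > focal).sum())
    ties = int((vals == focal).sum())
    if below >= above:
        return ExtremityResult(gene_id, focal_sample, "higher", below,
                               len(comparators), ties, flags)
    return ExtremityResult(gene_id, focal_sample, "lower", above,
                           len(comparators), ties, flags)


# ------------------------------------------- breakpoint CIs and repeats


def breakpoint_ci_and_repeats(
    svs: list,
    repeats: pd.DataFrame,
    match_window: int = 50,
) -> pd.DataFrame:
    """Breakpoint confidence-interval widths and repeat-family concordance.

    ``ci_width_total`` is the summed width of CIPOS and CIEND.  A variant
    is ``repeat_matched`` when both breakpoints (each widened by
    ``match_window`` bp) overlap repeats of the same family; the shared
    family is reported.
    """
    rep_by_chrom = {c: g for c, g in repeats.groupby("chrom")}

    def families_at(chrom: str, pos: int) -> set[str]:
        sub = rep_by_chrom.get(chrom)
        if sub is None:
            return set()
        hit = sub[(sub.end > pos - match_window) & (sub.start < pos + match_window)]
        return set(hit.family)

    rows = []
    for sv in svs:
        ci_width = (sv.ci_pos[1] - sv.ci_pos[0]) + (sv.ci_end[1] - sv.ci_end[0])
        if sv.svtype == "BND":
            fams_a = families_at(sv.chrom, sv.start)
            fams_b = families_at(sv.mate_chrom, sv.mate_pos)
        else:
            fams_a = families_at(sv.chrom, sv.start)
            fams_b = families_at(sv.chrom, sv.end)
        shared = sorted(fams_a & fams_b)
        rows.append(
            {
                "sv_id": sv.id,
                "sample_id": sv.sample_id,
                "svtype": sv.svtype,
                "ci_width_total": ci_width,
                "repeat_matched": bool(shared),
                "repeat_family": shared[0] if shared else "",
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------- score associations


def genic_context(sv, genes: pd.DataFrame) -> str:
    """Classify an SV interval as coding / intronic / intergenic."""
    start, end = int(sv.start), int(sv.end)
    sub = genes[(genes.chrom == sv.chrom) & (genes.end > start)
                & (genes.start < end)]
    if sub.empty:
        return "intergenic"
    for g in sub.itertuples():
        if any(_overlaps(es, ee, start, end) for es, ee in g.exons):
            return "coding"
    return "intronic"


def score_associations(
    scored: pd.DataFrame,
    meta: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    metric_col: str = "corr_median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score-covariate associations (Spearman) and genic-context classes.

    Returns (association table, scored table with a ``genic_class``
    column).  Associations: score ~ variant length (non-BND) and
    score ~ tumor purity (per-variant, joined from metadata).
    """
    merged = scored.merge(meta[["sample_id", "purity"]], on="sample_id", how="left")
    rows = []
    nonbnd = merged[(merged.svtype != "BND") & merged.length.notna()]
    if len(nonbnd) >= 3 and nonbnd.length.nunique() > 1 \
            and nonbnd[metric_col].nunique() > 1:
        rho, p = stats.spearmanr(nonbnd.length, nonbnd[metric_col])
        rows.append({"association": "score_vs_length", "n": len(nonbnd),
                     "spearman_rho": float(rho), "p_value": float(p)})
    with_purity = merged[merged.purity.notna()]
    if len(with_purity) >= 3 and with_purity.purity.nunique() > 1 \
            and with_purity[metric_col].nunique() > 1:
        rho, p = stats.spearmanr(with_purity.purity, with_purity[metric_col])
        rows.append({"association": "score_vs_purity", "n": len(with_purity),
                     "spearman_rho": float(rho), "p_value": float(p)})

    out = scored.copy()
    if genes is not None:
        out["genic_class"] = [
            "noncoding_bnd" if sv.svtype == "BND" else genic_context(sv, genes)
            for sv in out.itertuples()
        ]
    return pd.DataFrame(rows), out
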