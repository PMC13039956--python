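"""Cohort-level statistics: summaries, stage comparison, cutoffs, genes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svfold import StructuralVariant
from svfold.cohort_stats import (
    breakpoint_ci_and_repeats,
    calibrate_cutoff,
    disrupted_genes,
    expression_extremity,
    genic_context,
    peak_overlap_enrichment,
    progressive_vs_initial,
    score_associations,
    summarize_categories,
)


def _meta(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "participant_id", "tumor_type",
                 "tumor_category", "stage", "purity"],
    )


def _scored(rows):
    return pd.DataFrame(
        rows,
        columns=["sv_id", "sample_id", "chrom", "start", "end", "svtype",
                 "length", "corr_median"],
    )


META = _meta(
    [
        ("S1", "P1", "T1", "C1", "initial", 0.8),
        ("S2", "P1", "T1", "C1", "progressive", 0.7),
        ("S3", "P2", "T2", "C2", "initial", 0.6),
        ("S4", "P3", "T2", "C2", "initial", np.nan),
    ]
)


def test_summarize_categories_fractions_and_high_scores():
    rng = np.random.default_rng(0)
    rows = []
    k = 0
    for sample, n, shift in (("S1", 30, 0.0), ("S2", 30, 0.0),
                             ("S3", 40, 0.5), ("S4", 40, 0.5)):
        for _ in range(n):
            k += 1
            rows.append((f"v{k}", sample, "chr1", 100 * k, 100 * k + 50,
                         "DEL", 50, rng.uniform() * 0.1 + shift))
    summary = summarize_categories(_scored(rows), META)
    # SV-type fractions sum to one per category
    type_cols = [c for c in summary.columns if c.startswith("frac_")
                 and c[5:] in ("DEL", "DUP", "INV", "INS", "BND")]
    assert np.allclose(summary[type_cols].sum(axis=1), 1.0)
    # C2's planted +0.5 shift puts all its variants above the cohort p90
    assert summary.loc["C2", "frac_above_cohort_p90"] > \
        summary.loc["C1", "frac_above_cohort_p90"]
    assert summary.loc["C1", "n_samples"] == 2
    # single-stage category fractions
    assert summary.loc["C2", "frac_initial"] == 1.0


def test_summarize_skips_unknown_samples():
    rows = [("v1", "S1", "chr1", 0, 50, "DEL", 50, 0.1),
            ("v2", "GHOST", "chr1", 0, 50, "DEL", 50, 0.9)]
    summary = summarize_categories(_scored(rows), META)
    assert summary.frac_above_cohort_p90.notna().all()


# ----------------------------------------------- initial vs progressive


def test_progressive_subtraction_exact_match_only():
    """Only exact (chrom, start, end, svtype) matches are removed; an SV
    absent from the initial set is never removed."""
    rows = [
        ("i1", "S1", "chr1", 100, 200, "DEL", 100, 0.1),
        ("i2", "S1", "chr1", 500, 800, "DUP", 300, 0.1),
        ("p1", "S2", "chr1", 100, 200, "DEL", 100, 0.2),  # shared -> removed
        ("p2", "S2", "chr1", 100, 201, "DEL", 101, 0.2),  # off by 1 -> kept
        ("p3", "S2", "chr1", 500, 800, "INV", 300, 0.2),  # type differs -> kept
    ]
    out = progressive_vs_initial(_scored(rows), META, seed=0)
    row = out[out.participant_id == "P1"].iloc[0]
    assert row.n_progressive == 3
    assert row.n_progressive_private == 2
    assert row.logfc_count == pytest.approx(np.log2(3 / 2))


def test_identical_callsets_flagged():
    rows = [
        ("i1", "S1", "chr1", 100, 200, "DEL", 100, 0.1),
        ("p1", "S2", "chr1", 100, 200, "DEL", 100, 0.1),
    ]
    out = progressive_vs_initial(_scored(rows), META, seed=0)
    row = out[out.participant_id == "P1"].iloc[0]
    assert row.n_progressive_private == 0
    assert row.flag == "too_few_scores"
    assert np.isnan(row.t_statistic)


def test_welch_t_matches_closed_form():
    """The reported statistic equals the textbook Welch formula on a
    hand-computed two-vector example."""
    a = [0.12, 0.15, 0.11, 0.19, 0.16]  # progressive
    b = [0.10, 0.09, 0.12, 0.08]  # initial
    rows = [(f"i{k}", "S1", "chr1", k * 10, k * 10 + 5, "DEL", 5, v)
            for k, v in enumerate(b)]
    rows += [(f"p{k}", "S2", "chr2", k * 10, k * 10 + 5, "DEL", 5, v)
             for k, v in enumerate(a)]
    out = progressive_vs_initial(_scored(rows), META, seed=0)
    row = out[out.participant_id == "P1"].iloc[0]
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    expected_t = (ma - mb) / np.sqrt(va + vb)
    assert row.t_statistic == pytest.approx(expected_t, abs=1e-10)
    assert row.t_statistic > 0  # progressive more disruptive


def test_sample_choice_is_seeded_and_persisted():
    meta = _meta(
        [
            ("S1", "P1", "T1", "C1", "initial", 0.8),
            ("S1b", "P1", "T1", "C1", "initial", 0.8),
            ("S2", "P1", "T1", "C1", "progressive", 0.7),
        ]
    )
    rows = [("v1", "S1", "chr1", 0, 10, "DEL", 10, 0.1),
            ("v2", "S1b", "chr1", 0, 10, "DEL", 10, 0.1),
            ("v3", "S2", "chr1", 50, 60, "DEL", 10, 0.1)]
    first = progressive_vs_initial(_scored(rows), meta, seed=5)
    second = progressive_vs_initial(_scored(rows), meta, seed=5)
    assert first.iloc[0].initial_sample == second.iloc[0].initial_sample


# ------------------------------------------------------ cutoff calibration


def test_calibrate_uniform_scores():
    rng = np.random.default_rng(0)
    n = 20_000
    scores = pd.DataFrame(
        {"mse": rng.uniform(size=n)}, index=[f"v{i}" for i in range(n)]
    )
    cal = calibrate_cutoff(scores, chosen=98.8)
    assert cal.chosen_thresholds["mse"] == pytest.approx(0.988, abs=0.005)
    assert len(cal.selected) / n == pytest.approx(0.012, abs=0.003)
    # grid includes both ranges and thresholds are monotone
    thr = cal.thresholds["mse"]
    assert 90.0 in thr.index and 99.9 in thr.index
    assert thr.is_monotonic_increasing


def test_constant_scores_select_nothing_under_strict_rule():
    scores = pd.DataFrame({"mse": np.full(2000, 3.3)},
                          index=[f"v{i}" for i in range(2000)])
    cal = calibrate_cutoff(scores)
    assert cal.chosen_thresholds["mse"] == 3.3
    assert cal.selected == []


def test_review_list_is_five_lowest_above_threshold_per_metric():
    """1000 hand-ranked scores: the review list at each grid point is the
    known 5 lowest-scoring variants above that percentile, per metric."""
    n = 1000
    scores = pd.DataFrame(
        {"mse": np.arange(n, dtype=float), "corr": np.arange(n, dtype=float)[::-1]},
        index=[f"v{i}" for i in range(n)],
    )
    cal = calibrate_cutoff(scores, chosen=98.8)
    thr = cal.thresholds.loc[98.8, "mse"]
    expected = [f"v{i}" for i in range(n) if i > thr][:5]
    assert cal.review[(98.8, "mse")] == expected
    assert len(cal.review[(98.8, "corr")]) == 5
    # dual-metric "either" rule: selected on mse OR corr
    assert "v999" in cal.selected and "v0" in cal.selected


def test_empty_scores_error():
    with pytest.raises(ValueError):
        calibrate_cutoff(pd.DataFrame({"mse": []}))


# --------------------------------------------------------- disrupted genes


def _genes(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "exons", "protein_coding"]
    )


GENES = _genes(
    [
        # downstream of the DEL end, within 300 kb
        ("G_down", "chr1", 1_150_000, 1_160_000, "+",
         [(1_150_000, 1_151_000)], True),
        # fully inside the DEL
        ("G_inside", "chr1", 1_010_000, 1_020_000, "+",
         [(1_010_000, 1_011_000)], True),
        # overlaps the DEL with one exon inside it
        ("G_exonhit", "chr1", 1_040_000, 1_060_000, "+",
         [(1_041_000, 1_042_000)], True),
        # straddles the DEL edge but only an intron overlaps
        ("G_intron", "chr1", 1_045_000, 1_070_000, "+",
         [(1_060_000, 1_061_000)], True),
        # too far away (> 300 kb)
        ("G_far", "chr1", 1_500_000, 1_510_000, "+",
         [(1_500_000, 1_501_000)], True),
        # non-coding neighbour
        ("G_nc", "chr1", 1_100_000, 1_110_000, "+",
         [(1_100_000, 1_101_000)], False),
    ]
)

SV_DF = pd.DataFrame(
    [{"sv_id": "d1", "sample_id": "S1", "chrom": "chr1",
      "start": 1_000_000, "end": 1_050_000, "svtype": "DEL",
      "mate_chrom": None, "mate_pos": np.nan}]
)


def test_disrupted_genes_span_criterion():
    pairs = disrupted_genes(SV_DF, GENES, criterion="span")
    got = set(pairs.gene_id)
    assert got == {"G_down"}


def test_disrupted_genes_exon_criterion_keeps_intron_only_overlap():
    pairs = disrupted_genes(SV_DF, GENES, criterion="exon")
    got = set(pairs.gene_id)
    assert "G_intron" in got  # intron-only overlap passes the exon criterion
    assert "G_exonhit" not in got
    assert "G_inside" not in got
    assert got >= {"G_down", "G_intron"}


def test_disrupted_genes_invariant_to_gene_order_and_recurrence():
    shuffled = GENES.iloc[::-1].reset_index(drop=True)
    a = disrupted_genes(SV_DF, GENES, criterion="span")
    b = disrupted_genes(SV_DF, shuffled, criterion="span")
    assert set(a.gene_id) == set(b.gene_id)
    two_types = pd.concat(
        [SV_DF, SV_DF.assign(sv_id="d2", sample_id="S3")], ignore_index=True
    )
    pairs = disrupted_genes(two_types, GENES, meta=META, criterion="span")
    assert pairs.recurrent.all()  # S1 (T1) and S3 (T2) hit the same gene


# ------------------------------------------------------- peak enrichment


def test_peak_enrichment_planted_signal():
    """Disruptive SVs planted on peaks separate from off-peak SVs with
    p < 1e-4 at n = 50 per group."""
    rng = np.random.default_rng(1)
    peaks = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(50) * 100_000,
         "end": np.arange(50) * 100_000 + 20_000}
    )
    rows = []
    for i in range(50):  # disruptive: on peaks
        s = i * 100_000 + int(rng.integers(0, 10_000))
        rows.append(("chr1", s, s + 5_000, "DEL", 5_000, "disruptive"))
    for i in range(50):  # other: off peaks
        s = i * 100_000 + 30_000 + int(rng.integers(0, 10_000))
        rows.append(("chr1", s, s + 5_000, "DEL", 5_000, "other"))
    svs = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "svtype", "length", "label"]
    )
    per_sv, table = peak_overlap_enrichment(svs, peaks)
    assert (table.p_value < 1e-4).any()
    on = per_sv[per_sv.label == "disruptive"].peak_overlap
    off = per_sv[per_sv.label == "other"].peak_overlap
    assert on.median() > off.median()


def test_peak_enrichment_empty_peaks_and_no_overlap():
    svs = pd.DataFrame(
        [("chr1", 0, 1000, "DEL", 1000, "disruptive"),
         ("chr1", 5000, 6000, "DEL", 1000, "other")],
        columns=["chrom", "start", "end", "svtype", "length", "label"],
    )
    per_sv, table = peak_overlap_enrichment(svs, pd.DataFrame(
        columns=["chrom", "start", "end"]))
    assert (per_sv.peak_overlap == 0).all()
    assert table.empty


def test_identical_groups_give_null_pvalues():
    rng = np.random.default_rng(2)
    peaks = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [10_000_000]})
    rows = []
    for i in range(40):
        s = int(rng.integers(0, 5_000_000))
        rows.append(("chr1", s, s + 1000 + int(rng.integers(1000)), "DEL",
                     1000, "disruptive" if i % 2 else "other"))
    svs = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "svtype", "length", "label"]
    )
    _, table = peak_overlap_enrichment(svs, peaks)
    assert (table.p_value > 0.001).all()


# ---------------------------------------------------- expression extremity


def _expr_setup(n_comp, focal_value, comp_values):
    genes = _genes([("G1", "chr1", 1_000_000, 1_010_000, "+",
                     [(1_000_000, 1_001_000)], True)])
    samples = ["F"] + [f"C{i}" for i in range(n_comp)]
    meta = _meta([(s, f"P{s}", "T1", "C1", "initial", 0.5) for s in samples])
    tpm = pd.DataFrame({s: [v] for s, v in
                        zip(samples, [focal_value] + comp_values)},
                       index=["G1"])
    svs = pd.DataFrame(
        [{"sv_id": "b1", "sample_id": "F", "chrom": "chr1",
          "start": 1_005_000, "end": 1_005_001, "svtype": "BND"}]
    )
    return genes, meta, tpm, svs


def test_focal_below_all_comparators():
    genes, meta, tpm, svs = _expr_setup(31, 1.0, [5.0 + i for i in range(31)])
    r = expression_extremity("G1", "F", tpm, svs, meta, genes)
    assert (r.direction, r.k, r.n) == ("lower", 31, 31)
    assert str(r) == "lower than 31/31 samples"


def test_higher_than_27_of_28_pattern():
    comp = [1.0 + i for i in range(27)] + [100.0]  # one comparator above focal
    genes, meta, tpm, svs = _expr_setup(28, 50.0, comp)
    r = expression_extremity("G1", "F", tpm, svs, meta, genes)
    assert (r.direction, r.k, r.n, r.ties) == ("higher", 27, 28, 0)
    assert str(r) == "higher than 27/28 samples"


def test_focal_at_median():
    comp = list(range(1, 21))
    genes, meta, tpm, svs = _expr_setup(20, 10.5, [float(c) for c in comp])
    r = expression_extremity("G1", "F", tpm, svs, meta, genes)
    assert abs(r.k - 10) <= 1


def test_samples_with_nearby_svs_excluded_from_comparison():
    genes, meta, tpm, svs = _expr_setup(5, 1.0, [2.0, 3.0, 4.0, 5.0, 6.0])
    svs = pd.concat(
        [svs, pd.DataFrame([{"sv_id": "b2", "sample_id": "C0",
                             "chrom": "chr1", "start": 1_100_000,
                             "end": 1_100_001, "svtype": "DEL"}])],
        ignore_index=True,
    )
    r = expression_extremity("G1", "F", tpm, svs, meta, genes)
    assert r.n == 4  # C0 carries an SV within 300 kb -> excluded


def test_empty_comparison_set_flagged():
    genes, meta, tpm, svs = _expr_setup(1, 1.0, [2.0])
    svs = pd.concat(
        [svs, pd.DataFrame([{"sv_id": "b2", "sample_id": "C0",
                             "chrom": "chr1", "start": 1_000_500,
                             "end": 1_000_501, "svtype": "DEL"}])],
        ignore_index=True,
    )
    r = expression_extremity("G1", "F", tpm, svs, meta, genes)
    assert "empty_comparison_set" in r.flags


# ------------------------------------------------------- CIs and repeats


def test_ci_width_and_repeat_matching():
    repeats = pd.DataFrame(
        [("chr1", 900, 1300, "SINE"), ("chr1", 4900, 5300, "SINE"),
         ("chr2", 900, 1300, "SINE"), ("chr2", 4900, 5300, "LINE")],
        columns=["chrom", "start", "end", "family"],
    )
    both_sine = StructuralVariant("a", "chr1", 1000, 5000, "DEL",
                                  ci_pos=(-10, 10), ci_end=(-5, 5),
                                  sample_id="s")
    mixed = StructuralVariant("b", "chr2", 1000, 5000, "DEL", sample_id="s")
    out = breakpoint_ci_and_repeats([both_sine, mixed], repeats)
    a = out[out.sv_id == "a"].iloc[0]
    assert a.ci_width_total == 30
    assert a.repeat_matched and a.repeat_family == "SINE"
    b = out[out.sv_id == "b"].iloc[0]
    assert not b.repeat_matched  # SINE at one end, LINE at the other


# ------------------------------------------------------- associations


def test_score_length_association_perfect_rank():
    rows = [(f"v{i}", "S1", "chr1", 0, 10 * (i + 1), "DEL",
             10 * (i + 1), float(i)) for i in range(20)]
    assoc, _ = score_associations(_scored(rows), META)
    row = assoc[assoc.association == "score_vs_length"].iloc[0]
    assert row.spearman_rho == pytest.approx(1.0)


def test_purity_null_association():
    rng = np.random.default_rng(3)
    meta = _meta([(f"S{i}", f"P{i}", "T1", "C1", "initial",
                   float(rng.uniform(0.2, 0.9))) for i in range(40)])
    rows = [(f"v{i}", f"S{i}", "chr1", 0, 100, "DEL", 100,
             float(rng.uniform())) for i in range(40)]
    assoc, _ = score_associations(_scored(rows), meta)
    row = assoc[assoc.association == "score_vs_purity"].iloc[0]
    assert abs(row.spearman_rho) < 0.45  # independent draws: no correlation


def test_genic_context_classes():
    genes = _genes([("G1", "chr1", 1000, 9000, "+", [(1000, 2000),
                                                     (8000, 9000)], True)])

    class SV:
        def __init__(self, start, end):
            self.chrom, self.start, self.end = "chr1", start, end

    assert genic_context(SV(1500, 1600), genes) == "coding"
    assert genic_context(SV(3000, 4000), genes) == "intronic"
    assert genic_context(SV(20_000, 21_000), genes) == "intergenic"
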