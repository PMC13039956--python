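"""The synthetic study generator: determinism, planted structure, round-trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from svfold import filter_variants, read_sv_vcf
from svfold.predictor import revcomp
from svfold.synthetic import (
    SimulationConfig,
    generate_epigenome,
    generate_expression,
    generate_genome,
    simulate_study,
    write_study,
)


def test_same_seed_reproduces_identical_artifacts(tmp_path, small_study):
    """The entire study is a pure function of the config: FASTA bytes,
    VCFs and the TPM table are identical across runs."""
    again = simulate_study(small_study.config)
    assert again.genome.contigs == small_study.genome.contigs
    pd.testing.assert_frame_equal(again.metadata, small_study.metadata)
    pd.testing.assert_frame_equal(again.expression, small_study.expression)
    a_dir, b_dir = tmp_path / "a", tmp_path / "b"
    write_study(small_study, a_dir)
    write_study(again, b_dir)
    assert (a_dir / "genome.fa").read_bytes() == (b_dir / "genome.fa").read_bytes()
    sample = small_study.metadata.sample_id.iloc[0]
    assert (a_dir / "vcf" / f"{sample}.vcf").read_text() == \
        (b_dir / "vcf" / f"{sample}.vcf").read_text()


def test_contigs_carry_boundary_motifs(small_study):
    cfg = small_study.config
    for chrom in small_study.genome.contigs:
        n = (small_study.genome.boundaries.chrom == chrom).sum()
        assert n >= 4


def test_motif_bed_entries_match_fasta(small_study):
    p = small_study.config.predictor_params
    for row in small_study.genome.boundaries.itertuples():
        seq = small_study.genome.contigs[row.chrom][row.start : row.end]
        assert seq == p.boundary_motif
    for row in small_study.genome.anchors.itertuples():
        seq = small_study.genome.contigs[row.chrom][row.start : row.end]
        expected = p.anchor_motif if row.strand == "+" else revcomp(p.anchor_motif)
        assert seq == expected


def test_planted_motifs_are_the_only_occurrences(small_study):
    """Background sequence is scrubbed: every motif match is a planted one."""
    p = small_study.config.predictor_params
    for chrom, seq in small_study.genome.contigs.items():
        planted = set(
            small_study.genome.boundaries.query("chrom == @chrom").start
        ) | set(small_study.genome.anchors.query("chrom == @chrom").start)
        found = set()
        for motif in {p.boundary_motif, revcomp(p.boundary_motif),
                      p.anchor_motif, revcomp(p.anchor_motif)}:
            i = seq.find(motif)
            while i != -1:
                found.add(i)
                i = seq.find(motif, i + 1)
        assert found == planted


def test_enhancer_counts_distribution():
    cfg = SimulationConfig(seed=9, n_enhancers=5000)
    genome = generate_genome(cfg)
    els = generate_epigenome(cfg, genome)
    atac = np.array([e.atac_count for e in els])
    h3k = np.array([e.h3k27ac_count for e in els])
    assert ((atac >= 0) & (atac == atac.astype(int))).all()
    assert abs(atac.mean() / cfg.atac_mean - 1) < 0.10
    assert abs(h3k.mean() / cfg.h3k27ac_mean - 1) < 0.10
    # overdispersed relative to Poisson, and the two tracks correlate
    assert atac.var() > 2 * atac.mean()
    assert np.corrcoef(atac, h3k)[0, 1] > 0.5


def test_zero_enhancer_config_gives_empty_set():
    cfg = SimulationConfig(seed=9, n_enhancers=0)
    genome = generate_genome(cfg)
    assert generate_epigenome(cfg, genome) == []


def test_stage_fractions_and_type_counts():
    study_meta = simulate_study(SimulationConfig(seed=2)).metadata
    frac_prog = (study_meta.stage == "progressive").mean()
    assert frac_prog == pytest.approx(0.25, abs=0.02)
    assert (study_meta.groupby("tumor_type").size() == 10).all()
    # paired participants have exactly one sample per stage
    per_part = study_meta.groupby("participant_id").stage.value_counts()
    assert per_part.max() == 1


def test_truth_table_driver_structure(small_study):
    truth = small_study.truth
    cfg = small_study.config
    boundary = truth[truth.driver_class == "boundary"]
    assert len(boundary) == cfg.n_driver_bins * cfg.carriers_per_bin
    assert boundary.groupby(["chrom", "bin_start"]).size().eq(
        cfg.carriers_per_bin
    ).all()
    # carriers span at least two tumor types per bin
    types = small_study.metadata.set_index("sample_id").tumor_type
    for _, grp in boundary.groupby(["chrom", "bin_start"]):
        assert grp.sample_id.map(types).nunique() >= 2


def test_every_driver_deletes_exactly_one_boundary_motif(small_study):
    b = small_study.genome.boundaries
    svs = {sv.id: sv for sv in small_study.svs}
    for t in small_study.truth.itertuples():
        sv = svs[t.sv_id]
        assert sv.svtype == "DEL"
        inside = b.query("chrom == @sv.chrom and start >= @sv.start "
                         "and end <= @sv.end")
        assert len(inside) == 1


def test_progressive_samples_share_a_subset_of_initial_svs(small_study):
    meta = small_study.metadata
    by_sample = {}
    for sv in small_study.svs:
        by_sample.setdefault(sv.sample_id, []).append(sv)
    paired = meta.groupby("participant_id").filter(lambda g: len(g) == 2)
    n_shared_pairs = 0
    for pid, grp in paired.groupby("participant_id"):
        init = grp[grp.stage == "initial"].sample_id.iloc[0]
        prog = grp[grp.stage == "progressive"].sample_id.iloc[0]
        keys = lambda svs: {
            (s.chrom, s.start, s.end, s.svtype) for s in svs
        }
        shared = keys(by_sample[init]) & keys(by_sample[prog])
        private = keys(by_sample[prog]) - keys(by_sample[init])
        if min(len(by_sample[init]), len(by_sample[prog])) >= 2:
            assert shared  # the configured fraction carried over
        assert shared or private
        n_shared_pairs += bool(shared)
    assert n_shared_pairs >= 1


def test_generated_vcfs_roundtrip_with_zero_parse_errors(tmp_path, small_study):
    paths = write_study(small_study, tmp_path)
    total, errors = 0, []
    for sample in small_study.metadata.sample_id:
        svs = read_sv_vcf(paths["vcf_dir"] / f"{sample}.vcf", sample,
                          errors=errors)
        total += len(svs)
        retained, report = filter_variants(svs)
        assert report.unresolved_mate == 0
    assert errors == []
    assert total == len(small_study.svs)


def test_expression_shifts_driver_carriers(small_study):
    """Genes near a planted driver are shifted in the carrier sample by
    the configured fold change relative to the deterministic baseline."""
    cfg = small_study.config
    truth = small_study.truth
    genes = small_study.genome.genes
    tpm = small_study.expression
    found_shift = False
    for t in truth.itertuples():
        sv = next(s for s in small_study.svs if s.id == t.sv_id)
        near = genes[(genes.chrom == sv.chrom)
                     & (genes.end > sv.start - cfg.expr_flank)
                     & (genes.start < sv.end + cfg.expr_flank)]
        for gid in near.gene_id:
            other = tpm.loc[gid].drop(t.sample_id)
            focal = tpm.loc[gid, t.sample_id]
            if t.expr_sign > 0:
                found_shift |= focal > other.quantile(0.90)
            else:
                found_shift |= focal < other.quantile(0.10)
    assert found_shift


def test_loop_anchor_driver_class_behind_flag():
    """With loop_anchor_drivers on, an extra driver class deletes exactly
    one loop-anchor motif (and no boundary)."""
    cfg = SimulationConfig(seed=6, samples_per_type=4, svs_per_sample_mean=5.0,
                           carriers_per_bin=2, n_enhancer_drivers=0,
                           loop_anchor_drivers=True)
    study = simulate_study(cfg)
    anchors = study.truth[study.truth.driver_class == "loop_anchor"]
    assert len(anchors) == cfg.carriers_per_bin
    svs = {sv.id: sv for sv in study.svs}
    for t in anchors.itertuples():
        sv = svs[t.sv_id]
        in_anchor = study.genome.anchors.query(
            "chrom == @sv.chrom and start >= @sv.start and end <= @sv.end"
        )
        in_boundary = study.genome.boundaries.query(
            "chrom == @sv.chrom and start >= @sv.start and end <= @sv.end"
        )
        assert len(in_anchor) == 1 and len(in_boundary) == 0


def test_driver_bin_without_boundary_impossible():
    cfg = SimulationConfig(seed=3, boundary_spacing_mean=3_000_000,
                           n_driver_bins=8)
    with pytest.raises(ValueError, match="driver"):
        simulate_study(cfg)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="mixture"):
        SimulationConfig(sv_type_mixture={"DEL": 0.5})
    with pytest.raises(ValueError, match="category"):
        SimulationConfig(tumor_types=("T1",), tumor_categories=("C1", "C2"))
    with pytest.raises(ValueError, match="window"):
        SimulationConfig(contig_length=100_000)
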