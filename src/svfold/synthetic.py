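"""Self-contained synthetic study generator.

Produces everything the pipeline consumes: a toy genome whose folding
grammar is motif-encoded (boundary motifs at ~400 kb spacing delimit
TAD-like blocks, convergent anchor pairs mark loops), gene/exon and
repeat annotation, candidate enhancers with correlated ATAC/H3K27ac
counts, a multi-tumor-type SV cohort with planted boundary-deleting
driver DELs concentrated in designated 1 Mb bins, paired
initial/progressive samples sharing a subset of SVs, and a TPM
expression table in which driver-bearing samples are shifted for genes
near their driver.  The whole study is a pure, deterministic function of
:class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .abc_weighting import RegulatoryElement
from .geometry import L_IN
from .predictor import ToyPredictorParams, revcomp
from .sv_io import StructuralVariant, write_sv_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study; every default is the study condition.

    The defaults emulate the cohort structure the pipeline targets: 6
    tumor types in 3 categories, 10 samples per type, a Poisson mean of
    35 SVs per sample, ~75%/25% initial/progressive samples, and two
    designated driver bins with 8 boundary-deleting carriers each.
    """

    seed: int = 0
    # genome
    n_contigs: int = 3
    contig_length: int = 6_000_000
    boundary_spacing_mean: int = 400_000
    boundary_spacing_jitter: int = 60_000
    anchor_rate: float = 0.5
    predictor_params: ToyPredictorParams = field(default_factory=ToyPredictorParams)
    # annotation
    n_genes: int = 150
    exons_per_gene: int = 5
    exon_length: int = 200
    intron_length_mean: int = 2_000
    n_repeats: int = 600
    repeat_length: int = 300
    repeat_families: tuple[str, ...] = ("SINE", "LINE", "LTR", "Simple_repeat")
    # epigenome
    n_enhancers: int = 400
    enhancer_width: int = 500
    atac_mean: float = 50.0
    h3k27ac_mean: float = 50.0
    count_dispersion: float = 0.5  # NB overdispersion via shared gamma factor
    enhancer_near_gene_prob: float = 0.7
    enhancer_gene_flank: int = 20_000
    # cohort
    tumor_types: tuple[str, ...] = ("T1", "T2", "T3", "T4", "T5", "T6")
    tumor_categories: tuple[str, ...] = ("C1", "C1", "C2", "C2", "C3", "C3")
    samples_per_type: int = 10
    svs_per_sample_mean: float = 35.0
    sv_type_mixture: dict = field(
        default_factory=lambda: {
            "BND": 0.48,
            "DEL": 0.33,
            "DUP": 0.10,
            "INS": 0.05,
            "INV": 0.04,
        }
    )
    passenger_len_min: int = 50
    passenger_len_max: int = 5_000
    ci_passenger_max: int = 10
    # drivers
    n_driver_bins: int = 2
    carriers_per_bin: int = 8
    driver_len_min: int = 2_000
    driver_len_max: int = 8_000
    ci_driver_min: int = 20
    ci_driver_max: int = 60
    n_enhancer_drivers: int = 4
    loop_anchor_drivers: bool = False
    rdr_bin_size: int = 1_000_000
    # stages
    progressive_fraction: float = 0.25
    shared_sv_fraction: float = 0.5
    # expression
    expr_log_mean: float = 3.0
    expr_log_sd: float = 0.6
    expr_noise_sd: float = 0.3
    driver_log2fc: float = 1.5
    expr_flank: int = 300_000

    def __post_init__(self) -> None:
        if len(self.tumor_types) != len(self.tumor_categories):
            raise ValueError("one category per tumor type required")
        total = sum(self.sv_type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("sv_type_mixture must sum to 1")
        if self.contig_length < L_IN:
            raise ValueError("contigs must be at least one prediction window long")


@dataclass
class GenomeArtifacts:
    """In-memory genome plus annotation produced by :func:`generate_genome`."""

    contigs: dict[str, str]
    boundaries: pd.DataFrame  # chrom, start, end, name
    anchors: pd.DataFrame  # chrom, start, end, strand
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, exons, protein_coding
    repeats: pd.DataFrame  # chrom, start, end, family

    def motif_positions(self, chrom: str) -> np.ndarray:
        b = self.boundaries.loc[self.boundaries.chrom == chrom, "start"].to_numpy()
        a = self.anchors.loc[self.anchors.chrom == chrom, "start"].to_numpy()
        return np.sort(np.concatenate([b, a]))


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    genome: GenomeArtifacts
    enhancers: list[RegulatoryElement]
    svs: list[StructuralVariant]
    metadata: pd.DataFrame
    truth: pd.DataFrame
    expression: pd.DataFrame  # genes x samples TPM


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _plant(seq: list[str], pos: int, motif: str) -> None:
    seq[pos : pos + len(motif)] = motif


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None
                    ) -> GenomeArtifacts:
    """Random contigs with planted boundary/anchor motifs and annotation."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[0])
    p = config.predictor_params
    mlen = len(p.boundary_motif)
    contigs: dict[str, str] = {}
    boundary_rows, anchor_rows = [], []

    for c in range(config.n_contigs):
        chrom = f"chr{c + 1}"
        seq = list(_random_sequence(rng, config.contig_length))
        # scrub chance occurrences of the motifs so planted copies are the
        # only ones the predictor can see
        _scrub_motifs(seq, p)
        pos = int(config.boundary_spacing_mean // 2)
        block_start = 0
        while pos + mlen < config.contig_length - config.boundary_spacing_mean // 4:
            _plant(seq, pos, p.boundary_motif)
            boundary_rows.append((chrom, pos, pos + mlen, "boundary"))
            # convergent anchor pair inside the block that just closed
            if rng.random() < config.anchor_rate and pos - block_start > 60_000:
                fwd = block_start + int(
                    rng.integers(20_000, (pos - block_start) // 2)
                )
                rev = pos - int(rng.integers(20_000, (pos - block_start) // 2))
                if rev - fwd > 10_000:
                    _plant(seq, fwd, p.anchor_motif)
                    _plant(seq, rev, revcomp(p.anchor_motif))
                    anchor_rows.append((chrom, fwd, fwd + mlen, "+"))
                    anchor_rows.append((chrom, rev, rev + mlen, "-"))
            block_start = pos
            step = int(
                rng.normal(config.boundary_spacing_mean, config.boundary_spacing_jitter)
            )
            pos += max(step, 100_000)
        # planting can create fresh chance matches straddling plant edges;
        # scrub those while leaving the planted copies untouched
        planted = [
            (r[1], r[1] + mlen) for r in boundary_rows if r[0] == chrom
        ] + [(r[1], r[1] + mlen) for r in anchor_rows if r[0] == chrom]
        _scrub_motifs(seq, p, keep=planted)
        contigs[chrom] = "".join(seq)

    boundaries = pd.DataFrame(boundary_rows, columns=["chrom", "start", "end", "name"])
    anchors = pd.DataFrame(anchor_rows, columns=["chrom", "start", "end", "strand"])
    genes = _generate_genes(config, contigs, boundaries, rng)
    repeats = _generate_repeats(config, contigs, rng)
    return GenomeArtifacts(contigs, boundaries, anchors, genes, repeats)


def _scrub_motifs(
    seq: list[str],
    p: ToyPredictorParams,
    keep: list[tuple[int, int]] | None = None,
) -> None:
    """Replace chance motif matches with neutral bases.

    ``keep`` lists planted motif intervals that must stay intact; a chance
    match overlapping a planted copy is broken at a base outside it.
    """
    keep = sorted(keep or [])

    def protected(pos: int) -> bool:
        for ks, ke in keep:
            if ks <= pos < ke:
                return True
        return False

    motifs = {p.boundary_motif, revcomp(p.boundary_motif),
              p.anchor_motif, revcomp(p.anchor_motif)}
    for _ in range(8):  # mutations can (rarely) create new matches
        s = "".join(seq)
        dirty = False
        for motif in motifs:
            i = s.find(motif)
            while i != -1:
                if not any(ks == i for ks, _ in keep):
                    for k in range(len(motif)):
                        if not protected(i + k):
                            seq[i + k] = "A" if seq[i + k] != "A" else "C"
                            dirty = True
                            break
                i = s.find(motif, i + 1)
        if not dirty:
            return


def _generate_genes(config, contigs, boundaries, rng) -> pd.DataFrame:
    rows = []
    chroms = list(contigs)
    gene_span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length_mean
    )
    for g in range(config.n_genes):
        chrom = chroms[g % len(chroms)]
        clen = len(contigs[chrom])
        start = int(rng.integers(50_000, clen - gene_span - 50_000))
        exon_starts, pos = [], start
        for _ in range(config.exons_per_gene):
            exon_starts.append(pos)
            pos += config.exon_length + int(
                rng.integers(config.intron_length_mean // 2,
                             config.intron_length_mean * 3 // 2)
            )
        end = exon_starts[-1] + config.exon_length
        exons = [(s, s + config.exon_length) for s in exon_starts]
        rows.append(
            {
                "gene_id": f"G{g + 1:04d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "exons": exons,
                "protein_coding": bool(rng.random() < 0.9),
            }
        )
    return pd.DataFrame(rows)


def _generate_repeats(config, contigs, rng) -> pd.DataFrame:
    rows = []
    chroms = list(contigs)
    for _ in range(config.n_repeats):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, len(contigs[chrom]) - config.repeat_length))
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + config.repeat_length,
                "family": config.repeat_families[
                    int(rng.integers(len(config.repeat_families)))
                ],
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def generate_epigenome(
    config: SimulationConfig,
    genome: GenomeArtifacts,
    rng: np.random.Generator | None = None,
) -> list[RegulatoryElement]:
    """Candidate enhancers with correlated, overdispersed count tracks.

    Counts are negative-binomial via a shared per-element gamma factor
    (the shared factor induces the ATAC/H3K27ac correlation).  Elements
    are placed preferentially near gene starts.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[1])
    if config.n_enhancers == 0:
        return []
    elements = []
    genes = genome.genes
    chroms = list(genome.contigs)
    disp = config.count_dispersion
    for i in range(config.n_enhancers):
        if len(genes) and rng.random() < config.enhancer_near_gene_prob:
            gene = genes.iloc[int(rng.integers(len(genes)))]
            tss = gene.start if gene.strand == "+" else gene.end
            start = int(tss + rng.integers(-config.enhancer_gene_flank,
                                           config.enhancer_gene_flank))
            chrom = gene.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, len(genome.contigs[chrom])))
        start = max(0, min(start, len(genome.contigs[chrom]) - config.enhancer_width))
        g = rng.gamma(shape=1.0 / disp, scale=disp)
        atac = int(rng.poisson(config.atac_mean * g))
        h3k = int(rng.poisson(config.h3k27ac_mean * g))
        elements.append(
            RegulatoryElement(chrom, start, start + config.enhancer_width,
                              atac, h3k, name=f"E{i + 1:04d}")
        )
    return elements


def _sample_plan(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic participant/sample/stage layout.

    Paired participants (one initial + one progressive sample) are spread
    across tumor types so that progressive samples make up
    ``progressive_fraction`` of the cohort and each type keeps exactly
    ``samples_per_type`` samples.
    """
    n_types = len(config.tumor_types)
    total = config.samples_per_type * n_types
    n_paired = int(round(config.progressive_fraction * total))
    paired_per_type = [0] * n_types
    for i in range(n_paired):
        paired_per_type[i % n_types] += 1
    rows, s, p = [], 0, 0
    for t, tumor_type in enumerate(config.tumor_types):
        category = config.tumor_categories[t]
        n_pair = paired_per_type[t]
        n_single = config.samples_per_type - 2 * n_pair
        if n_single < 0:
            raise ValueError("progressive_fraction too high for samples_per_type")
        for _ in range(n_pair):
            p += 1
            for stage in ("initial", "progressive"):
                s += 1
                rows.append((f"S{s:04d}", f"P{p:04d}", tumor_type, category, stage))
        for _ in range(n_single):
            p += 1
            s += 1
            rows.append((f"S{s:04d}", f"P{p:04d}", tumor_type, category, "initial"))
    return pd.DataFrame(
        rows, columns=["sample_id", "participant_id", "tumor_type",
                       "tumor_category", "stage"]
    )


def _driver_bins(config: SimulationConfig, genome: GenomeArtifacts,
                 rng: np.random.Generator) -> list[tuple[str, int]]:
    """Designated 1 Mb driver bins: boundary-containing, away from contig ends."""
    bs = config.rdr_bin_size
    flank = L_IN // 2 + 10_000
    candidates = []
    for chrom, seq in genome.contigs.items():
        for start in range(0, len(seq), bs):
            if start < flank or start + bs > len(seq) - flank:
                continue
            in_bin = genome.boundaries.query(
                "chrom == @chrom and start >= @start and end <= @start + @bs"
            )
            if len(in_bin) >= 1:
                candidates.append((chrom, start))
    if len(candidates) < config.n_driver_bins:
        raise ValueError("not enough boundary-containing bins for drivers")
    # spread over contigs: stable round-robin over chromosomes
    by_chrom: dict[str, list] = {}
    for chrom, start in candidates:
        by_chrom.setdefault(chrom, []).append((chrom, start))
    chosen, chroms = [], sorted(by_chrom)
    i = 0
    while len(chosen) < config.n_driver_bins:
        pool = by_chrom[chroms[i % len(chroms)]]
        if pool:
            pick = int(rng.integers(len(pool)))
            chosen.append(pool.pop(pick))
        i += 1
    return chosen


def _passenger_interval(config, genome, chrom: str, length: int,
                        rng: np.random.Generator) -> tuple[int, int]:
    """Uniform interval avoiding planted motifs and contig edges."""
    clen = len(genome.contigs[chrom])
    flank = L_IN // 2 + 1_000
    motifs = genome.motif_positions(chrom)
    for _ in range(200):
        start = int(rng.integers(flank, clen - flank - length))
        end = start + length
        i = np.searchsorted(motifs, start - 15)
        if i < len(motifs) and motifs[i] < end + 3:
            continue
        return start, end
    raise RuntimeError("could not place passenger SV clear of motifs")


def _ci(rng: np.random.Generator, width_max: int, width_min: int = 0
        ) -> tuple[int, int]:
    w = int(rng.integers(width_min, width_max + 1))
    return (-w, w)


def _make_passenger(config, genome, sample_id: str, sv_id: str, category_mix,
                    rng: np.random.Generator) -> StructuralVariant:
    chroms = list(genome.contigs)
    svtype = str(rng.choice(list(category_mix), p=list(category_mix.values())))
    chrom = chroms[int(rng.integers(len(chroms)))]
    length = int(
        np.exp(
            rng.uniform(np.log(config.passenger_len_min),
                        np.log(config.passenger_len_max))
        )
    )
    ci = _ci(rng, config.ci_passenger_max)
    if svtype == "BND":
        start, _ = _passenger_interval(config, genome, chrom, 1, rng)
        mate_chrom = chroms[int(rng.integers(len(chroms)))]
        mate_pos, _ = _passenger_interval(config, genome, mate_chrom, 1, rng)
        orient = ("t[p[", "t]p]", "]p]t", "[p[t")[int(rng.integers(4))]
        return StructuralVariant(
            id=sv_id, chrom=chrom, start=start, end=start + 1, svtype="BND",
            mate_chrom=mate_chrom, mate_pos=mate_pos,
            junction_orientation=orient, ci_pos=ci, ci_end=ci,
            sample_id=sample_id,
        )
    if svtype == "INS":
        start, _ = _passenger_interval(config, genome, chrom, 1, rng)
        return StructuralVariant(
            id=sv_id, chrom=chrom, start=start, end=start + 1, svtype="INS",
            inserted_seq=_random_sequence(rng, length), ci_pos=ci, ci_end=ci,
            sample_id=sample_id,
        )
    start, end = _passenger_interval(config, genome, chrom, length, rng)
    return StructuralVariant(
        id=sv_id, chrom=chrom, start=start, end=end, svtype=svtype,
        ci_pos=ci, ci_end=ci, sample_id=sample_id,
    )


def _category_mixtures(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Slightly tilted SV-type mixtures per tumor category (deterministic)."""
    cats = sorted(set(config.tumor_categories))
    base = config.sv_type_mixture
    out = {}
    for i, cat in enumerate(cats):
        tilt = {t: v * (1 + 0.1 * ((i + j) % 3 - 1)) for j, (t, v) in
                enumerate(sorted(base.items()))}
        total = sum(tilt.values())
        out[cat] = {t: v / total for t, v in tilt.items()}
    return out


def _driver_del(config, genome, chrom: str, motif_start: int, sample_id: str,
                sv_id: str, rng: np.random.Generator) -> StructuralVariant:
    """A DEL removing exactly the boundary motif at ``motif_start``."""
    mlen = len(config.predictor_params.boundary_motif)
    length = int(rng.integers(config.driver_len_min, config.driver_len_max))
    u = int(rng.integers(mlen + 10, length - 10))
    start, end = motif_start + mlen + 10 - u, motif_start + mlen + 10 - u + length
    motifs = genome.motif_positions(chrom)
    inside = motifs[(motifs >= start - mlen) & (motifs < end)]
    if len(inside) != 1:
        # fall back to a tight deletion around the motif
        start, end = motif_start - 200, motif_start + mlen + 200
    return StructuralVariant(
        id=sv_id, chrom=chrom, start=int(start), end=int(end), svtype="DEL",
        ci_pos=_ci(rng, config.ci_driver_max, config.ci_driver_min),
        ci_end=_ci(rng, config.ci_driver_max, config.ci_driver_min),
        sample_id=sample_id,
    )


def generate_cohort(
    config: SimulationConfig,
    genome: GenomeArtifacts,
    enhancers: list[RegulatoryElement] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[StructuralVariant], pd.DataFrame, pd.DataFrame]:
    """SV callsets, sample metadata and the planted-driver truth table."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[2])
    enhancers = enhancers or []
    meta = _sample_plan(config)
    meta["purity"] = np.where(
        rng.random(len(meta)) < 0.05, np.nan, rng.uniform(0.3, 0.9, len(meta))
    ).round(3)
    mixtures = _category_mixtures(config)

    svs: list[StructuralVariant] = []
    by_sample: dict[str, list[StructuralVariant]] = {}
    initial_of: dict[str, str] = {}  # participant -> initial sample id

    for row in meta.itertuples():
        sample = row.sample_id
        mix = mixtures[row.tumor_category]
        n_svs = max(1, int(rng.poisson(config.svs_per_sample_mean)))
        sample_svs: list[StructuralVariant] = []
        if row.stage == "progressive" and row.participant_id in initial_of:
            shared_pool = by_sample[initial_of[row.participant_id]]
            n_shared = int(round(config.shared_sv_fraction
                                 * min(len(shared_pool), n_svs)))
            idx = rng.choice(len(shared_pool), size=n_shared, replace=False)
            for k, i in enumerate(sorted(idx)):
                src = shared_pool[i]
                sample_svs.append(
                    replace(src, id=f"{sample}_sv{k + 1:03d}", sample_id=sample)
                )
        else:
            initial_of.setdefault(row.participant_id, sample)
        k = len(sample_svs)
        while len(sample_svs) < n_svs:
            k += 1
            sample_svs.append(
                _make_passenger(config, genome, sample, f"{sample}_sv{k:03d}",
                                mix, rng)
            )
        by_sample[sample] = sample_svs
        svs.extend(sample_svs)

    truth = _plant_drivers(config, genome, enhancers, meta, by_sample, svs, rng)
    return svs, meta, truth


def _plant_drivers(config, genome, enhancers, meta, by_sample, svs, rng
                   ) -> pd.DataFrame:
    """Boundary-deleting driver DELs in designated bins + enhancer drivers."""
    truth_rows = []
    bins = _driver_bins(config, genome, rng)
    samples = meta.sample_id.tolist()
    types = meta.set_index("sample_id").tumor_type

    used: set[str] = set()
    for chrom, bin_start in bins:
        in_bin = genome.boundaries.query(
            "chrom == @chrom and start >= @bin_start and "
            "end <= @bin_start + @config.rdr_bin_size"
        )
        motif_start = int(in_bin.iloc[0].start)
        # spread carriers over tumor types: seeded shuffle, then greedily
        # require the first two carriers to come from distinct types
        free = [s for s in samples if s not in used]
        order = [free[i] for i in rng.permutation(len(free))]
        carriers = []
        seen_types: list[str] = []
        for s in order:
            if len(carriers) == config.carriers_per_bin:
                break
            if types[s] in seen_types and len(set(seen_types)) < 2:
                continue
            carriers.append(s)
            seen_types.append(types[s])
        for s in carriers:
            used.add(s)
            sv_id = f"{s}_drv_{chrom}_{bin_start // config.rdr_bin_size}"
            sv = _driver_del(config, genome, chrom, motif_start, s, sv_id, rng)
            by_sample[s].append(sv)
            svs.append(sv)
            truth_rows.append(
                {
                    "sv_id": sv_id,
                    "sample_id": s,
                    "driver_class": "boundary",
                    "chrom": chrom,
                    "bin_start": bin_start,
                    "motif_start": motif_start,
                    "expr_sign": int(rng.choice([-1, 1])),
                }
            )

    # enhancer-proximal drivers: boundary deletions whose merged contacts sit
    # next to a high-activity enhancer (used by the ABC-weighting analyses)
    if config.n_enhancer_drivers and enhancers:
        acts = np.array([e.activity for e in enhancers])
        hi = [e for e, a in zip(enhancers, acts) if a >= np.quantile(acts, 0.75)]
        planted = 0
        bset = {(c, b) for c, b in bins}
        flank = L_IN // 2 + config.driver_len_max + 1_000
        for el in hi:
            if planted >= config.n_enhancer_drivers:
                break
            clen = len(genome.contigs[el.chrom])
            near = genome.boundaries.query(
                "chrom == @el.chrom and abs(start - @el.start) < 100_000 "
                "and start >= @flank and start <= @clen - @flank"
            )
            if near.empty:
                continue
            motif_start = int(near.iloc[0].start)
            bin_start = (motif_start // config.rdr_bin_size) * config.rdr_bin_size
            if (el.chrom, bin_start) in bset:
                continue
            free = [s for s in meta.sample_id if s not in used]
            if not free:
                break
            s = free[int(rng.integers(len(free)))]
            used.add(s)
            sv_id = f"{s}_edrv_{planted + 1}"
            sv = _driver_del(config, genome, el.chrom, motif_start, s, sv_id, rng)
            by_sample[s].append(sv)
            svs.append(sv)
            truth_rows.append(
                {
                    "sv_id": sv_id,
                    "sample_id": s,
                    "driver_class": "enhancer",
                    "chrom": el.chrom,
                    "bin_start": bin_start,
                    "motif_start": motif_start,
                    "expr_sign": int(rng.choice([-1, 1])),
                }
            )
            planted += 1

    # optional loop-anchor-deleting driver class: DELs removing one anchor
    # motif (loss of a loop rather than a boundary)
    if config.loop_anchor_drivers and len(genome.anchors):
        flank = L_IN // 2 + config.driver_len_max + 1_000
        bset = {(c, b) for c, b in bins}
        for anchor in genome.anchors.itertuples():
            clen = len(genome.contigs[anchor.chrom])
            if not flank <= anchor.start <= clen - flank:
                continue
            bin_start = (anchor.start // config.rdr_bin_size) * config.rdr_bin_size
            if (anchor.chrom, bin_start) in bset:
                continue
            free = [s for s in meta.sample_id if s not in used]
            carriers = [free[i] for i in
                        rng.permutation(len(free))[: config.carriers_per_bin]]
            for s in carriers:
                used.add(s)
                sv_id = f"{s}_adrv_{anchor.chrom}_{bin_start // config.rdr_bin_size}"
                sv = _driver_del(config, genome, anchor.chrom,
                                 int(anchor.start), s, sv_id, rng)
                by_sample[s].append(sv)
                svs.append(sv)
                truth_rows.append(
                    {
                        "sv_id": sv_id,
                        "sample_id": s,
                        "driver_class": "loop_anchor",
                        "chrom": anchor.chrom,
                        "bin_start": bin_start,
                        "motif_start": int(anchor.start),
                        "expr_sign": int(rng.choice([-1, 1])),
                    }
                )
            break
    return pd.DataFrame(truth_rows)


def generate_expression(
    config: SimulationConfig,
    genome: GenomeArtifacts,
    svs: list[StructuralVariant],
    truth: pd.DataFrame,
    meta: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """TPM table (genes x samples); driver carriers are shifted near drivers.

    Baseline per gene is log-normal; samples carrying a planted driver
    within ``expr_flank`` of a gene get the configured log2 fold change
    with the sign recorded in the truth table.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    genes = genome.genes
    samples = meta.sample_id.tolist()
    base = np.exp(rng.normal(config.expr_log_mean, config.expr_log_sd, len(genes)))
    noise = np.exp(
        rng.normal(0.0, config.expr_noise_sd, size=(len(genes), len(samples)))
    )
    tpm = pd.DataFrame(base[:, None] * noise,
                       index=genes.gene_id.tolist(), columns=samples)

    sv_by_id = {sv.id: sv for sv in svs}
    for t in truth.itertuples():
        sv = sv_by_id[t.sv_id]
        near = genes[
            (genes.chrom == sv.chrom)
            & (genes.end > sv.start - config.expr_flank)
            & (genes.start < sv.end + config.expr_flank)
        ]
        fold = 2.0 ** (t.expr_sign * config.driver_log2fc)
        for gid in near.gene_id:
            tpm.loc[gid, t.sample_id] *= fold
    return tpm


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """The full synthetic study as a pure function of the config."""
    ss = np.random.SeedSequence(config.seed).spawn(4)
    genome = generate_genome(config, np.random.default_rng(ss[0]))
    enhancers = generate_epigenome(config, genome, np.random.default_rng(ss[1]))
    svs, meta, truth = generate_cohort(
        config, genome, enhancers, np.random.default_rng(ss[2])
    )
    expression = generate_expression(
        config, genome, svs, truth, meta, np.random.default_rng(ss[3])
    )
    return SyntheticStudy(config, genome, enhancers, svs, meta, truth, expression)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Serialize every artifact as plain-text standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    with fasta.open("w") as fh:
        for chrom, seq in study.genome.contigs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = fasta

    motifs = pd.concat(
        [
            study.genome.boundaries.assign(strand="+"),
            study.genome.anchors.assign(name="anchor"),
        ]
    )[["chrom", "start", "end", "name", "strand"]]
    motifs.insert(4, "score", 0)
    motifs.to_csv(out / "motifs.bed", sep="\t", header=False, index=False)
    paths["motifs"] = out / "motifs.bed"

    paths["genes"] = out / "genes.gff3"
    _write_gff3(study.genome.genes, paths["genes"])

    rep = study.genome.repeats.copy()
    rep["score"] = 0
    rep["strand"] = "+"
    rep[["chrom", "start", "end", "family", "score", "strand"]].to_csv(
        out / "repeats.bed", sep="\t", header=False, index=False
    )
    paths["repeats"] = out / "repeats.bed"

    enh_rows = [
        (e.chrom, e.start, e.end, e.name, 0, ".", e.atac_count, e.h3k27ac_count)
        for e in study.enhancers
    ]
    pd.DataFrame(enh_rows).to_csv(out / "enhancers.bed", sep="\t",
                                  header=False, index=False)
    paths["enhancers"] = out / "enhancers.bed"

    contigs = {c: len(s) for c, s in study.genome.contigs.items()}
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for sample, group in _group_by_sample(study.svs).items():
        write_sv_vcf(group, vcf_dir / f"{sample}.vcf", contigs)
    paths["vcf_dir"] = vcf_dir

    study.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    paths["metadata"] = out / "metadata.tsv"
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth.tsv"
    study.expression.rename_axis("gene_id").to_csv(out / "expression.tsv", sep="\t")
    paths["expression"] = out / "expression.tsv"
    return paths


def _group_by_sample(svs: list[StructuralVariant]) -> dict[str, list[StructuralVariant]]:
    groups: dict[str, list[StructuralVariant]] = {}
    for sv in svs:
        groups.setdefault(sv.sample_id, []).append(sv)
    return groups


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes.itertuples():
        biotype = "protein_coding" if g.protein_coding else "lncRNA"
        lines.append(
            f"{g.chrom}\tsvfold\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};biotype={biotype}"
        )
        for i, (es, ee) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\tsvfold\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.e{i};Parent={g.gene_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
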