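"""Recurrently disrupted region (RDR) discovery.

The genome is divided into 1 Mb bins; per bin and per sample only the
highest-scoring variant counts, giving a sample-by-bin matrix of maximum
disruption scores.  UMAP embedding of the rows followed by density
clustering (DBSCAN) surfaces groups of samples that share a disrupted
bin; a bin every cluster member disrupts past the score cutoff is a
candidate RDR, and each candidate's recurrence is tested against the
genome-wide per-bin rate with a one-sided binomial test
(Benjamini-Hochberg corrected across bins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import DBSCAN
from statsmodels.stats.multitest import multipletests

from .predictor import ContactMap

BIN_SIZE_DEFAULT = 1_000_000


def _bin_ids(chrom_sizes: dict[str, int], bin_size: int) -> list[tuple[str, int]]:
    out = []
    for chrom, size in chrom_sizes.items():
        out.extend((chrom, s) for s in range(0, size, bin_size))
    return out


def build_bin_matrix(
    scored: pd.DataFrame,
    chrom_sizes: dict[str, int],
    metric: str = "mse",
    aggregate: str = "median",
    bin_size: int = BIN_SIZE_DEFAULT,
) -> pd.DataFrame:
    """Sample-by-bin matrix of per-sample maximum disruption scores.

    ``scored`` is the scored-variants table (one row per variant with
    sample_id, chrom, start, end, mate_chrom, mate_pos and score columns).
    An SV contributes its score to every bin its interval intersects; a
    BND contributes at both breakpoint loci.  Columns are labelled
    "chrom:start" and ordered genomically.
    """
    if scored.empty:
        raise ValueError("no scored variants")
    col = f"{metric}_{aggregate}"
    if col not in scored.columns:
        raise KeyError(f"scored table lacks column {col!r}")
    bins = _bin_ids(chrom_sizes, bin_size)
    index = {b: i for i, b in enumerate(bins)}
    samples = sorted(scored.sample_id.unique())
    srow = {s: i for i, s in enumerate(samples)}
    m = np.zeros((len(samples), len(bins)))

    for row in scored.itertuples():
        score = getattr(row, col)
        loci: list[tuple[str, int, int]] = []
        if row.svtype == "BND":
            loci.append((row.chrom, row.start, row.start + 1))
            if row.mate_chrom is not None and not pd.isna(row.mate_pos):
                loci.append((row.mate_chrom, int(row.mate_pos),
                             int(row.mate_pos) + 1))
        else:
            loci.append((row.chrom, int(row.start), int(row.end)))
        i = srow[row.sample_id]
        for chrom, start, end in loci:
            for b in range(start // bin_size, (max(end - 1, start)) // bin_size + 1):
                j = index.get((chrom, b * bin_size))
                if j is not None and score > m[i, j]:
                    m[i, j] = score
    cols = [f"{c}:{s}" for c, s in bins]
    return pd.DataFrame(m, index=samples, columns=cols)


@dataclass
class ClusterResult:
    labels: pd.Series  # sample -> cluster label (-1 = background)
    embedding: pd.DataFrame  # sample x (umap1, umap2)

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sample, lab in self.labels.items():
            if lab != -1:
                out.setdefault(int(lab), []).append(sample)
        return out


def embed_and_cluster(
    matrix: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 10,
    min_dist: float = 0.1,
    eps: float = 1.0,
    min_samples: int = 4,
) -> ClusterResult:
    """UMAP embedding of the sample rows followed by DBSCAN.

    Deterministic given ``seed``.  Samples in no dense group get label -1
    (background).  An all-zero matrix yields only background.
    """
    if len(matrix) < 10:
        raise ValueError("need at least 10 samples to embed")
    values = matrix.to_numpy(dtype=float)
    if not values.any():
        labels = pd.Series(-1, index=matrix.index)
        coords = pd.DataFrame(0.0, index=matrix.index, columns=["umap1", "umap2"])
        return ClusterResult(labels, coords)

    import umap  # deferred: slow import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=min(n_neighbors, len(matrix) - 1),
            min_dist=min_dist,
            n_components=2,
            random_state=seed,
        )
        emb = reducer.fit_transform(values)
    lab = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(emb)
    labels = pd.Series(lab, index=matrix.index)
    coords = pd.DataFrame(emb, index=matrix.index, columns=["umap1", "umap2"])
    return ClusterResult(labels, coords)


def driver_bin(
    cluster_samples: list[str], matrix: pd.DataFrame, cutoff: float
) -> str | None:
    """The bin every cluster member disrupts past ``cutoff`` (or None).

    Ties are broken toward the smallest genomic coordinate (column order).
    """
    if not cluster_samples:
        raise ValueError("cluster is empty")
    sub = matrix.loc[cluster_samples]
    common = (sub >= cutoff).all(axis=0)
    hits = [c for c in matrix.columns if common[c]]
    return hits[0] if hits else None


def recurrence_test(
    matrix: pd.DataFrame, cutoff: float
) -> pd.DataFrame:
    """Per-bin recurrence statistics against the genome-wide rate.

    For every bin: ``n_mutated`` = samples with any SV there (entry > 0),
    ``n_disrupted`` = samples past the cutoff.  One-sided binomial tests
    compare each count against the genome-wide mean per-bin rate, with BH
    correction across bins (q_mutated / q_disrupted).
    """
    n_samples = len(matrix)
    n_mut = (matrix > 0).sum(axis=0)
    n_dis = (matrix >= cutoff).sum(axis=0) if cutoff > 0 else n_mut
    p_mut_rate = float(n_mut.mean()) / n_samples
    p_dis_rate = float(n_dis.mean()) / n_samples

    def btest(k: int, rate: float) -> float:
        if k == 0:
            return 1.0
        rate = min(max(rate, 1e-12), 1.0)
        return stats.binomtest(int(k), n_samples, rate,
                               alternative="greater").pvalue

    p_mut = np.array([btest(k, p_mut_rate) for k in n_mut])
    p_dis = np.array([btest(k, p_dis_rate) for k in n_dis])
    q_mut = multipletests(p_mut, method="fdr_bh")[1]
    q_dis = multipletests(p_dis, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "n_mutated": n_mut,
            "n_disrupted": n_dis,
            "p_mutated": p_mut,
            "p_disrupted": p_dis,
            "q_mutated": q_mut,
            "q_disrupted": q_dis,
        },
        index=matrix.columns,
    )


def reference_quality_filter(
    predicted: ContactMap,
    experimental: ContactMap | np.ndarray | None,
    threshold: float = 0.5,
) -> tuple[bool, set[str]]:
    """Keep/drop decision for a bin based on REF-map concordance.

    Bins whose predicted reference map correlates poorly (< threshold)
    with a supplied experimental (or ground-truth) map are dropped; with
    no map supplied the bin is kept with an ``unchecked`` flag.
    """
    if experimental is None:
        return True, {"unchecked"}
    exp = experimental.values if isinstance(experimental, ContactMap) else experimental
    dist = np.abs(
        np.subtract.outer(np.arange(predicted.values.shape[0]),
                          np.arange(predicted.values.shape[0]))
    )
    mask = np.triu(dist >= ContactMap.DIAG_BAND)
    a, b = predicted.values[mask], np.asarray(exp, dtype=float)[mask]
    if a.std() == 0 or b.std() == 0:
        return False, {"zero_variance"}
    r = float(np.corrcoef(a, b)[0, 1])
    return r >= threshold, set()


@dataclass
class RdrCall:
    """One recurrently disrupted region."""

    bin_id: str
    samples: list[str]
    tumor_types: list[str]
    n_mutated: int
    n_disrupted: int
    p_mutated: float
    p_disrupted: float
    q_mutated: float
    q_disrupted: float
    quality: str = "ok"

    def __post_init__(self) -> None:
        if not self.n_disrupted <= self.n_mutated:
            raise ValueError("n_disrupted cannot exceed n_mutated")


@dataclass
class RdrConfig:
    bin_size: int = BIN_SIZE_DEFAULT
    metric: str = "mse"
    aggregate: str = "median"
    cutoff_percentile: float = 98.8  # of the cohort score vector
    umap_seed: int = 0
    umap_n_neighbors: int = 10
    dbscan_eps: float = 1.0
    dbscan_min_samples: int = 4
    alpha: float = 0.05
    quality_threshold: float = 0.5


def find_rdrs(
    scored: pd.DataFrame,
    chrom_sizes: dict[str, int],
    meta: pd.DataFrame | None = None,
    config: RdrConfig | None = None,
    cutoff: float | None = None,
    bin_quality: dict[str, bool] | None = None,
) -> tuple[list[RdrCall], pd.DataFrame, ClusterResult]:
    """The full RDR procedure: matrix -> embed -> cluster -> test.

    ``cutoff`` overrides the percentile-derived score cutoff.
    ``bin_quality`` maps bin ids to keep/drop decisions precomputed with
    :func:`reference_quality_filter`; bins marked False are dropped, bins
    absent from the mapping are kept flagged "unchecked".  Returns the RDR
    calls (q_disrupted < alpha), the per-bin recurrence table and the
    clustering, so review artifacts can be exported.
    """
    config = config or RdrConfig()
    matrix = build_bin_matrix(
        scored, chrom_sizes, metric=config.metric,
        aggregate=config.aggregate, bin_size=config.bin_size,
    )
    if cutoff is None:
        col = f"{config.metric}_{config.aggregate}"
        cutoff = float(np.percentile(scored[col], config.cutoff_percentile))
    clustering = embed_and_cluster(
        matrix,
        seed=config.umap_seed,
        n_neighbors=config.umap_n_neighbors,
        eps=config.dbscan_eps,
        min_samples=config.dbscan_min_samples,
    )
    table = recurrence_test(matrix, cutoff)

    types = (
        meta.set_index("sample_id").tumor_type
        if meta is not None
        else pd.Series(dtype=object)
    )
    calls: list[RdrCall] = []
    seen_bins: set[str] = set()
    for _, samples in sorted(clustering.clusters().items()):
        b = driver_bin(samples, matrix, cutoff)
        if b is None or b in seen_bins:
            continue
        row = table.loc[b]
        if row.q_disrupted >= config.alpha:
            continue
        quality = "ok"
        if bin_quality is not None:
            if b not in bin_quality:
                quality = "unchecked"
            elif not bin_quality[b]:
                continue  # reference map did not match: drop the bin
        seen_bins.add(b)
        members = sorted(samples)
        calls.append(
            RdrCall(
                bin_id=b,
                samples=members,
                tumor_types=sorted({str(types.get(s, "?")) for s in members}),
                n_mutated=int(row.n_mutated),
                n_disrupted=int(row.n_disrupted),
                p_mutated=float(row.p_mutated),
                p_disrupted=float(row.p_disrupted),
                q_mutated=float(row.q_mutated),
                q_disrupted=float(row.q_disrupted),
                quality=quality,
            )
        )
    return calls, table, clustering
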