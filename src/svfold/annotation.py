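"""Loaders for gene, repeat and peak annotation files."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_genes_gff3(path: str | Path) -> pd.DataFrame:
    """Load gene models (gene + exon features) from GFF3.

    Returns one row per gene with 0-based half-open coordinates, an
    ``exons`` list of (start, end) tuples and a ``protein_coding`` flag
    (from the ``biotype`` attribute; genes without one count as coding).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start - 1, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        ]
        biotype = (gene.attributes.get("biotype") or ["protein_coding"])[0]
        rows.append(
            {
                "gene_id": gene.id,
                "chrom": gene.seqid,
                "start": gene.start - 1,
                "end": gene.end,
                "strand": gene.strand,
                "exons": exons,
                "protein_coding": biotype == "protein_coding",
            }
        )
    return pd.DataFrame(rows)


def read_repeats_bed(path: str | Path) -> pd.DataFrame:
    """Repeat annotation BED with the family label in the name column."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "family", "score", "strand"],
        usecols=[0, 1, 2, 3],
    )
    return df


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Peak intervals (first three BED columns; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df
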