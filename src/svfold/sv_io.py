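"""Reading, validating, filtering and writing structural-variant calls.

The expected input dialect is a Manta-style somatic VCF: symbolic ALTs
for DEL/DUP/INV/INS with ``SVTYPE``/``END``/``SVLEN`` INFO keys, and
breakends (BND) as mate pairs in bracket notation linked by ``MATEID``.
Internally every coordinate is 0-based half-open; VCF input/output is
1-based.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

log = logging.getLogger(__name__)

SV_TYPES = frozenset({"DEL", "DUP", "INV", "INS", "BND"})

#: The four breakend junction classes of the VCF bracket notation.
#: ``t`` is the local (anchor) base, ``p`` the mate locus.
BND_ORIENTATIONS = ("t[p[", "t]p]", "]p]t", "[p[t")

_BRACKET_RE = re.compile(
    r"^(?P<t1>[A-Za-z]*)(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<t2>[A-Za-z]*)$"
)


@dataclass
class StructuralVariant:
    """One structural-variant call.

    ``start``/``end`` are 0-based half-open: for DEL/DUP/INV ``end`` is the
    VCF END; for INS and BND ``end = start + 1``.  BND records carry the
    partner locus and the junction orientation (one of
    :data:`BND_ORIENTATIONS`); ``mate_pos`` is 0-based and denotes the base
    immediately adjacent to the junction on the mate side.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    inserted_seq: str = ""
    mate_chrom: str | None = None
    mate_pos: int | None = None
    junction_orientation: str | None = None
    ci_pos: tuple[int, int] = (0, 0)
    ci_end: tuple[int, int] = (0, 0)
    filter_status: str = "PASS"
    sample_id: str = ""
    mate_id: str | None = None
    mate_resolved: bool = True

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r}")
        if self.svtype in ("DEL", "DUP", "INV") and not self.start < self.end:
            raise ValueError(f"{self.svtype} requires start < end")
        if self.svtype == "BND":
            if self.junction_orientation not in BND_ORIENTATIONS:
                raise ValueError(
                    f"BND orientation {self.junction_orientation!r} invalid"
                )

    @property
    def breakpoint_key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.svtype)


@dataclass
class FilterReport:
    """Per-reason exclusion counts; conserved against the input size."""

    input_count: int = 0
    non_pass: int = 0
    over_length: int = 0
    duplicate_breakpoints: int = 0
    unresolved_mate: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input_count": self.input_count,
            "non_pass": self.non_pass,
            "over_length": self.over_length,
            "duplicate_breakpoints": self.duplicate_breakpoints,
            "unresolved_mate": self.unresolved_mate,
            "retained": self.retained,
        }

    def check_conserved(self) -> bool:
        excluded = (
            self.non_pass
            + self.over_length
            + self.duplicate_breakpoints
            + self.unresolved_mate
        )
        return self.retained + excluded == self.input_count


def parse_bracket_alt(alt: str) -> tuple[str, int, str, str]:
    """Parse a breakend ALT string.

    Returns ``(mate_chrom, mate_pos_0based, orientation, t)`` where
    orientation is one of :data:`BND_ORIENTATIONS` and ``t`` the anchor
    base(s).  Raises ``ValueError`` on malformed input.
    """
    m = _BRACKET_RE.match(alt)
    if not m:
        raise ValueError(f"malformed breakend ALT {alt!r}")
    if m.group("b1") != m.group("b2"):
        raise ValueError(f"mismatched brackets in ALT {alt!r}")
    t1, t2, bracket = m.group("t1"), m.group("t2"), m.group("b1")
    if bool(t1) == bool(t2):
        raise ValueError(f"ALT {alt!r} must have the anchor base on one side")
    if t1:
        orientation = "t[p[" if bracket == "[" else "t]p]"
        t = t1
    else:
        orientation = "[p[t" if bracket == "[" else "]p]t"
        t = t2
    return m.group("chrom"), int(m.group("pos")) - 1, orientation, t


def _info_get(info, key: str):
    """info.get tolerant of keys missing from the VCF header entirely."""
    try:
        return info.get(key)
    except ValueError:
        return None


def _ci(info, key: str) -> tuple[int, int]:
    v = _info_get(info, key)
    if v is None:
        return (0, 0)
    return int(v[0]), int(v[1])


def read_sv_vcf(
    path: str | Path,
    sample_id: str = "",
    errors: list[str] | None = None,
) -> list[StructuralVariant]:
    """Read structural variants from a (single-sample) VCF.

    BND mate pairs are joined via MATEID and emitted once, anchored on the
    mate with the smaller (chrom, pos).  Malformed records are collected
    into ``errors`` (if given) and skipped rather than raised.
    """
    if errors is None:
        errors = []
    variants: list[StructuralVariant] = []
    bnds: dict[str, StructuralVariant] = {}

    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                log.warning("record %s lacks SVTYPE; rejected", rec.id)
                errors.append(f"{rec.id or rec.pos}: missing SVTYPE")
                continue
            filt = ";".join(rec.filter.keys()) or "PASS"
            rid = rec.id or f"{rec.chrom}:{rec.pos}:{svtype}"
            try:
                if svtype == "BND":
                    alt = rec.alts[0]
                    mate_chrom, mate_pos, orient, _ = parse_bracket_alt(alt)
                    mate_id = _info_get(rec.info, "MATEID")
                    if isinstance(mate_id, tuple):
                        mate_id = mate_id[0]
                    sv = StructuralVariant(
                        id=rid,
                        chrom=rec.chrom,
                        start=rec.start,
                        end=rec.start + 1,
                        svtype="BND",
                        mate_chrom=mate_chrom,
                        mate_pos=mate_pos,
                        junction_orientation=orient,
                        ci_pos=_ci(rec.info, "CIPOS"),
                        ci_end=_ci(rec.info, "CIEND"),
                        filter_status=filt,
                        sample_id=sample_id,
                        mate_id=mate_id,
                    )
                    bnds[rid] = sv
                elif svtype == "INS":
                    alt = rec.alts[0] if rec.alts else ""
                    if alt and not alt.startswith("<"):
                        inserted = alt[len(rec.ref):]
                    else:
                        svlen = _info_get(rec.info, "SVLEN")
                        if svlen is None:
                            log.warning(
                                "symbolic INS %s without SVLEN; rejected", rid
                            )
                            errors.append(f"{rid}: symbolic INS without SVLEN")
                            continue
                        n = abs(int(svlen[0] if isinstance(svlen, tuple) else svlen))
                        inserted = "N" * n
                    variants.append(
                        StructuralVariant(
                            id=rid,
                            chrom=rec.chrom,
                            start=rec.start,
                            end=rec.start + 1,
                            svtype="INS",
                            inserted_seq=inserted,
                            ci_pos=_ci(rec.info, "CIPOS"),
                            ci_end=_ci(rec.info, "CIEND"),
                            filter_status=filt,
                            sample_id=sample_id,
                        )
                    )
                elif svtype in ("DEL", "DUP", "INV"):
                    variants.append(
                        StructuralVariant(
                            id=rid,
                            chrom=rec.chrom,
                            start=rec.start,
                            end=rec.stop,
                            svtype=svtype,
                            ci_pos=_ci(rec.info, "CIPOS"),
                            ci_end=_ci(rec.info, "CIEND"),
                            filter_status=filt,
                            sample_id=sample_id,
                        )
                    )
                else:
                    errors.append(f"{rid}: unknown SVTYPE {svtype}")
            except ValueError as exc:
                log.warning("record %s rejected: %s", rid, exc)
                errors.append(f"{rid}: {exc}")

    variants.extend(_join_bnd_mates(bnds))
    return variants


def _join_bnd_mates(bnds: dict[str, StructuralVariant]) -> list[StructuralVariant]:
    """Emit each BND mate pair once; unmated records are flagged."""
    out: list[StructuralVariant] = []
    seen: set[str] = set()
    for rid, sv in bnds.items():
        if rid in seen:
            continue
        mate = bnds.get(sv.mate_id) if sv.mate_id else None
        if mate is None:
            out.append(replace(sv, mate_resolved=False))
            seen.add(rid)
            continue
        seen.add(rid)
        seen.add(mate.id)
        # anchor on the mate with the smaller (chrom, pos)
        primary = min((sv, mate), key=lambda v: (v.chrom, v.start, v.id))
        out.append(primary)
    return out


def sv_length(sv: StructuralVariant) -> int | None:
    """SV length in bp; None for BND (undefined across chromosomes)."""
    if sv.svtype == "BND":
        return None
    if sv.svtype == "INS":
        return len(sv.inserted_seq)
    return sv.end - sv.start


def filter_variants(
    svs: list[StructuralVariant],
    max_len: int = 500_000,
    duplicate_scope: str = "sample",
    duplicate_mode: str = "remove_all",
) -> tuple[list[StructuralVariant], FilterReport]:
    """Apply the callset filters used throughout the pipeline.

    Removes, in order: non-PASS calls; BNDs whose mate record was absent;
    non-BND variants longer than ``max_len`` (default 500 kb, beyond which
    too little of the prediction window remains informative); and variants
    sharing identical breakpoints ``(chrom, start, end, svtype)`` with
    another variant.  Duplicate removal drops *every* member of the group
    (``duplicate_mode="keep_one"`` keeps the first instead); the comparison
    scope is per sample by default (``duplicate_scope="cohort"`` widens it).
    """
    report = FilterReport(input_count=len(svs))
    stage: list[StructuralVariant] = []
    for sv in svs:
        if sv.filter_status != "PASS":
            report.non_pass += 1
        elif sv.svtype == "BND" and not sv.mate_resolved:
            report.unresolved_mate += 1
        elif sv.svtype != "BND" and sv.end - sv.start > max_len:
            report.over_length += 1
        else:
            stage.append(sv)

    def dup_key(sv: StructuralVariant):
        key = sv.breakpoint_key
        return (sv.sample_id, *key) if duplicate_scope == "sample" else key

    counts = Counter(dup_key(sv) for sv in stage)
    retained: list[StructuralVariant] = []
    kept_one: set = set()
    for sv in stage:
        k = dup_key(sv)
        if counts[k] > 1:
            if duplicate_mode == "keep_one" and k not in kept_one:
                kept_one.add(k)
                retained.append(sv)
            else:
                report.duplicate_breakpoints += 1
        else:
            retained.append(sv)
    report.retained = len(retained)
    assert report.check_conserved()
    return retained, report


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Load the sample metadata TSV.

    Requires columns sample_id, participant_id, tumor_type, tumor_category,
    stage (initial|progressive), purity (fraction or empty).
    """
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "participant_id": str})
    required = {
        "sample_id",
        "participant_id",
        "tumor_type",
        "tumor_category",
        "stage",
        "purity",
    }
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = set(meta["stage"]) - {"initial", "progressive"}
    if bad:
        raise ValueError(f"invalid stage values: {sorted(bad)}")
    if meta.duplicated("sample_id").any():
        raise ValueError("sample_id values must be unique")
    return meta


def write_sv_vcf(
    svs: list[StructuralVariant],
    path: str | Path,
    contigs: dict[str, int],
) -> None:
    """Write variants to a VCF v4.2 file (plain text, 1-based coordinates).

    BND variants are expanded back into both bracket-notation mates.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of SV">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="CI around POS">',
        '##INFO=<ID=CIEND,Number=2,Type=Integer,Description="CI around END">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=INS,Description="Insertion">',
    ]
    for name, length in contigs.items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    rows: list[tuple[str, int, str]] = []
    for sv in svs:
        ci = f"CIPOS={sv.ci_pos[0]},{sv.ci_pos[1]};CIEND={sv.ci_end[0]},{sv.ci_end[1]}"
        if sv.svtype == "BND":
            rows.extend(_bnd_rows(sv, ci))
        elif sv.svtype == "INS":
            info = f"SVTYPE=INS;SVLEN={len(sv.inserted_seq)};{ci}"
            alt = "N" + sv.inserted_seq if sv.inserted_seq.strip("N") else "<INS>"
            rows.append(
                (
                    sv.chrom,
                    sv.start + 1,
                    f"{sv.chrom}\t{sv.start + 1}\t{sv.id}\tN\t{alt}\t.\t"
                    f"{sv.filter_status}\t{info}",
                )
            )
        else:
            info = f"SVTYPE={sv.svtype};END={sv.end};{ci}"
            rows.append(
                (
                    sv.chrom,
                    sv.start + 1,
                    f"{sv.chrom}\t{sv.start + 1}\t{sv.id}\tN\t<{sv.svtype}>\t.\t"
                    f"{sv.filter_status}\t{info}",
                )
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def _bnd_rows(sv: StructuralVariant, ci: str) -> list[tuple[str, int, str]]:
    """Both mate records for one joined BND variant."""
    a_id, b_id = f"{sv.id}_1", f"{sv.id}_2"
    a_pos, b_pos = sv.start + 1, sv.mate_pos + 1
    orient = sv.junction_orientation
    # ALT for the anchor record; the mate record gets the reciprocal class.
    reciprocal = {"t[p[": "]p]t", "]p]t": "t[p[", "t]p]": "t]p]", "[p[t": "[p[t"}
    mate_locus = f"{sv.mate_chrom}:{b_pos}"
    own_locus = f"{sv.chrom}:{a_pos}"

    def alt_for(orientation: str, locus: str) -> str:
        if orientation == "t[p[":
            return f"N[{locus}["
        if orientation == "t]p]":
            return f"N]{locus}]"
        if orientation == "]p]t":
            return f"]{locus}]N"
        return f"[{locus}[N"

    info_a = f"SVTYPE=BND;MATEID={b_id};{ci}"
    info_b = f"SVTYPE=BND;MATEID={a_id};{ci}"
    row_a = (
        sv.chrom,
        a_pos,
        f"{sv.chrom}\t{a_pos}\t{a_id}\tN\t{alt_for(orient, mate_locus)}\t.\t"
        f"{sv.filter_status}\t{info_a}",
    )
    row_b = (
        sv.mate_chrom,
        b_pos,
        f"{sv.mate_chrom}\t{b_pos}\t{b_id}\tN\t{alt_for(reciprocal[orient], own_locus)}\t.\t"
        f"{sv.filter_status}\t{info_b}",
    )
    return [row_a, row_b]
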