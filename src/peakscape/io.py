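"""Readers and writers for the plain-text formats the pipeline consumes.

BED/narrowPeak/bedGraph are 0-based half-open on disk and in memory, so
parsing preserves coordinates bit-exactly.  All TSV tables are
tab-delimited with a header row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix, GeneModel, GenomicInterval, Peak

_DIALECTS = {"bed", "narrowPeak", "bedgraph"}


@dataclass(frozen=True)
class BedGraphRecord:
    interval: GenomicInterval
    value: float


def read_intervals(path: str | os.PathLike, dialect: str = "bed"):
    """Read BED3/BED6, narrowPeak (10 column) or bedGraph records.

    Returns a list of :class:`Peak` for bed/narrowPeak (score populated from
    column 5 when present) and a list of :class:`BedGraphRecord` for
    bedGraph.  An empty file yields an empty list.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected {_DIALECTS}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                records.append(_parse_line(fields, dialect, lineno))
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed {dialect} line {lineno}: {exc}"
                ) from exc
    return records


def _parse_line(fields: list[str], dialect: str, lineno: int):
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    if end <= start:
        raise ValueError(f"end {end} <= start {start}")
    if dialect == "bedgraph":
        return BedGraphRecord(
            GenomicInterval(chrom, start, end), float(fields[3])
        )
    name = fields[3] if len(fields) > 3 and fields[3] != "." else f"rec{lineno}"
    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
    strand = fields[5] if len(fields) > 5 else "."
    summit = None
    if dialect == "narrowPeak":
        if len(fields) < 10:
            raise ValueError("narrowPeak requires 10 columns")
        summit = int(fields[9])
        if summit == -1:
            summit = None
    return Peak(
        id=name,
        interval=GenomicInterval(chrom, start, end, strand),
        summit_offset=summit,
        score=score,
    )


def write_bed(
    peaks: list[Peak], path: str | os.PathLike, header: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"#{header}\n")
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t"
                f"{p.score:g}\t{iv.strand}\n"
            )


def write_narrowpeak(peaks: list[Peak], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t{p.score:g}\t"
                f"{iv.strand}\t0\t-1\t-1\t{summit}\n"
            )


def write_bedgraph(
    records: list[BedGraphRecord], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.value:g}\n")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from the GTF-lite TSV (one row per gene).

    Columns: gene_id, symbol, chrom, strand, start, end, exon_starts,
    exon_ends (comma-separated); optional utr5_starts/utr5_ends and
    utr3_starts/utr3_ends columns in the same encoding.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    genes = []
    for row in df.itertuples(index=False):
        iv = GenomicInterval(
            row.chrom, int(row.start), int(row.end), row.strand
        )
        exons = _parse_interval_lists(
            row.chrom, row.exon_starts, row.exon_ends, row.strand
        )
        utr5 = utr3 = []
        if hasattr(row, "utr5_starts"):
            utr5 = _parse_interval_lists(
                row.chrom, row.utr5_starts, row.utr5_ends, row.strand
            )
        if hasattr(row, "utr3_starts"):
            utr3 = _parse_interval_lists(
                row.chrom, row.utr3_starts, row.utr3_ends, row.strand
            )
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                symbol=row.symbol,
                interval=iv,
                exons=exons,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def _parse_interval_lists(chrom, starts, ends, strand):
    if starts is None or pd.isna(starts) or starts == "":
        return []
    s = [int(x) for x in str(starts).rstrip(",").split(",")]
    e = [int(x) for x in str(ends).rstrip(",").split(",")]
    return [GenomicInterval(chrom, a, b, strand) for a, b in zip(s, e)]


def write_gene_models(genes: list[GeneModel], path: str | os.PathLike) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.interval.chrom,
                "strand": g.interval.strand,
                "start": g.interval.start,
                "end": g.interval.end,
                "exon_starts": ",".join(str(e.start) for e in g.exons),
                "exon_ends": ",".join(str(e.end) for e in g.exons),
                "utr5_starts": ",".join(str(u.start) for u in g.utr5),
                "utr5_ends": ",".join(str(u.end) for u in g.utr5),
                "utr3_starts": ",".join(str(u.start) for u in g.utr3),
                "utr3_ends": ",".join(str(u.end) for u in g.utr3),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices


def read_counts(
    counts_path: str | os.PathLike, samples_path: str | os.PathLike
) -> CountMatrix:
    """Read a feature-by-sample count TSV plus a sample→condition table."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    groups = dict(zip(samples["sample_id"], samples["condition"]))
    return CountMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        counts=df.to_numpy(),
        sample_groups=groups,
    )


def write_counts(
    cm: CountMatrix,
    counts_path: str | os.PathLike,
    samples_path: str | os.PathLike | None = None,
    feature_label: str = "feature_id",
) -> None:
    df = cm.to_frame()
    df.index.name = feature_label
    df.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        pd.DataFrame(
            {
                "sample_id": cm.sample_ids,
                "condition": [cm.sample_groups[s] for s in cm.sample_ids],
            }
        ).to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT gene-set file: set name, description, then members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has <3 columns")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name in sets:
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# motif tables


def read_motif_membership(path: str | os.PathLike) -> dict[str, list[str]]:
    """Motif→peak membership TSV with columns motif_id, peak_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for motif, peak in zip(df["motif_id"], df["peak_id"]):
        out.setdefault(motif, []).append(peak)
    return out


def write_motif_membership(
    membership: dict[str, list[str]], path: str | os.PathLike
) -> None:
    rows = [
        {"motif_id": m, "peak_id": p}
        for m in membership
        for p in membership[m]
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peak_gc(path: str | os.PathLike) -> dict[str, float]:
    """Per-peak GC table (peak_id, gc)."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["peak_id"].astype(str), df["gc"].astype(float)))


def write_peak_gc(gc: dict[str, float], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"peak_id": list(gc), "gc": [gc[p] for p in gc]}
    ).to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
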