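"""Readers and writers for the pipeline's tabular formats.

Internal coordinates are 1-based inclusive throughout the package; BED output
is converted to 0-based half-open at this single boundary so that a
write/read round trip is bit-exact.

Formats
-------
alignments   TSV: sequence, chrom, start, end, strand, count, n_hits, library_id
libraries    TSV: library_id, replicate_group, genotype, is_wild_type
loci         BED6 (name = locus id) plus a likelihood TSV keyed by locus id
annotations  GFF3 (type column) or BED with a fourth (name) column giving
             the feature type
methylation  TSV: chrom, pos, context, proportion, coverage
chip reads   BED6
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

ALIGNMENT_COLUMNS = [
    "sequence",
    "chrom",
    "start",
    "end",
    "strand",
    "count",
    "n_hits",
    "library_id",
]

METHYLATION_CONTEXTS = ("CpG", "CHG", "CHH")

#: feature types routed to the transposable-element superfamily set
TE_SUPERFAMILY_PREFIXES = ("DNA", "LINE", "LTR", "RC/", "RathE", "SINE")


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def read_alignments(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-separated table of aligned small RNA reads.

    Each row is one distinct (sequence, location, library) stack: ``count``
    is the number of redundant copies sequenced and ``n_hits`` the number of
    genomic locations to which the sequence aligns.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValueError
        If any row violates the coordinate or strand contract; the message
        names the first offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "chrom": str, "strand": str})
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"alignment table missing column(s): {', '.join(missing)}")
    df = df[ALIGNMENT_COLUMNS].copy()
    for col in ("start", "end", "count", "n_hits"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    _validate_alignments(df)
    return df


def _validate_alignments(df: pd.DataFrame) -> None:
    bad = df.index[df["end"] < df["start"]]
    if len(bad):
        raise ValueError(f"end < start at row {bad[0]}")
    bad = df.index[~df["strand"].isin(["+", "-"])]
    if len(bad):
        raise ValueError(f"strand must be + or - at row {bad[0]}")
    bad = df.index[df["count"] < 1]
    if len(bad):
        raise ValueError(f"count < 1 at row {bad[0]}")
    bad = df.index[df["n_hits"] < 1]
    if len(bad):
        raise ValueError(f"n_hits < 1 at row {bad[0]}")


def write_alignments(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_libraries(path: str | os.PathLike) -> pd.DataFrame:
    """Read library metadata: one row per library with its replicate group,
    genotype and wild-type flag."""
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str, "replicate_group": str})
    required = ["library_id", "replicate_group", "genotype", "is_wild_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"library table missing column(s): {', '.join(missing)}")
    df["is_wild_type"] = df["is_wild_type"].astype(bool)
    if df["library_id"].duplicated().any():
        raise ValueError("duplicate library_id: each library belongs to exactly one replicate group")
    return df


def write_libraries(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_loci_bed(loci: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write loci (internal 1-based inclusive) as BED6, 0-based half-open."""
    bed = pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "start": loci["start"].astype(int) - 1,
            "end": loci["end"].astype(int),
            "name": loci["locus_id"],
            "score": 0,
            "strand": ".",
        }
    )
    if (bed["start"] < 0).any():
        raise ValueError("locus start below 1: coordinate overflow")
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_loci_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a locus BED6 file back into 1-based inclusive coordinates."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return pd.DataFrame(
        {
            "locus_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
        }
    )


def write_bed_reads(reads: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write interval reads (e.g. ChIP) as BED6 from 1-based inclusive input."""
    bed = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"].astype(int) - 1,
            "end": reads["end"].astype(int),
            "name": reads.get("name", "."),
            "score": 0,
            "strand": reads.get("strand", "."),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_bed_reads(path: str | os.PathLike) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    return pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int) + 1,
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        }
    )


def _classify_feature_type(ftype: str) -> str:
    if ftype.startswith(TE_SUPERFAMILY_PREFIXES):
        return "te_superfamily"
    return ftype


def read_annotations(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read genomic annotations from GFF3 or a typed BED file.

    Returns a mapping from feature type (``gene``, ``IR``, ``NAT``,
    ``lincRNA``, ``easiRNA``, ``mobile``, TE superfamily names such as
    ``LTR/Gypsy``, or any custom type present in the file) to an interval
    DataFrame with columns chrom/start/end/strand in 1-based inclusive
    coordinates.  Unknown types pass through as custom categories.
    """
    path = os.fspath(path)
    try:
        first = open(path).readline()
    except StopIteration:  # pragma: no cover - empty handled below
        first = ""
    sets: dict[str, list] = {}
    if first.startswith("##gff") or path.endswith((".gff", ".gff3")):
        cols = ["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes"]
        try:
            gff = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            return {}
        for ftype, sub in gff.groupby("type"):
            sets.setdefault(str(ftype), []).append(
                sub[["chrom", "start", "end", "strand"]].astype({"start": int, "end": int})
            )
    else:
        try:
            bed = pd.read_csv(
                path,
                sep="\t",
                header=None,
                names=["chrom", "start", "end", "name", "score", "strand"],
                dtype={"chrom": str, "name": str},
            )
        except pd.errors.EmptyDataError:
            return {}
        bed["start"] = bed["start"].astype(int) + 1
        if "strand" not in bed or bed["strand"].isna().all():
            bed["strand"] = "."
        for ftype, sub in bed.groupby("name"):
            sets.setdefault(str(ftype), []).append(sub[["chrom", "start", "end", "strand"]])
    return {k: pd.concat(v, ignore_index=True) for k, v in sets.items()}


def write_annotations_gff3(sets: Mapping[str, pd.DataFrame], path: str | os.PathLike) -> None:
    rows = []
    for ftype in sorted(sets):
        df = sets[ftype]
        for r in df.itertuples(index=False):
            strand = getattr(r, "strand", ".")
            rows.append(f"{r.chrom}\tsrnaloc\t{ftype}\t{int(r.start)}\t{int(r.end)}\t.\t{strand}\t.\t.")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\n".join(rows))
        if rows:
            fh.write("\n")


def read_methylation(path: str | os.PathLike) -> pd.DataFrame:
    """Read per-cytosine methylation proportions.

    Columns: chrom, pos (1-based), context in {CpG, CHG, CHH},
    proportion in [0, 1], coverage.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    required = ["chrom", "pos", "context", "proportion", "coverage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"methylation table missing column(s): {', '.join(missing)}")
    bad = df.index[(df["proportion"] < 0) | (df["proportion"] > 1)]
    if len(bad):
        raise ValueError(f"proportion outside [0, 1] at row {bad[0]}")
    bad = df.index[~df["context"].isin(METHYLATION_CONTEXTS)]
    if len(bad):
        raise ValueError(f"unknown methylation context at row {bad[0]}")
    df["pos"] = df["pos"].astype(int)
    return df


def write_methylation(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_likelihoods(lik: pd.DataFrame, path: str | os.PathLike) -> None:
    lik.to_csv(path, sep="\t", index_label="locus_id")


def read_likelihoods(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id")


def write_feature_table(ft: pd.DataFrame, path: str | os.PathLike) -> None:
    ft.to_csv(path, sep="\t", index_label="locus_id")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id", dtype=str)
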