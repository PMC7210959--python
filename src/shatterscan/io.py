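"""Readers and writers for the tabular formats the pipeline touches.

Formats
-------
- UCSC ``chrom.sizes`` (two columns: name, length) plus a centromere BED
  for the genome model.
- SEG-like TSV copy-number segmentations: columns ``sample``, ``chrom``,
  ``start``, ``end``, ``copy_number``; 0-based half-open coordinates.
- BEDPE structural variants: the standard 10 columns, plus optional
  ``homlen`` (breakpoint homology length, bp) and ``sample`` columns.
- Fusion-call TSV, sample-metadata TSV and chromothripsis-call TSV.

Everything is validated against a :class:`~shatterscan.genome.GenomeModel`
on read; coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel, GenomeValidationError, normalize_chrom

__all__ = [
    "read_genome_model",
    "write_genome_model",
    "read_segments",
    "write_segments",
    "read_svs",
    "write_svs",
    "read_fusions",
    "write_fusions",
    "read_metadata",
    "write_metadata",
    "read_calls",
    "write_calls",
    "round_half_up",
    "derive_join_class",
    "sv_type_from_join",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "copy_number", "state"]
SV_COLUMNS = [
    "sample", "sv_id", "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2", "sv_type", "join_class", "homlen",
]
FUSION_COLUMNS = [
    "sample", "fusion_id", "gene_a", "gene_b",
    "chrom_a", "pos_a", "chrom_b", "pos_b", "confidence",
]
CALL_COLUMNS = [
    "sample", "chrom", "start", "end", "n_switches", "confidence",
    "n_states", "canonical", "telomere", "centromere",
]

# BEDPE strand -> breakend orientation. '+' means the joined segment extends
# to lower coordinates from the breakend (tail), '-' the opposite (head).
STRAND_TO_ORIENTATION = {"+": "tail", "-": "head"}

JOIN_TO_TYPE = {
    "tail-head": "deletion-like",
    "head-tail": "duplication-like",
    "head-head": "inversion",
    "tail-tail": "inversion",
}


class FormatError(ValueError):
    """Malformed input file."""


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with ties going up (2.5 -> 3).

    numpy's ``round`` uses banker's rounding; copy-number states use the
    deterministic half-up convention instead.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


# ---------------------------------------------------------------------------
# genome model


def read_genome_model(sizes_path, centromere_bed=None) -> GenomeModel:
    """Build a :class:`GenomeModel` from a chrom.sizes file and optional BED.

    Chromosome order follows the sizes file. Every centromere BED row must
    name a chromosome present in the sizes file.
    """
    names: list[str] = []
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(Path(sizes_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise FormatError(f"{sizes_path}:{lineno}: expected name and length")
        name = normalize_chrom(parts[0])
        try:
            length = int(parts[1])
        except ValueError:
            raise FormatError(
                f"{sizes_path}:{lineno}: non-integer length {parts[1]!r}"
            ) from None
        names.append(name)
        lengths[name] = length

    centromeres: dict[str, tuple[int, int]] = {}
    if centromere_bed is not None:
        for lineno, line in enumerate(Path(centromere_bed).read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{centromere_bed}:{lineno}: expected BED3")
            chrom = normalize_chrom(parts[0])
            if chrom not in lengths:
                raise GenomeValidationError(
                    f"{centromere_bed}:{lineno}: unknown chromosome {parts[0]!r}"
                )
            centromeres[chrom] = (int(parts[1]), int(parts[2]))

    return GenomeModel(tuple(names), lengths, centromeres)


def write_genome_model(genome: GenomeModel, sizes_path, centromere_bed=None) -> None:
    with open(sizes_path, "w") as fh:
        for c in genome.chromosomes:
            fh.write(f"{c}\t{genome.length(c)}\n")
    if centromere_bed is not None:
        with open(centromere_bed, "w") as fh:
            for c in genome.chromosomes:
                cen = genome.centromere(c)
                if cen is not None:
                    fh.write(f"{c}\t{cen[0]}\t{cen[1]}\n")


# ---------------------------------------------------------------------------
# copy-number segments


def validate_segments(df: pd.DataFrame, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Sort, bound-check and overlap-check a segment table in place-ish."""
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise FormatError(
            f"segment with start >= end: {bad['sample']} {bad['chrom']}:"
            f"{bad['start']}-{bad['end']}"
        )
    if genome is not None:
        for chrom, sub in df.groupby("chrom", sort=False):
            limit = genome.length(chrom)
            if (sub["end"] > limit).any():
                raise GenomeValidationError(
                    f"segment past end of chromosome {chrom} (length {limit})"
                )
    df = df.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)
    for (sample, chrom), sub in df.groupby(["sample", "chrom"], sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise FormatError(
                f"overlapping segments for sample {sample!r} chromosome {chrom}"
            )
    if "state" not in df.columns:
        df["state"] = round_half_up(df["copy_number"])
    return df[SEGMENT_COLUMNS]


def read_segments(path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a SEG-like TSV into the canonical segment table.

    Required columns: sample, chrom, start, end, copy_number (0-based
    half-open). The integer ``state`` is derived by half-up rounding.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"sample", "chrom", "start", "end", "copy_number"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["copy_number"] = df["copy_number"].astype(float)
    if (df["copy_number"] < 0).any():
        raise FormatError(f"{path}: negative copy number")
    df["state"] = round_half_up(df["copy_number"])
    return validate_segments(df, genome)


def write_segments(df: pd.DataFrame, path) -> None:
    df[SEGMENT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# structural variants


def derive_join_class(strand1: str, strand2: str) -> str:
    try:
        return (
            f"{STRAND_TO_ORIENTATION[strand1]}-{STRAND_TO_ORIENTATION[strand2]}"
        )
    except KeyError:
        raise FormatError(f"malformed strand pair ({strand1!r}, {strand2!r})") from None


def sv_type_from_join(chrom1: str, chrom2: str, join_class: str) -> str:
    if normalize_chrom(chrom1) != normalize_chrom(chrom2):
        return "translocation"
    return JOIN_TO_TYPE[join_class]


def _finalize_svs(df: pd.DataFrame, genome: GenomeModel | None) -> pd.DataFrame:
    df["chrom1"] = df["chrom1"].map(normalize_chrom)
    df["chrom2"] = df["chrom2"].map(normalize_chrom)
    df["join_class"] = [
        derive_join_class(s1, s2) for s1, s2 in zip(df["strand1"], df["strand2"])
    ]
    df["sv_type"] = [
        sv_type_from_join(c1, c2, j)
        for c1, c2, j in zip(df["chrom1"], df["chrom2"], df["join_class"])
    ]
    if genome is not None:
        for chrom_col, pos_col in (("chrom1", "pos1"), ("chrom2", "pos2")):
            for chrom, sub in df.groupby(chrom_col, sort=False):
                limit = genome.length(chrom)
                if ((sub[pos_col] < 0) | (sub[pos_col] > limit)).any():
                    raise GenomeValidationError(
                        f"SV breakend outside chromosome {chrom}"
                    )
    df["homlen"] = df["homlen"].astype("Int64")
    return df[SV_COLUMNS].reset_index(drop=True)


def read_svs(path, genome: GenomeModel | None = None, sample: str | None = None) -> pd.DataFrame:
    """Read structural variants from BEDPE.

    Standard 10 BEDPE columns (chrom1 start1 end1 chrom2 start2 end2 name
    score strand1 strand2) with optional trailing ``homlen`` and ``sample``
    columns. Breakend positions are taken as the interval starts. A missing
    homlen column (or '.') marks homology as unknown.
    """
    text = Path(path).read_text()
    header: list[str] | None = None
    lines = text.splitlines()
    if lines and lines[0].startswith("#"):
        header = lines[0].lstrip("#").split("\t")
        body = "\n".join(lines[1:])
    else:
        body = text
    if not body.strip():
        df = pd.DataFrame(columns=SV_COLUMNS)
        df["homlen"] = df.get("homlen", pd.Series(dtype="Int64"))
        return df
    raw = pd.read_csv(
        _io.StringIO(body), sep="\t", header=None, dtype=str, na_filter=False
    )
    ncol = raw.shape[1]
    if ncol < 10:
        raise FormatError(f"{path}: BEDPE needs >= 10 columns, found {ncol}")
    base = [
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "name", "score", "strand1", "strand2",
    ]
    if header is not None and len(header) == ncol:
        cols = [c.strip().lower() for c in header]
    else:
        cols = base + [f"extra{i}" for i in range(ncol - 10)]
        if ncol >= 11:
            cols[10] = "homlen"
        if ncol >= 12:
            cols[11] = "sample"
    raw.columns = cols

    out = pd.DataFrame(
        {
            "sv_id": raw["name"],
            "chrom1": raw["chrom1"],
            "pos1": raw["start1"].astype(np.int64),
            "strand1": raw["strand1"],
            "chrom2": raw["chrom2"],
            "pos2": raw["start2"].astype(np.int64),
            "strand2": raw["strand2"],
        }
    )
    if "sample" in raw.columns:
        out["sample"] = raw["sample"]
    elif sample is not None:
        out["sample"] = sample
    else:
        raise FormatError(
            f"{path}: no sample column and no sample= argument supplied"
        )
    if "homlen" in raw.columns:
        out["homlen"] = pd.array(
            [None if v in (".", "", "NA") else int(v) for v in raw["homlen"]],
            dtype="Int64",
        )
    else:
        out["homlen"] = pd.array([None] * len(raw), dtype="Int64")
    return _finalize_svs(out, genome)


def write_svs(df: pd.DataFrame, path) -> None:
    """Write the canonical SV table as 12-column BEDPE (+homlen, +sample)."""
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\thomlen\tsample\n"
        )
        for row in df.itertuples(index=False):
            hom = "." if pd.isna(row.homlen) else int(row.homlen)
            fh.write(
                f"{row.chrom1}\t{row.pos1}\t{row.pos1 + 1}\t"
                f"{row.chrom2}\t{row.pos2}\t{row.pos2 + 1}\t"
                f"{row.sv_id}\t.\t{row.strand1}\t{row.strand2}\t{hom}\t{row.sample}\n"
            )


# ---------------------------------------------------------------------------
# fusions, metadata, calls


def read_fusions(path, genome: GenomeModel | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom_a": str, "chrom_b": str})
    missing = set(FUSION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    df["chrom_a"] = df["chrom_a"].map(normalize_chrom)
    df["chrom_b"] = df["chrom_b"].map(normalize_chrom)
    if genome is not None:
        for chrom_col, pos_col in (("chrom_a", "pos_a"), ("chrom_b", "pos_b")):
            for chrom, sub in df.groupby(chrom_col, sort=False):
                limit = genome.length(chrom)
                if ((sub[pos_col] < 0) | (sub[pos_col] > limit)).any():
                    raise GenomeValidationError(
                        f"fusion breakpoint outside chromosome {chrom}"
                    )
    return df[FUSION_COLUMNS]


def write_fusions(df: pd.DataFrame, path) -> None:
    df[FUSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata TSV; signature-exposure columns are prefixed ``sig_``."""
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns:
        raise FormatError(f"{path}: missing 'sample' column")
    for col in df.columns:
        if col.startswith("sig_") and (df[col] < 0).any():
            raise FormatError(f"{path}: negative exposure in {col}")
    if "tumor_cell_content" in df.columns:
        tcc = df["tumor_cell_content"]
        if ((tcc <= 0) | (tcc > 1)).any():
            raise FormatError(f"{path}: tumour cell content outside (0, 1]")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CALL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("canonical", "telomere", "centromere"):
        if df[col].dtype != bool:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    return df[CALL_COLUMNS]


def write_calls(calls, path) -> None:
    """Write chromothripsis calls as TSV; accepts a DataFrame or call list."""
    if not isinstance(calls, pd.DataFrame):
        from .scoring import calls_to_frame

        calls = calls_to_frame(calls)
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)
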