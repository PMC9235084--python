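"""Readers and writers for every on-disk format the pipeline touches.

All interval formats are 0-based, half-open (BED convention) both on disk
and in memory; 1-based dialects must be converted by the caller. The
contact matrix is a triplet file (i, j, count) alongside a 4-column bin
BED (chrom, start, end, global index). Abundance tables are long-format
TSV with one row per protein per experiment group.

Malformed input raises :class:`FormatError` naming the offending line;
readers never silently drop records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinTable, ContactMatrix

__all__ = [
    "FormatError",
    "read_bins", "write_bins",
    "read_matrix", "write_matrix",
    "read_bed", "write_bed",
    "read_bedgraph", "write_bedgraph",
    "read_fragments", "write_fragments",
    "read_interactions", "write_interactions",
    "read_abundance", "write_abundance",
    "read_gmt", "write_gmt",
]

ABUNDANCE_COLUMNS = ["protein_id", "group", "wt1", "wt2", "dko1", "dko2"]


class FormatError(ValueError):
    """Raised on malformed input; message carries path and line number."""


def _lines(path) -> list[tuple[int, list[str]]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            out.append((lineno, line.split("\t")))
    return out


def _err(path, lineno: int, msg: str) -> FormatError:
    return FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- bins --
def read_bins(path) -> BinTable:
    rows = []
    for lineno, f in _lines(path):
        if len(f) < 4:
            raise _err(path, lineno, "expected 4 columns (chrom, start, end, index)")
        try:
            rows.append((f[0], int(f[1]), int(f[2]), int(f[3])))
        except ValueError:
            raise _err(path, lineno, "non-integer coordinate or index") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "index"])
    if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
        raise FormatError(f"{path}: bin indices are not dense and ascending from 0")
    try:
        return BinTable(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_bins(bins: BinTable, path) -> None:
    df = bins.df.copy()
    df["index"] = np.arange(len(df))
    df.to_csv(path, sep="\t", header=False, index=False)


# -------------------------------------------------------------- matrix --
def read_matrix(matrix_path, bins_path) -> ContactMatrix:
    bins = read_bins(bins_path)
    ii, jj, cc = [], [], []
    for lineno, f in _lines(matrix_path):
        if len(f) < 3:
            raise _err(matrix_path, lineno, "expected 3 columns (i, j, count)")
        try:
            i, j = int(f[0]), int(f[1])
            c = float(f[2])
        except ValueError:
            raise _err(matrix_path, lineno, "unparseable triplet") from None
        if i < 0 or j < 0 or i >= bins.n_bins or j >= bins.n_bins:
            raise _err(matrix_path, lineno, f"bin index out of range (n={bins.n_bins})")
        if c < 0:
            raise _err(matrix_path, lineno, "negative count")
        ii.append(i)
        jj.append(j)
        cc.append(c)
    return ContactMatrix.from_coo(bins, ii, jj, cc)


def write_matrix(cm: ContactMatrix, matrix_path, bins_path) -> None:
    write_bins(cm.bins, bins_path)
    trip = cm.to_triplets()
    # keep integer formatting for count-valued matrices
    if np.allclose(trip["count"], np.round(trip["count"])):
        trip["count"] = trip["count"].astype(np.int64)
    trip.to_csv(matrix_path, sep="\t", header=False, index=False)


# ----------------------------------------------------------------- bed --
def read_bed(path) -> pd.DataFrame:
    """BED3/BED4(score) -> DataFrame(chrom, start, end[, score])."""
    rows = []
    any_score = False
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise _err(path, lineno, "expected at least 3 BED columns")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise _err(path, lineno, "non-integer coordinates") from None
        if start >= end:
            raise _err(path, lineno, "start >= end")
        score = None
        if len(f) >= 4 and f[3] not in (".", ""):
            try:
                score = float(f[3])
            except ValueError:
                raise _err(path, lineno, "unparseable score") from None
            any_score = True
        rows.append((f[0], start, end, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    if not any_score:
        df = df.drop(columns=["score"])
    return _check_sorted(df, path)


def _check_sorted(df: pd.DataFrame, path) -> pd.DataFrame:
    for chrom, grp in df.groupby("chrom", sort=False):
        if not grp["start"].is_monotonic_increasing:
            raise FormatError(f"{path}: intervals on {chrom} are not sorted")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["score"] if "score" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------ bedgraph --
def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    for lineno, f in _lines(path):
        if len(f) < 4:
            raise _err(path, lineno, "expected 4 bedGraph columns")
        try:
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
        except ValueError:
            raise _err(path, lineno, "unparseable bedGraph line") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: interval with start >= end")
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            raise FormatError(f"{path}: overlapping or unsorted intervals on {chrom}")
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


# ----------------------------------------------------------- fragments --
def read_fragments(path) -> pd.DataFrame:
    """Restriction-fragment map: chrom, start, end, fragment_id, is_bait."""
    rows = []
    for lineno, f in _lines(path):
        if len(f) < 5:
            raise _err(path, lineno, "expected 5 columns (chrom, start, end, id, bait)")
        try:
            rows.append((f[0], int(f[1]), int(f[2]), f[3], bool(int(f[4]))))
        except ValueError:
            raise _err(path, lineno, "unparseable fragment line") from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id", "is_bait"])
    if df["fragment_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate fragment id")
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        if s[0] != 0 or np.any(s[1:] != e[:-1]):
            raise FormatError(f"{path}: fragments do not tile {chrom}")
    return df


def write_fragments(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "fragment_id"]].copy()
    out["is_bait"] = df["is_bait"].astype(int)
    out.to_csv(path, sep="\t", header=False, index=False)


# -------------------------------------------------------- interactions --
def read_interactions(path, fragments: pd.DataFrame) -> pd.DataFrame:
    known = set(fragments["fragment_id"])
    baits = set(fragments.loc[fragments["is_bait"], "fragment_id"])
    rows = []
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise _err(path, lineno, "expected 3 columns (bait_id, otherend_id, score)")
        bait, oe = f[0], f[1]
        try:
            score = float(f[2])
        except ValueError:
            raise _err(path, lineno, "unparseable score") from None
        if bait not in known:
            raise _err(path, lineno, f"unknown bait fragment {bait}")
        if oe not in known:
            raise _err(path, lineno, f"unknown other-end fragment {oe}")
        if bait not in baits:
            raise _err(path, lineno, f"fragment {bait} is not flagged as a bait")
        if not np.isfinite(score) or score < 0:
            raise _err(path, lineno, "score must be finite and >= 0")
        rows.append((bait, oe, score))
    return pd.DataFrame(rows, columns=["bait_id", "otherend_id", "score"])


def write_interactions(calls: pd.DataFrame, path) -> None:
    calls[["bait_id", "otherend_id", "score"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ----------------------------------------------------------- abundance --
def read_abundance(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Long-format label-free abundance table.

    Expected header: protein_id, group, wt1, wt2, dko1, dko2.
    ``column_map`` renames nonstandard source headers onto that scheme.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df = df[ABUNDANCE_COLUMNS].copy()
    for col in ["wt1", "wt2", "dko1", "dko2"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            lineno = int(vals.isna().idxmax()) + 2  # + header line
            raise _err(path, lineno, f"unparseable abundance in column {col}")
        if (vals < 0).any():
            lineno = int((vals < 0).idxmax()) + 2
            raise _err(path, lineno, f"negative abundance in column {col}")
        df[col] = vals.astype(float)
    return df


def write_abundance(df: pd.DataFrame, path) -> None:
    df[ABUNDANCE_COLUMNS].to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- gmt --
def read_gmt(path) -> dict[str, tuple[str, frozenset[str]]]:
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, f in _lines(path):
        if len(f) < 3:
            raise _err(path, lineno, "GMT line needs term, description, >=1 member")
        term, desc, members = f[0], f[1], [m for m in f[2:] if m]
        if not members:
            raise _err(path, lineno, f"term {term} has no members")
        if term in terms:
            raise _err(path, lineno, f"duplicate term {term}")
        terms[term] = (desc, frozenset(members))
    return terms


def write_gmt(annotation: dict[str, tuple[str, frozenset[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, members) in annotation.items():
            fh.write("\t".join([term, desc, *sorted(members)]) + "\n")


def track_bin_values(track: pd.DataFrame, bins: BinTable) -> np.ndarray:
    """Length-weighted mean track value per bin (0 where uncovered)."""
    values = np.zeros(bins.n_bins)
    weights = np.zeros(bins.n_bins)
    bin_starts = bins.df["start"].to_numpy()
    bin_ends = bins.df["end"].to_numpy()
    for chrom, grp in track.groupby("chrom", sort=False):
        if chrom not in bins.chroms:
            continue
        lo, hi = bins.chrom_range(chrom)
        for start, end, value in zip(grp["start"], grp["end"], grp["value"]):
            first = int(np.searchsorted(bin_ends[lo:hi], start, side="right")) + lo
            for b in range(first, hi):
                ov = min(end, bin_ends[b]) - max(start, bin_starts[b])
                if ov <= 0:
                    break
                values[b] += value * ov
                weights[b] += ov
    out = np.zeros(bins.n_bins)
    np.divide(values, weights, out=out, where=weights > 0)
    return out
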