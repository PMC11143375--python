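"""Readers and writers for the text formats the pipeline touches.

Coordinates are 0-based half-open (BED convention) everywhere in memory and
on disk; narrowPeak summits are stored as an offset from the interval start
(column 10) and q-values as -log10 (column 9), matching the format the
upstream peak callers emit. Gzipped fragment files are handled transparently
via the file extension.

Result tables are TSVs with ``#``-prefixed metadata header lines (config
hash, seed, thresholds) so that parameter drift between runs is auditable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


class FormatError(ValueError):
    """Raised for malformed input files; message carries the line number."""


# ---------------------------------------------------------------- fragments

def write_fragments_tsv(fragments: pd.DataFrame, path) -> None:
    """Write a fragments table (chrom, start, end, barcode, count)."""
    df = fragments.copy()
    if "count" not in df.columns:
        df["count"] = 1
    df[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_fragments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=FRAGMENT_COLUMNS,
                     dtype={"chrom": str, "start": np.int64,
                            "end": np.int64, "barcode": str,
                            "count": np.int64})
    _validate_intervals(df, path)
    return df


def _validate_intervals(df: pd.DataFrame, path) -> None:
    bad = np.flatnonzero((df["end"].to_numpy() <= df["start"].to_numpy())
                         | (df["start"].to_numpy() < 0))
    if bad.size:
        raise FormatError(
            f"{path}: line {bad[0] + 1}: end <= start or negative start "
            "(is the file 1-based?)")


# --------------------------------------------------------------- narrowPeak

def write_narrowpeak(sub_peaks: pd.DataFrame, path) -> None:
    """Write sub-peaks (chrom, start, end, summit, q) as 10-column narrowPeak."""
    q = sub_peaks["q"].to_numpy(dtype=float)
    out = pd.DataFrame({
        "chrom": sub_peaks["chrom"],
        "start": sub_peaks["start"],
        "end": sub_peaks["end"],
        "name": [f"peak_{i}" for i in range(len(sub_peaks))],
        "score": 0,
        "strand": ".",
        "signal": 0.0,
        "p": -1.0,
        "q": -np.log10(q),
        "summit": sub_peaks["summit"].to_numpy() - sub_peaks["start"].to_numpy(),
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path) -> pd.DataFrame:
    """Read narrowPeak; returns chrom, start, end, summit (absolute bp), q."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "signal", "p", "q", "summit"])
    _validate_intervals(df, path)
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64),
        "summit": (df["start"] + df["summit"]).astype(np.int64),
        "q": np.power(10.0, -df["q"].to_numpy(dtype=float)),
    })
    bad = np.flatnonzero((out["summit"] < out["start"])
                         | (out["summit"] >= out["end"]))
    if bad.size:
        raise FormatError(f"{path}: line {bad[0] + 1}: summit outside peak")
    return out


# ---------------------------------------------------------------------- BED

def write_bed(intervals: pd.DataFrame, path, extra_columns=()) -> None:
    cols = ["chrom", "start", "end", *extra_columns]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, extra_columns=()) -> pd.DataFrame:
    names = ["chrom", "start", "end", *extra_columns]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(len(names)))
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _validate_intervals(df, path)
    return df


# ---------------------------------------------------------------------- MTX

def write_mtx(matrix: sp.spmatrix, barcodes, features, prefix) -> None:
    """Write a cells x features sparse matrix as MTX + barcode/feature lists.

    The MTX file stores features x cells (the dominant on-disk convention).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(prefix) + ".mtx", sp.coo_matrix(matrix.T))
    pd.Series(list(barcodes)).to_csv(str(prefix) + ".barcodes.tsv",
                                     header=False, index=False)
    pd.Series(list(features)).to_csv(str(prefix) + ".features.tsv",
                                     header=False, index=False)


def read_mtx(prefix):
    """Read an MTX triplet written by :func:`write_mtx`.

    Returns ``(csr cells x features, barcodes, features)``.
    """
    m = scipy.io.mmread(str(prefix) + ".mtx").T.tocsr()
    barcodes = pd.read_csv(str(prefix) + ".barcodes.tsv",
                           header=None)[0].astype(str).tolist()
    features = pd.read_csv(str(prefix) + ".features.tsv",
                           header=None)[0].astype(str).tolist()
    if m.shape != (len(barcodes), len(features)):
        raise FormatError(f"{prefix}: matrix shape {m.shape} does not match "
                          f"{len(barcodes)} barcodes x {len(features)} features")
    return m, barcodes, features


# ----------------------------------------------------------------- bedgraph

def write_bedgraph(track: pd.DataFrame, path) -> None:
    """Write (chrom, start, end, value) runs as bedgraph."""
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, comment="#",
                       names=["chrom", "start", "end", "value"])


# ------------------------------------------------------------ result tables

def write_result_table(df: pd.DataFrame, path, metadata: dict | None = None,
                       index: bool = False) -> None:
    """Write a results TSV with ``#`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def read_result_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_result_metadata(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta


# -------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
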