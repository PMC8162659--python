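"""File formats and genome-sequence context classification.

Coordinate conventions, centralized here:

* cytosine reports: 1-based positions (Bismark cytosine/CX report dialect);
* BED and bedGraph: 0-based half-open;
* everything in memory that is an interval (bins, domains, windows) is
  0-based half-open.

Gzip is handled transparently for every text reader/writer (by ``.gz``
suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .records import COLUMNS, CytosineRecord, empty_frame, records_to_frame, validate_frame

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A malformed input line; the message names the file and line number."""


class DuplicateSiteError(ValueError):
    """Two records claim the same (chrom, pos, strand) where one is expected."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# cytosine report
# ---------------------------------------------------------------------------

def iter_cytosine_report(path) -> Iterator[CytosineRecord]:
    """Stream records from a tab-separated cytosine report.

    Columns: chrom, pos (1-based), strand, count_meth, count_unmeth,
    context, trinucleotide.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            chrom, pos, strand, meth, unmeth, context, tri = parts
            try:
                pos_i, meth_i, unmeth_i = int(pos), int(meth), int(unmeth)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if meth_i < 0 or unmeth_i < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if strand not in ("+", "-", "."):
                raise ParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            yield CytosineRecord(chrom, pos_i, strand, meth_i, unmeth_i, context, tri)


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a whole cytosine report into the canonical record frame."""
    return records_to_frame(iter_cytosine_report(path))


def write_cytosine_report(records, path) -> None:
    """Write records (frame or iterable of CytosineRecord) as a report."""
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    validate_frame(records)
    with _open_text(path, "wt") as fh:
        records[COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(contigs: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in contigs:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# annotations (BED) and bedGraph
# ---------------------------------------------------------------------------

@dataclass
class AnnotationSet:
    """Labeled genomic intervals, 0-based half-open."""

    intervals: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "label"]))

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("annotation intervals require start < end")

    @property
    def labels(self) -> list[str]:
        return sorted(self.intervals["label"].unique())

    def validate_against(self, contig_sizes: Mapping[str, int]) -> None:
        for chrom, start, end, _ in self.intervals.itertuples(index=False):
            if chrom not in contig_sizes:
                raise ValueError(f"annotation contig {chrom!r} not in genome")
            if start < 0 or end > contig_sizes[chrom]:
                raise ValueError(f"interval {chrom}:{start}-{end} out of contig bounds")

    def for_label(self, label: str) -> pd.DataFrame:
        return self.intervals[self.intervals["label"] == label]


def read_bed(path) -> AnnotationSet:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            label = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], int(parts[1]), int(parts[2]), label))
    return AnnotationSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def write_bed(annotations: AnnotationSet, path) -> None:
    with _open_text(path, "wt") as fh:
        annotations.intervals.to_csv(fh, sep="\t", header=False, index=False)


def write_bedgraph(frame: pd.DataFrame, path, value_col: str = "level") -> None:
    """Write (chrom, start, end, value) rows; rows with NaN value are dropped."""
    out = frame[["chrom", "start", "end", value_col]].dropna(subset=[value_col])
    with _open_text(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# genome -> cytosine context templates
# ---------------------------------------------------------------------------

def _contigs_of(genome) -> list[tuple[str, str]]:
    if hasattr(genome, "contigs"):  # GenomeFixture
        return list(genome.contigs)
    if isinstance(genome, Mapping):
        return list(genome.items())
    return list(read_fasta(genome).items())


def _strand_templates(seq_bytes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0-based C positions, trinucleotides and contexts on one strand."""
    c_pos = np.flatnonzero(seq_bytes == b"C")
    padded = np.concatenate([seq_bytes, np.array([b"N", b"N"], dtype="S1")])
    second = padded[c_pos + 1]
    third = padded[c_pos + 2]
    tri = np.char.add(np.char.add(padded[c_pos], second), third).astype("U3")
    context = np.where(second == b"G", "CG", np.where(third == b"G", "CHG", "CHH"))
    return c_pos, tri, context


def classify_contexts(genome) -> pd.DataFrame:
    """Emit a zero-count record template for every C on both strands.

    ``genome`` may be a GenomeFixture, a mapping name->sequence, or a FASTA
    path.  Contexts follow the standard definitions: CG iff the next base is
    G, else CHG iff the base after that is G, else CHH.  Cs within 2 bp of a
    contig end carry an N-padded trinucleotide (the flag for edge sites) and
    take their context from the available bases.  Non-ACGT bases are treated
    as N and counted in a log line; they can never be a C so such sites are
    skipped implicitly.
    """
    frames = []
    for name, seq in _contigs_of(genome):
        seq = seq.upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
        unknown = ~np.isin(arr, np.array([b"A", b"C", b"G", b"T"], dtype="S1"))
        if unknown.any():
            log.info("contig %s: %d non-ACGT bases treated as N", name, int(unknown.sum()))
            arr[unknown] = b"N"
        # plus strand
        pos_p, tri_p, ctx_p = _strand_templates(arr)
        # minus strand: classify on the reverse complement, map back
        rc = np.frombuffer(
            seq.translate(_COMPLEMENT)[::-1].encode("ascii"), dtype="S1").copy()
        rc[~np.isin(rc, np.array([b"A", b"C", b"G", b"T"], dtype="S1"))] = b"N"
        pos_m_rc, tri_m, ctx_m = _strand_templates(rc)
        pos_m = len(arr) - 1 - pos_m_rc  # original 0-based position of the C (a G on +)
        n_p, n_m = len(pos_p), len(pos_m)
        frame = pd.DataFrame({
            "chrom": np.repeat(name, n_p + n_m),
            "pos": np.concatenate([pos_p + 1, pos_m + 1]),
            "strand": np.concatenate([np.repeat("+", n_p), np.repeat("-", n_m)]),
            "count_meth": np.zeros(n_p + n_m, dtype=np.int64),
            "count_unmeth": np.zeros(n_p + n_m, dtype=np.int64),
            "context": np.concatenate([ctx_p, ctx_m]),
            "tri": np.concatenate([tri_p, tri_m]),
        })
        frame = frame.sort_values(["pos", "strand"], kind="stable", ignore_index=True)
        frames.append(frame)
    if not frames:
        return empty_frame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CG strand merging
# ---------------------------------------------------------------------------

def merge_cg_strands(records) -> pd.DataFrame:
    """Combine the two strands of each CpG into one record.

    A plus-strand CG cytosine at 1-based position p pairs with the
    minus-strand cytosine at p+1; the merged record keeps the plus-strand
    position and trinucleotide, with strand ``"."`` and counts summed.
    Unpaired CG records pass through unchanged; non-CG records are never
    merged.  Duplicate (chrom, pos, strand) CG inputs raise
    :class:`DuplicateSiteError`.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    cg = records[records["context"] == "CG"]
    rest = records[records["context"] != "CG"]
    if cg.duplicated(subset=["chrom", "pos", "strand"]).any():
        dup = cg[cg.duplicated(subset=["chrom", "pos", "strand"])].iloc[0]
        raise DuplicateSiteError(
            f"duplicate CG record at {dup['chrom']}:{dup['pos']}({dup['strand']})")
    plus = cg[cg["strand"] == "+"].copy()
    minus = cg[cg["strand"] == "-"].copy()
    passthrough = cg[~cg["strand"].isin(["+", "-"])]
    minus["_key"] = minus["pos"] - 1
    merged = plus.merge(
        minus[["chrom", "_key", "count_meth", "count_unmeth"]],
        left_on=["chrom", "pos"], right_on=["chrom", "_key"],
        how="outer", suffixes=("", "_m"), indicator=True)
    paired = merged["_merge"] == "both"
    merged.loc[paired, "count_meth"] += merged.loc[paired, "count_meth_m"]
    merged.loc[paired, "count_unmeth"] += merged.loc[paired, "count_unmeth_m"]
    merged.loc[paired, "strand"] = "."
    # lone minus-strand records: restore their own coordinates
    lone_minus = merged["_merge"] == "right_only"
    merged.loc[lone_minus, "pos"] = merged.loc[lone_minus, "_key"] + 1
    merged.loc[lone_minus, "strand"] = "-"
    merged.loc[lone_minus, "count_meth"] = merged.loc[lone_minus, "count_meth_m"]
    merged.loc[lone_minus, "count_unmeth"] = merged.loc[lone_minus, "count_unmeth_m"]
    merged.loc[lone_minus, "context"] = "CG"
    lut = minus.set_index(["chrom", "_key"])["tri"]
    if lone_minus.any():
        keys = list(zip(merged.loc[lone_minus, "chrom"], merged.loc[lone_minus, "_key"]))
        merged.loc[lone_minus, "tri"] = lut.loc[keys].to_numpy()
    merged = merged[COLUMNS].astype({"pos": "int64", "count_meth": "int64",
                                     "count_unmeth": "int64"})
    out = pd.concat([merged, passthrough, rest], ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable", ignore_index=True)
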