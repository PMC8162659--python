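"""Weighted methylation levels: global, per bin, per annotation, per site.

All levels are *weighted* (count-pooled): Σ methylated / Σ total over the
covered sites of the region, never the mean of per-site fractions.  Bins
tile each contig from coordinate 0; bins failing coverage thresholds are
missing (NaN), which downstream comparisons treat as absent, not as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import AnnotationSet
from .records import records_to_frame

DINUCLEOTIDES = ("CA", "CT", "CC")


def filter_context(records: pd.DataFrame, context_filter: str | None) -> pd.DataFrame:
    """Select records by context specifier.

    ``None`` keeps everything; ``"CG"``/``"CHG"``/``"CHH"`` select a context
    class; ``"CH"`` selects all non-CG; a dinucleotide (``"CA"``, ``"CT"``,
    ``"CC"``) or a full trinucleotide selects by the record's trinucleotide.
    """
    if context_filter is None:
        return records
    if context_filter in ("CG", "CHG", "CHH"):
        return records[records["context"] == context_filter]
    if context_filter == "CH":
        return records[records["context"] != "CG"]
    if context_filter in DINUCLEOTIDES:
        return records[(records["context"] != "CG")
                       & (records["tri"].str[:2] == context_filter)]
    if len(context_filter) == 3 and context_filter.startswith("C"):
        return records[records["tri"] == context_filter]
    raise ConfigError(f"unknown context filter {context_filter!r}")


def _as_frame(records) -> pd.DataFrame:
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    return records


def global_level(records, context_filter: str | None = None) -> float:
    """Genome-wide weighted methylation level over covered passing sites."""
    sub = filter_context(_as_frame(records), context_filter)
    total = int((sub["count_meth"] + sub["count_unmeth"]).sum())
    if total == 0:
        raise ValueError("global level undefined: zero covered sites after filtering")
    return float(sub["count_meth"].sum()) / total


@dataclass
class BinTrack:
    """Fixed-size genomic bins with weighted methylation levels.

    ``frame`` has one row per bin tiled from 0 on every contig seen (or per
    ``contig_sizes`` when supplied): chrom, start, end, level (NaN when the
    bin fails coverage thresholds), n_sites, total_depth, partial (last,
    truncated bin of a contig).
    """

    frame: pd.DataFrame
    bin_size: int
    context: str | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def covered(self) -> pd.DataFrame:
        return self.frame[self.frame["level"].notna()]

    def keys(self) -> set[tuple[str, int]]:
        """All (chrom, start) bin identifiers, missing bins included."""
        return set(zip(self.frame["chrom"], self.frame["start"]))

    def level_map(self) -> dict[tuple[str, int], float]:
        cov = self.covered
        return dict(zip(zip(cov["chrom"], cov["start"]), cov["level"]))

    def to_tsv(self, path) -> None:
        from .io import _open_text

        with _open_text(path, "wt") as fh:
            fh.write(f"#bin_size={self.bin_size}\tcontext={self.context or ''}\n")
            self.frame.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinTrack":
        from .io import _open_text

        with _open_text(path) as fh:
            header = fh.readline().strip().lstrip("#")
            meta = dict(kv.split("=", 1) for kv in header.split("\t"))
            frame = pd.read_csv(fh, sep="\t")
        return cls(frame=frame, bin_size=int(meta["bin_size"]),
                   context=meta.get("context") or None)


def bin_levels(records, bin_size: int = 10_000, context_filter: str | None = None,
               min_sites: int = 5, min_depth_per_bin: int = 0,
               contig_sizes: Mapping[str, int] | None = None) -> BinTrack:
    """Weighted methylation per fixed-size bin.

    A site at 1-based position p belongs to bin floor((p-1)/bin_size).  Bins
    with fewer than ``min_sites`` covered sites (depth >= 1) or pooled depth
    below ``min_depth_per_bin`` are emitted with level NaN.
    """
    if bin_size <= 0:
        raise ConfigError("bin_size must be > 0")
    sub = filter_context(_as_frame(records), context_filter).copy()
    depth = sub["count_meth"] + sub["count_unmeth"]
    sub = sub[depth > 0]
    if contig_sizes is None:
        contig_sizes = {c: int(g["pos"].max())
                        for c, g in _as_frame(records).groupby("chrom")}
    rows = []
    grouped = {c: g for c, g in sub.groupby("chrom")}
    for chrom in sorted(contig_sizes):
        size = contig_sizes[chrom]
        starts = np.arange(0, size, bin_size)
        n_bins = len(starts)
        meth = np.zeros(n_bins)
        tot = np.zeros(n_bins)
        nsites = np.zeros(n_bins, dtype=np.int64)
        if chrom in grouped:
            g = grouped[chrom]
            idx = (g["pos"].to_numpy() - 1) // bin_size
            np.add.at(meth, idx, g["count_meth"].to_numpy())
            np.add.at(tot, idx, (g["count_meth"] + g["count_unmeth"]).to_numpy())
            np.add.at(nsites, idx, 1)
        level = np.where(
            (nsites >= min_sites) & (tot >= max(min_depth_per_bin, 1)),
            np.divide(meth, tot, out=np.zeros(n_bins), where=tot > 0), np.nan)
        ends = np.minimum(starts + bin_size, size)
        rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "level": level,
            "n_sites": nsites, "total_depth": tot.astype(np.int64),
            "partial": ends - starts < bin_size,
        }))
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["chrom", "start", "end", "level", "n_sites", "total_depth", "partial"])
    return BinTrack(frame=frame, bin_size=bin_size, context=context_filter)


def annotation_levels(records, annotations: AnnotationSet,
                      context_filter: str | None = None) -> pd.DataFrame:
    """Pooled weighted level per annotation label.

    A site inside overlapping intervals carrying different labels counts
    toward each label; within one label a site counts once even if that
    label's intervals overlap.  Labels with zero covered sites get level NaN.
    """
    sub = filter_context(_as_frame(records), context_filter)
    sub = sub[(sub["count_meth"] + sub["count_unmeth"]) > 0]
    rows = []
    for label in annotations.labels:
        iv = annotations.for_label(label)
        meth = tot = nsites = 0
        for chrom, g in sub.groupby("chrom"):
            ivc = iv[iv["chrom"] == chrom].sort_values("start")
            if not len(ivc):
                continue
            # merge per-label intervals so overlapping ones count sites once
            starts, ends = [], []
            for s, e in ivc[["start", "end"]].itertuples(index=False):
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            starts_a, ends_a = np.array(starts), np.array(ends)
            pos0 = g["pos"].to_numpy() - 1
            idx = np.searchsorted(starts_a, pos0, side="right") - 1
            inside = (idx >= 0) & (pos0 < ends_a[np.clip(idx, 0, None)])
            meth += int(g["count_meth"].to_numpy()[inside].sum())
            tot += int((g["count_meth"] + g["count_unmeth"]).to_numpy()[inside].sum())
            nsites += int(inside.sum())
        rows.append({"label": label, "level": meth / tot if tot else np.nan,
                     "n_sites": nsites, "total_depth": tot})
    return pd.DataFrame(rows).set_index("label")


def site_levels(records, min_depth: int = 16) -> pd.DataFrame:
    """Per-site methylation fractions for sites with depth >= min_depth.

    The default of 16 implements a "sequencing depth > 15" filter.  Returns
    a frame with chrom, pos, strand, level, depth.
    """
    sub = _as_frame(records).copy()
    depth = sub["count_meth"] + sub["count_unmeth"]
    sub = sub[depth >= min_depth]
    depth = depth[depth >= min_depth]
    out = sub[["chrom", "pos", "strand"]].copy()
    out["level"] = sub["count_meth"] / depth
    out["depth"] = depth
    return out.reset_index(drop=True)


def level_histogram(bins: BinTrack, bin_width_pct: int = 10) -> pd.DataFrame:
    """Frequency of non-missing bins per methylation-level interval.

    Intervals are [k·w, (k+1)·w) percent with the top interval closed at
    100; frequencies sum to the number of non-missing bins.
    """
    if 100 % bin_width_pct != 0:
        raise ConfigError("bin_width_pct must divide 100")
    edges = np.arange(0, 100 + bin_width_pct, bin_width_pct)
    levels = bins.covered["level"].to_numpy() * 100.0
    counts, _ = np.histogram(levels, bins=edges)  # last interval closed
    return pd.DataFrame({"lo_pct": edges[:-1], "hi_pct": edges[1:], "count": counts})
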