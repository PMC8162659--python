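"""Core record types and the canonical in-memory container.

A methylome is held as a pandas DataFrame with one row per strand-resolved
cytosine observation (columns :data:`COLUMNS`).  ``pos`` is the 1-based
position of the C on the forward coordinate system regardless of strand,
matching the Bismark cytosine-report convention; ``tri`` is the trinucleotide
read 5'->3' on the cytosine's own strand and therefore always starts with C.
Strand-merged CG records carry strand ``"."`` and are keyed to the
plus-strand C.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import pandas as pd


class CytosineRecord(NamedTuple):
    """One cytosine's strand-resolved methylation observation."""

    chrom: str
    pos: int  # 1-based position of the C
    strand: str  # '+', '-' or '.' (strand-merged CG)
    count_meth: int
    count_unmeth: int
    context: str  # CG / CHG / CHH
    tri: str  # trinucleotide on the C's strand, N-padded at contig ends

    @property
    def depth(self) -> int:
        return self.count_meth + self.count_unmeth

    @property
    def level(self) -> float:
        """Methylation fraction; NaN at zero depth."""
        d = self.depth
        return self.count_meth / d if d else float("nan")


COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "tri"]

_DTYPES = {
    "chrom": "object",
    "pos": "int64",
    "strand": "object",
    "count_meth": "int64",
    "count_unmeth": "int64",
    "context": "object",
    "tri": "object",
}


def empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})


def records_to_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = list(records)
    if not rows:
        return empty_frame()
    return pd.DataFrame(rows, columns=COLUMNS).astype(_DTYPES)


def frame_to_records(frame: pd.DataFrame) -> list[CytosineRecord]:
    return [CytosineRecord(*row) for row in frame[COLUMNS].itertuples(index=False)]


def validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Check the record-frame invariants; returns the frame for chaining."""
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"record frame missing columns: {missing}")
    if len(frame):
        if (frame["count_meth"] < 0).any() or (frame["count_unmeth"] < 0).any():
            raise ValueError("negative methylation counts")
        bad_strand = ~frame["strand"].isin(["+", "-", "."])
        if bad_strand.any():
            raise ValueError(f"invalid strand values: {frame.loc[bad_strand, 'strand'].unique()}")
    return frame
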