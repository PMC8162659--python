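"""Non-CG (CH) methylation by dinucleotide/trinucleotide context, and the
next-nucleotide preference of the methylating enzyme.

CH analyses stay strand-resolved; the "next" base is the base 3' of the CH
dinucleotide on the cytosine's own strand (the third base of the
trinucleotide).  The next-base preference distinguishes DNMT3A-style
(C-preferring) from DNMT3B-style (G-preferring) activity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import records_to_frame

NEXT_BASES = ("A", "C", "G", "T")


def _ch_frame(records) -> pd.DataFrame:
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    ch = records[records["context"] != "CG"]
    # drop edge sites whose dinucleotide is undefined (N-padded)
    return ch[~ch["tri"].str[:2].str.contains("N")]


def ch_levels(records, grouping: str = "dinucleotide") -> pd.DataFrame:
    """Weighted CH methylation level per dinucleotide or trinucleotide.

    Strand-resolved; CG records are excluded.  Raises on zero covered CH
    sites.  Dinucleotide levels are by construction the count-weighted
    averages of their constituent trinucleotide levels.
    """
    ch = _ch_frame(records).copy()
    if grouping == "dinucleotide":
        ch["group"] = ch["tri"].str[:2]
    elif grouping == "trinucleotide":
        ch = ch[~ch["tri"].str.contains("N")]
        ch["group"] = ch["tri"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    total = (ch["count_meth"] + ch["count_unmeth"]).sum()
    if total == 0:
        raise ValueError("CH level undefined: zero covered CH sites")
    agg = ch.groupby("group").agg(
        count_meth=("count_meth", "sum"),
        count_unmeth=("count_unmeth", "sum"),
        n_sites=("pos", "size"))
    agg["total_depth"] = agg["count_meth"] + agg["count_unmeth"]
    agg["level"] = agg["count_meth"] / agg["total_depth"].where(agg["total_depth"] > 0)
    return agg[["level", "count_meth", "total_depth", "n_sites"]]


def next_nucleotide_preference(records, genome=None) -> pd.DataFrame:
    """Distribution over {A,C,G,T} of the base following methylated CH sites.

    preference[b] = Σ count_meth at CH sites whose next base is b, divided
    by Σ count_meth over all CH sites (methylation-count weighted, not a
    binary site call); background[b] is the same ratio computed with total
    counts.  Both columns sum to 1.  The next base is read from the stored
    trinucleotide; ``genome`` (a fixture, mapping, or FASTA path) is only
    consulted to resolve sites whose trinucleotide is N-padded.
    """
    ch = _ch_frame(records).copy()
    nxt = ch["tri"].str[2]
    if genome is not None and (nxt == "N").any():
        from .io import _contigs_of
        seqs = dict(_contigs_of(genome))
        need = ch[nxt == "N"]
        resolved = []
        for chrom, pos, strand in need[["chrom", "pos", "strand"]].itertuples(index=False):
            seq = seqs[chrom]
            base = seq[pos + 1] if strand == "+" and pos + 1 < len(seq) else "N"
            resolved.append(base)
        nxt = nxt.copy()
        nxt[nxt == "N"] = resolved
    ch["next"] = nxt
    ch = ch[ch["next"].isin(NEXT_BASES)]
    meth = ch.groupby("next")["count_meth"].sum().reindex(NEXT_BASES, fill_value=0)
    tot = (ch["count_meth"] + ch["count_unmeth"]).groupby(ch["next"]).sum() \
        .reindex(NEXT_BASES, fill_value=0)
    if meth.sum() == 0 or tot.sum() == 0:
        raise ValueError("next-base preference undefined: no methylated CH counts")
    return pd.DataFrame({
        "preference": meth / meth.sum(),
        "background": tot / tot.sum(),
    })
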