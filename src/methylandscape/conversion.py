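"""Bisulfite conversion-rate QC from an unmethylated spike-in contig.

Every cytosine on the spike-in (lambda-phage-style) contig is truly
unmethylated, so reads calling it methylated measure conversion failure.
All contexts are pooled; count pooling across sites makes per-site depth
filters unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import QCError
from .records import records_to_frame


@dataclass(frozen=True)
class ConversionEstimate:
    rate: float  # fraction of unmethylated Cs successfully converted
    n_cytosines_observed: int
    total_depth: int

    @property
    def error_rate(self) -> float:
        """Apparent-methylation error, 1 - rate."""
        return 1.0 - self.rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "conversion_rate": self.rate,
            "error_rate": self.error_rate,
            "n_cytosines": self.n_cytosines_observed,
            "total_depth": self.total_depth,
        }])


def estimate_conversion(records, spike_in_name: str) -> ConversionEstimate:
    """Pool all spike-in cytosine counts into one conversion-rate estimate.

    rate = Σ unmethylated / Σ (methylated + unmethylated) over every context
    on the spike-in contig.  Zero spike-in coverage is a QC failure, never a
    rate of 0.
    """
    if not isinstance(records, pd.DataFrame):
        records = records_to_frame(records)
    spike = records[records["chrom"] == spike_in_name]
    depth = spike["count_meth"] + spike["count_unmeth"]
    total = int(depth.sum())
    if total == 0:
        raise QCError(f"no coverage on spike-in contig {spike_in_name!r}")
    meth = int(spike["count_meth"].sum())
    return ConversionEstimate(
        rate=(total - meth) / total,
        n_cytosines_observed=int((depth > 0).sum()),
        total_depth=total,
    )
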