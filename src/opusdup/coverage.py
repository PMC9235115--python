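"""Coverage-uniformity QC over a target panel.

Raw coverage is counted per fixed-size bin (a read is assigned to the bin
containing its leftmost aligned position, so counts are conserved), then
normalized by the median across all bins and log2-transformed. Per-bin GC
fraction is reported alongside when a reference is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd


@dataclass
class CoverageParams:
    bin_size: int = 50

    def __post_init__(self):
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")


def read_bed(path: str) -> List[Tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]


def make_bins(targets: Iterable[Tuple[str, int, int]], bin_size: int
              ) -> pd.DataFrame:
    rows = []
    for chrom, start, end in targets:
        for b in range(start, end, bin_size):
            rows.append((chrom, b, min(b + bin_size, end)))
    df = pd.DataFrame(rows, columns=["chrom", "bin_start", "bin_end"])
    df["partial"] = (df.bin_end - df.bin_start) < bin_size
    return df


def bin_coverage(reads: Iterable, targets: List[Tuple[str, int, int]],
                 params: Optional[CoverageParams] = None,
                 reference: Optional[dict] = None) -> pd.DataFrame:
    """Per-bin raw counts, median-normalized log2 coverage, and GC fraction.

    ``reference`` maps chrom -> sequence (for GC); a trailing partial bin is
    kept and flagged. With an all-zero median the normalized columns are NaN
    and ``undefined_normalization`` is set on ``DataFrame.attrs``.
    """
    params = params or CoverageParams()
    bins = make_bins(targets, params.bin_size)
    counts = np.zeros(len(bins), dtype=np.int64)
    # bin lookup per chrom: interval starts
    by_chrom = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        by_chrom[chrom] = (grp.bin_start.to_numpy(), grp.bin_end.to_numpy(),
                           grp.index.to_numpy())
    for r in reads:
        info = by_chrom.get(r.chrom)
        if info is None:
            continue
        starts, ends, idx = info
        i = np.searchsorted(starts, r.pos, side="right") - 1
        if i >= 0 and r.pos < ends[i]:
            counts[idx[i]] += 1
    bins["raw"] = counts
    med = float(np.median(counts))
    if med == 0:
        bins["normalized"] = np.nan
        bins["log2norm"] = np.nan
        bins.attrs["undefined_normalization"] = True
    else:
        norm = counts / med
        bins["normalized"] = norm
        with np.errstate(divide="ignore"):
            bins["log2norm"] = np.log2(norm)
        bins.attrs["undefined_normalization"] = False
    if reference is not None:
        gc = []
        for row in bins.itertuples():
            seq = reference.get(row.chrom, "")[row.bin_start:row.bin_end].upper()
            gc.append((seq.count("G") + seq.count("C")) / len(seq) if seq else np.nan)
        bins["gc"] = gc
    return bins
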