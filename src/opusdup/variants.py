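"""Per-position base counting, variant incidence, VAF and significance.

Base-count tables are built per analysis level: ``filtered`` (quality-
filtered mapped reads, Phred >= 30 per base), ``SSCS`` and ``DCS``
(consensus reads, no base-quality filter — their bases are already
consensus calls). Only substitutions are counted; N never counts.
Per-position significance against a background sample uses a 2x2
chi-squared test on (ref, var) counts followed by Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

_BASES = "ACGT"
_CODE = {ord(b): i for i, b in enumerate(_BASES)}


@dataclass
class PileupParams:
    min_base_quality: int = 30  # applied to raw filtered reads only
    end_trim: int = 0  # 7 in sonication mode
    count_substitutions_only: bool = True
    target_region: Optional[Tuple[str, int, int]] = None

    def __post_init__(self):
        if self.min_base_quality < 0 or self.end_trim < 0:
            raise ValueError("min_base_quality and end_trim must be >= 0")


class BaseCountTable:
    """Counts of A/C/G/T per position over a target region.

    ``counts`` is an (L, 4) integer array; column order A, C, G, T.
    """

    def __init__(self, chrom: str, start: int, end: int, reference: str,
                 level: str = "filtered"):
        if end <= start:
            raise ValueError("empty target region")
        if len(reference) != end - start:
            raise ValueError("reference slice length must match the region")
        self.chrom = chrom
        self.start = start
        self.end = end
        self.reference = reference.upper()
        self.level = level
        self.counts = np.zeros((end - start, 4), dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end)

    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def ref_index(self) -> np.ndarray:
        return np.frombuffer(self.reference.encode(), np.uint8)

    def ref_counts(self) -> np.ndarray:
        idx = np.array([_CODE.get(c, -1) for c in self.ref_index()])
        out = np.zeros(len(self.reference), dtype=np.int64)
        ok = idx >= 0
        out[ok] = self.counts[np.nonzero(ok)[0], idx[ok]]
        return out

    def variant_counts(self) -> np.ndarray:
        return self.coverage() - self.ref_counts()

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(_BASES))
        df.insert(0, "chrom", self.chrom)
        df.insert(1, "pos", self.positions)
        df.insert(2, "ref", list(self.reference))
        df["level"] = self.level
        return df

    def write_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def countable_span(pos: int, length: int, end_trim: int) -> Tuple[int, int]:
    """Aligned interval of a read that survives end trimming (may be empty)."""
    lo = pos + end_trim
    hi = pos + length - end_trim
    return (lo, hi) if hi > lo else (lo, lo)


def trim_read_ends(sequence: str, end_trim: int) -> str:
    """Mask the first and last ``end_trim`` bases to N (library-prep damage
    concentrates at fragment ends)."""
    if end_trim == 0 or not sequence:
        return sequence
    n = min(end_trim, len(sequence))
    masked = "N" * n
    if 2 * n >= len(sequence):
        return "N" * len(sequence)
    return masked + sequence[n:len(sequence) - n] + masked


def build_base_counts(reads: Iterable, reference: str, level: str = "filtered",
                      params: Optional[PileupParams] = None,
                      chrom: Optional[str] = None,
                      region: Optional[Tuple[int, int]] = None) -> BaseCountTable:
    """Pile up aligned reads (or consensus reads) into a base-count table.

    ``reference`` is the full reference sequence of the contig; ``region``
    restricts counting (default: whole contig). The Phred cutoff applies only
    at the ``filtered`` level; N and out-of-region bases never count.
    """
    params = params or PileupParams()
    reads = list(reads)
    if chrom is None:
        if params.target_region is not None:
            chrom = params.target_region[0]
        else:
            chrom = reads[0].chrom if reads else "ref"
    if region is None:
        region = (params.target_region[1], params.target_region[2]) \
            if params.target_region is not None else (0, len(reference))
    start, end = region
    if end > len(reference):
        raise ValueError("target region extends beyond the reference")
    table = BaseCountTable(chrom, start, end, reference[start:end], level)
    qcut = params.min_base_quality if level == "filtered" else 0
    trim = params.end_trim
    for r in reads:
        seq = np.frombuffer(r.sequence.encode(), np.uint8)
        n = seq.size
        lo, hi = countable_span(r.pos, n, trim)
        if hi <= lo:
            continue
        lo = max(lo, start)
        hi = min(hi, end)
        if hi <= lo:
            continue
        sl = slice(lo - r.pos, hi - r.pos)
        sub = seq[sl]
        keep = sub != ord("N")
        if qcut > 0:
            qual = np.frombuffer(bytes(r.base_qualities), np.uint8)[sl]
            keep &= qual >= qcut
        pos_idx = np.arange(lo - start, hi - start)[keep]
        base_idx = np.searchsorted(np.frombuffer(b"ACGT", np.uint8), sub[keep])
        np.add.at(table.counts, (pos_idx, base_idx), 1)
    return table


@dataclass
class IncidenceReport:
    level: str
    excluded_positions: List[int]
    variant_bases: int
    total_bases: int
    incidence: float
    undefined: bool = False


def variant_incidence(table: BaseCountTable,
                      excluded_positions: Sequence[int] = ()) -> IncidenceReport:
    """Variant bases / total bases, after removing excluded positions
    (spiked-in and known germline variants) entirely."""
    excluded = sorted(set(excluded_positions))
    mask = np.ones(table.end - table.start, dtype=bool)
    for p in excluded:
        if table.start <= p < table.end:
            mask[p - table.start] = False
    total = int(table.coverage()[mask].sum())
    var = int(table.variant_counts()[mask].sum())
    if total == 0:
        return IncidenceReport(table.level, excluded, var, 0, float("nan"), True)
    return IncidenceReport(table.level, excluded, var, total, var / total)


def vaf(table: BaseCountTable, position: int, alt: str) -> float:
    """Variant allele fraction of ``alt`` at a position (undefined -> nan)."""
    if not table.start <= position < table.end:
        raise ValueError("position outside table region")
    i = position - table.start
    if alt == table.reference[i]:
        raise ValueError("requested alt equals the reference base")
    cov = int(table.counts[i].sum())
    if cov == 0:
        return float("nan")
    return int(table.counts[i, _BASES.index(alt)]) / cov


@dataclass
class PositionTestResult:
    position: int
    alt: str
    var_test: int
    ref_test: int
    var_background: int
    ref_background: int
    vaf_test: float
    vaf_background: float
    chi2: float
    p: float
    q: float = float("nan")
    significant: bool = False


def test_vs_background(test_table: BaseCountTable,
                       background_table: BaseCountTable,
                       fdr: float = 0.05,
                       continuity_correction: bool = False
                       ) -> List[PositionTestResult]:
    """Chi-squared + BH test of every (position, alt) where the test sample
    shows a higher VAF than the background.

    Positions with zero coverage in either sample are not testable. The BH
    pool is all tested (position, alt) pairs; ``significant`` means
    BH-adjusted q <= fdr.
    """
    if (test_table.start, test_table.end) != (background_table.start,
                                              background_table.end):
        raise ValueError("tables must cover the same region")
    results: List[PositionTestResult] = []
    cov_t = test_table.coverage()
    cov_b = background_table.coverage()
    ref_t = test_table.ref_counts()
    ref_b = background_table.ref_counts()
    for i in range(test_table.end - test_table.start):
        if cov_t[i] == 0 or cov_b[i] == 0:
            continue
        refbase = test_table.reference[i]
        for j, alt in enumerate(_BASES):
            if alt == refbase:
                continue
            vt = int(test_table.counts[i, j])
            vb = int(background_table.counts[i, j])
            f_t = vt / cov_t[i]
            f_b = vb / cov_b[i]
            if f_t <= f_b:
                continue
            tab = np.array([[vt, ref_t[i]], [vb, ref_b[i]]])
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                chi2, p = 0.0, 1.0
            else:
                chi2, p = chi2_contingency(tab, correction=continuity_correction)[:2]
            results.append(PositionTestResult(
                position=test_table.start + i, alt=alt,
                var_test=vt, ref_test=int(ref_t[i]),
                var_background=vb, ref_background=int(ref_b[i]),
                vaf_test=f_t, vaf_background=f_b,
                chi2=float(chi2), p=float(p)))
    if results:
        qs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qs):
            r.q = float(q)
            r.significant = q <= fdr
    return results


def results_to_dataframe(results: Sequence[PositionTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
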