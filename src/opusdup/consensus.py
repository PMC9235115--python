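"""Tag families, single-strand and duplex consensus sequences.

Reads sharing (genomic boundary, combined UMI, pair orientation, read
number) descend from one strand of one original duplex and form a tag
family. A family of at least ``min_family_size`` reads yields a
single-strand consensus sequence (SSCS): at each position the base seen in
strictly more than ``agreement_threshold`` (default 2/3) of reads is
written, else N. The two SSCS descending from opposite strands of the same
duplex are then compared position-wise: a duplex consensus (DCS) base is
kept only where both agree and neither is N, which removes every error
confined to a single strand.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .records import AlignedReadRecord, ConsensusRead, TagFamilyKey, partner_key

_SYMBOLS = b"ACGT"


@dataclass
class ConsensusParams:
    min_family_size: int = 3
    agreement_threshold: Union[Fraction, float, str] = Fraction(2, 3)
    pad_symbol: str = "N"

    def __post_init__(self):
        if self.min_family_size < 1:
            raise ValueError("min_family_size must be >= 1")
        t = self.agreement_threshold
        if not isinstance(t, Fraction):
            # exact rational arithmetic so the 2-of-3 boundary is judged
            # correctly; a float 2/3 would pass what the strict rule rejects
            t = Fraction(t) if isinstance(t, str) else Fraction(t).limit_denominator(10**6)
            self.agreement_threshold = t
        if not 0 < self.agreement_threshold < 1:
            raise ValueError("agreement_threshold must be in (0, 1)")


@dataclass
class RecoveryReport:
    """DCS recovery: number of DCS / (number of SSCS / 2)."""

    n_sscs: int
    n_dcs: int
    recovery: float
    undefined: bool = False


def family_key(read: AlignedReadRecord) -> TagFamilyKey:
    return TagFamilyKey(read.chrom, read.fragment_start, read.fragment_end,
                        read.umi_combined, read.orientation, read.read_number)


def group_families(records: Iterable[AlignedReadRecord]
                   ) -> Tuple[Dict[TagFamilyKey, List[AlignedReadRecord]],
                              List[AlignedReadRecord]]:
    """Group reads into tag families; records missing a boundary or UMI go
    to the reject bin."""
    families: Dict[TagFamilyKey, List[AlignedReadRecord]] = defaultdict(list)
    rejects: List[AlignedReadRecord] = []
    for r in records:
        if r.fragment_start < 0 or r.fragment_end <= r.fragment_start or not r.umi_combined:
            rejects.append(r)
            continue
        families[family_key(r)].append(r)
    return dict(families), rejects


def pad_family(reads: Sequence[AlignedReadRecord], pad_symbol: str = "N"
               ) -> Tuple[List[str], int]:
    """Equalize read lengths over the family footprint.

    Each read is placed at its genomic offset within [min(pos), max(end));
    positions a read does not cover are padded with N. Original bases are
    never altered. Returns the padded sequences and the footprint start.
    """
    start = min(r.pos for r in reads)
    end = max(r.end for r in reads)
    width = end - start
    out = []
    for r in reads:
        off = r.pos - start
        out.append(pad_symbol * off + r.sequence
                   + pad_symbol * (width - off - len(r.sequence)))
    return out, start


def call_sscs(key: TagFamilyKey, reads: Sequence[AlignedReadRecord],
              params: Optional[ConsensusParams] = None) -> Optional[ConsensusRead]:
    """Single-strand consensus of one tag family, or None below the family
    size minimum.

    N in member reads counts toward the denominator but can never be written
    as a winning base (the output is N either way)."""
    params = params or ConsensusParams()
    k = len(reads)
    if k < params.min_family_size:
        return None
    padded, start = pad_family(reads, params.pad_symbol)
    mat = np.frombuffer("".join(padded).encode(), dtype=np.uint8).reshape(k, -1)
    counts = np.stack([(mat == c).sum(axis=0) for c in _SYMBOLS])
    best = counts.argmax(axis=0)
    best_count = counts.max(axis=0)
    thr = params.agreement_threshold
    # strict: count/k > threshold  <=>  count * den > num * k
    wins = best_count * thr.denominator > thr.numerator * k
    codes = np.frombuffer(_SYMBOLS, np.uint8)[best]
    seq = np.where(wins, codes, ord("N")).astype(np.uint8)
    return ConsensusRead(
        level="SSCS", key=key, chrom=key.chrom, pos=start,
        is_reverse=reads[0].is_reverse, sequence=seq.tobytes().decode(),
        family_size=k)


def call_all_sscs(families: Dict[TagFamilyKey, List[AlignedReadRecord]],
                  params: Optional[ConsensusParams] = None) -> List[ConsensusRead]:
    params = params or ConsensusParams()
    out = []
    for key in sorted(families):
        c = call_sscs(key, families[key], params)
        if c is not None:
            out.append(c)
    return out


class DisjointFootprintsError(ValueError):
    pass


@dataclass
class PairingResult:
    pairs: List[Tuple[ConsensusRead, ConsensusRead]]
    unpaired: List[ConsensusRead]
    n_ambiguous: int = 0


def pair_sscs(sscs: Sequence[ConsensusRead]) -> PairingResult:
    """Match SSCS into duplex partners by the strand-swap rule.

    The partner of family (boundary, alpha+beta, orientation, read r) is
    (boundary, beta+alpha, swapped orientation, read 3-r): read 1 of one
    strand covers the same fragment end as read 2 of the other. Tag-family
    keys are exact tuples, so each SSCS has at most one partner; pairs are
    emitted with the lexicographically smaller key first.
    """
    by_key: Dict[TagFamilyKey, ConsensusRead] = {}
    ambiguous = 0
    for c in sscs:
        if c.key in by_key:  # duplicate keys would make pairing ambiguous
            ambiguous += 1
            continue
        by_key[c.key] = c
    pairs = []
    unpaired = []
    for key in sorted(by_key):
        c = by_key[key]
        pk = partner_key(key)
        partner = by_key.get(pk)
        if partner is None:
            unpaired.append(c)
        elif key < pk:
            pairs.append((c, partner))
    return PairingResult(pairs, unpaired, ambiguous)


def call_dcs(sscs_a: ConsensusRead, sscs_b: ConsensusRead) -> ConsensusRead:
    """Duplex consensus over the overlap of two partner SSCS: a base is kept
    only where both SSCS carry the same non-N base."""
    start = max(sscs_a.pos, sscs_b.pos)
    end = min(sscs_a.end, sscs_b.end)
    if end <= start:
        raise DisjointFootprintsError(
            f"SSCS footprints do not overlap: {sscs_a.key} / {sscs_b.key}")
    a = np.frombuffer(sscs_a.sequence.encode(), np.uint8)[start - sscs_a.pos:
                                                          end - sscs_a.pos]
    b = np.frombuffer(sscs_b.sequence.encode(), np.uint8)[start - sscs_b.pos:
                                                          end - sscs_b.pos]
    seq = np.where((a == b) & (a != ord("N")), a, ord("N")).astype(np.uint8)
    return ConsensusRead(
        level="DCS", key=sscs_a.key, key_b=sscs_b.key, chrom=sscs_a.chrom,
        pos=start, is_reverse=sscs_a.is_reverse,
        sequence=seq.tobytes().decode(),
        family_size=sscs_a.family_size, family_size_b=sscs_b.family_size)


def call_all_dcs(sscs: Sequence[ConsensusRead]
                 ) -> Tuple[List[ConsensusRead], PairingResult]:
    pairing = pair_sscs(sscs)
    return [call_dcs(a, b) for a, b in pairing.pairs], pairing


def compute_recovery(n_sscs: int, n_dcs: int) -> RecoveryReport:
    """DCS recovery = n_dcs / (n_sscs / 2); undefined when no SSCS exist."""
    if n_sscs < 0 or n_dcs < 0:
        raise ValueError("counts must be non-negative")
    if n_sscs == 0:
        return RecoveryReport(0, n_dcs, float("nan"), undefined=True)
    return RecoveryReport(n_sscs, n_dcs, n_dcs / (n_sscs / 2))


def family_size_histogram(families: Dict[TagFamilyKey, List]) -> Dict[int, int]:
    return dict(sorted(Counter(len(v) for v in families.values()).items()))


def consensus_read_name(c: ConsensusRead) -> str:
    sizes = str(c.family_size) if c.key_b is None else f"{c.family_size},{c.family_size_b}"
    k = c.key
    return (f"{c.level}:{k.chrom}:{k.fragment_start}-{k.fragment_end}:"
            f"{k.umi_combined}:{k.orientation}:r{k.read_number}:fs={sizes}")


def parse_consensus_name(name: str) -> dict:
    level, chrom, span, umi, orient, rnum, fs = name.split(":")
    start, end = span.split("-")
    sizes = [int(x) for x in fs[3:].split(",")]
    return {
        "level": level,
        "key": TagFamilyKey(chrom, int(start), int(end), umi, orient, int(rnum[1:])),
        "family_sizes": sizes,
    }


def write_consensus_fastq(consensus_reads: Sequence[ConsensusRead], path: str) -> None:
    """FASTQ with constant Q40 for called bases and Q2 for N."""
    with open(path, "w") as out:
        for c in consensus_reads:
            qual = "".join(chr(q + 33) for q in c.base_qualities)
            out.write(f"@{consensus_read_name(c)}\n{c.sequence}\n+\n{qual}\n")
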