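"""Core record types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; conversion
to 1-based happens only at SAM emission.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(slots=True)
class AlignedReadRecord:
    """One mapped read with its UMI and duplex bookkeeping.

    ``pos`` is the 0-based leftmost aligned position; the aligned end is
    ``pos + len(sequence)`` (reads are treated as fully aligned blocks;
    clipped-base semantics are out of scope). ``sequence`` is stored in
    reference-forward orientation, as in SAM.
    """

    read_id: str
    chrom: str
    pos: int
    mapq: int
    is_reverse: bool
    read_number: int
    sequence: str
    base_qualities: bytes
    mate_chrom: str = ""
    mate_pos: int = -1
    fragment_start: int = -1
    fragment_end: int = -1
    umi_self: str = ""
    umi_combined: str = ""
    orientation: str = ""

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned block."""
        return self.pos + len(self.sequence)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"


class TagFamilyKey(NamedTuple):
    """Grouping key: genomic boundary + combined UMI + orientation + read number.

    ``umi_combined`` is the UMI of the read-1 side followed by the UMI of the
    read-2 side; the two library molecules derived from the two strands of one
    duplex therefore carry the two halves in swapped order.
    """

    chrom: str
    fragment_start: int
    fragment_end: int
    umi_combined: str
    orientation: str
    read_number: int


_ORIENT_SWAP = {"FR": "RF", "RF": "FR", "FF": "RR", "RR": "FF"}


def partner_key(key: TagFamilyKey) -> TagFamilyKey:
    """Key of the tag family descending from the opposite strand that covers
    the same genomic footprint (strand-swap rule).

    Read 1 of one strand starts at the same fragment end as read 2 of the
    other strand, and the combined UMI halves appear in swapped order, so the
    partner has the halves swapped, the read number flipped and the pair
    orientation label (read1-based) exchanged FR<->RF.
    """
    umi = key.umi_combined
    half = len(umi) // 2
    return TagFamilyKey(
        key.chrom,
        key.fragment_start,
        key.fragment_end,
        umi[half:] + umi[:half],
        _ORIENT_SWAP.get(key.orientation, key.orientation),
        3 - key.read_number,
    )


@dataclass(slots=True)
class ConsensusRead:
    """An SSCS or DCS with per-position calls (base or N)."""

    level: str  # "SSCS" or "DCS"
    key: TagFamilyKey
    chrom: str
    pos: int
    is_reverse: bool
    sequence: str
    family_size: int
    key_b: Optional[TagFamilyKey] = None
    family_size_b: int = 0

    @property
    def end(self) -> int:
        return self.pos + len(self.sequence)

    @property
    def base_qualities(self) -> bytes:
        # constant Q40 for called bases, Q2 for N
        return bytes(2 if c == "N" else 40 for c in self.sequence)


@dataclass(slots=True)
class RawRead:
    """A raw (unaligned) read, used in FASTQ/UMI-extraction mode."""

    name: str
    sequence: str
    quality: str
    umi: str = ""
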