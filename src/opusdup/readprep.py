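"""UMI extraction from raw reads and pair-level filtering of alignments.

The filter keeps convergently mapped pairs (FR or RF, read1-based labels)
on the same chromosome with both mates at MAPQ >= 36, mirroring the
pre-consensus cleanup step of the duplex workflow.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pysam

from .records import AlignedReadRecord, RawRead


@dataclass
class PairFilterParams:
    min_mapq: int = 36
    allowed_orientations: Set[str] = field(default_factory=lambda: {"FR", "RF"})
    require_same_chrom: bool = True

    def __post_init__(self):
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


def extract_umi(read1: RawRead, read2: RawRead, umi_length: int
                ) -> Optional[Tuple[RawRead, RawRead]]:
    """Split the first ``umi_length`` bases off each mate as its UMI.

    Returns the tagged pair, or None when either mate is too short to carry
    a UMI plus at least one template base (callers count the drop).
    """
    if umi_length == 0:
        return read1, read2
    if len(read1.sequence) <= umi_length or len(read2.sequence) <= umi_length:
        return None
    out = []
    for r in (read1, read2):
        out.append(RawRead(
            name=r.name,
            sequence=r.sequence[umi_length:],
            quality=r.quality[umi_length:],
            umi=r.sequence[:umi_length],
        ))
    return out[0], out[1]


def pair_orientation(r1: AlignedReadRecord, r2: AlignedReadRecord) -> str:
    """Read1-based orientation label.

    FR / RF are convergent (the leftmost mate maps forward, the rightmost
    reverse); FF / RR are tandem; divergent face-away pairs get their own
    label so they can be rejected like tandem ones.
    """
    if r1.is_reverse == r2.is_reverse:
        return "RR" if r1.is_reverse else "FF"
    fwd, rev = (r2, r1) if r1.is_reverse else (r1, r2)
    if fwd.pos <= rev.pos:
        return "RF" if r1.is_reverse else "FR"
    return "divergent"


def filter_pair(r1: AlignedReadRecord, r2: AlignedReadRecord,
                params: PairFilterParams) -> Tuple[bool, Optional[str]]:
    """Keep/drop decision with a per-category reason."""
    if params.require_same_chrom and r1.chrom != r2.chrom:
        return False, "chrom_mismatch"
    if r1.mapq < params.min_mapq or r2.mapq < params.min_mapq:
        return False, "low_mapq"
    if pair_orientation(r1, r2) not in params.allowed_orientations:
        return False, "orientation"
    return True, None


def fragment_boundary(r1: AlignedReadRecord, r2: AlignedReadRecord
                      ) -> Tuple[str, int, int]:
    """Genomic boundary of the originating fragment: the interval hull of
    the two mates' aligned blocks (0-based half-open)."""
    if r1.chrom != r2.chrom:
        raise ValueError("mates on different chromosomes have no boundary")
    return r1.chrom, min(r1.pos, r2.pos), max(r1.end, r2.end)


@dataclass
class PairFilterStats:
    n_pairs_in: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def as_dict(self) -> Dict[str, int]:
        d = {"pairs_in": self.n_pairs_in, "pairs_kept": self.n_kept}
        d.update({f"dropped_{k}": v for k, v in sorted(self.dropped.items())})
        return d


def pair_up(records: Iterable[AlignedReadRecord]
            ) -> Tuple[List[Tuple[AlignedReadRecord, AlignedReadRecord]], int]:
    """Match read 1 / read 2 mates by read id; returns pairs and the number
    of unpaired records."""
    by_id: Dict[str, List[Optional[AlignedReadRecord]]] = defaultdict(lambda: [None, None])
    order: List[str] = []
    for r in records:
        slot = by_id[r.read_id]
        if slot[0] is None and slot[1] is None:
            order.append(r.read_id)
        slot[r.read_number - 1] = r
    pairs = []
    unpaired = 0
    for rid in order:
        r1, r2 = by_id[rid]
        if r1 is None or r2 is None:
            unpaired += 1
            continue
        pairs.append((r1, r2))
    return pairs, unpaired


def prepare_pairs(records: Iterable[AlignedReadRecord],
                  params: Optional[PairFilterParams] = None
                  ) -> Tuple[List[AlignedReadRecord], PairFilterStats]:
    """Pair, filter, and annotate records with boundary, orientation and
    combined UMI; returns the kept records (both mates) and accounting."""
    params = params or PairFilterParams()
    pairs, unpaired = pair_up(records)
    stats = PairFilterStats(n_pairs_in=len(pairs) + unpaired)
    stats.dropped["unpaired"] = unpaired
    kept: List[AlignedReadRecord] = []
    for r1, r2 in pairs:
        ok, reason = filter_pair(r1, r2, params)
        if not ok:
            stats.dropped[reason] += 1
            continue
        chrom, start, end = fragment_boundary(r1, r2)
        orient = pair_orientation(r1, r2)
        combined = r1.umi_self + r2.umi_self
        for r in (r1, r2):
            r.fragment_start = start
            r.fragment_end = end
            r.orientation = orient
            if not r.umi_combined:
                r.umi_combined = combined
        stats.n_kept += 1
        kept.extend((r1, r2))
    return kept, stats


def _reference_projected(a: "pysam.AlignedSegment") -> Tuple[str, bytes]:
    """Project a read onto the reference span it aligns to.

    Matches/mismatches keep their base and quality; deletions and reference
    skips become N (quality 0), so they never contribute to base counts;
    insertions and clipped bases are dropped. The result has length equal to
    the alignment's reference span, restoring the block-alignment convention
    the rest of the pipeline uses."""
    seq = a.query_sequence
    quals = a.query_qualities
    if quals is None:
        quals = [30] * len(seq)
    cig = a.cigartuples or [(0, len(seq))]
    if all(op in (0, 7, 8) for op, _ in cig):  # pure match blocks
        return seq, bytes(quals)
    out_seq: List[str] = []
    out_q: List[int] = []
    qpos = 0
    for op, n in cig:
        if op in (0, 7, 8):  # M, =, X consume both
            out_seq.append(seq[qpos:qpos + n])
            out_q.extend(quals[qpos:qpos + n])
            qpos += n
        elif op in (1, 4):  # insertion / soft clip consume query only
            qpos += n
        elif op in (2, 3):  # deletion / ref skip consume reference only
            out_seq.append("N" * n)
            out_q.extend([0] * n)
        # 5 (hard clip) and 6 (pad) consume neither
    return "".join(out_seq), bytes(out_q)


def records_from_sam(path: str, umi_length: int = 6) -> List[AlignedReadRecord]:
    """Load mapped reads from SAM/BAM into pipeline records.

    The combined UMI is taken from the RX tag and the read's own UMI from OX
    when present; otherwise a trailing ``_<UMI>`` read-name suffix
    (umi-tools style) is used as the read's own UMI.
    """
    out: List[AlignedReadRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            umi_combined = a.get_tag("RX") if a.has_tag("RX") else ""
            if a.has_tag("OX"):
                umi_self = a.get_tag("OX")
            elif "_" in a.query_name:
                umi_self = a.query_name.rsplit("_", 1)[1]
            else:
                umi_self = ""
            seq, qual = _reference_projected(a)
            out.append(AlignedReadRecord(
                read_id=a.query_name,
                chrom=a.reference_name,
                pos=a.reference_start,
                mapq=a.mapping_quality,
                is_reverse=a.is_reverse,
                read_number=2 if a.is_read2 else 1,
                sequence=seq,
                base_qualities=qual,
                mate_chrom=a.next_reference_name or "",
                mate_pos=a.next_reference_start,
                umi_self=umi_self,
                umi_combined=umi_combined,
            ))
    return out
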