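"""Synthetic duplex sequencing data with ground truth.

Emulates the data-generating process that double-stranded-UMI error
correction assumes: each original DNA duplex carries one random UMI at each
end; each strand is amplified independently into a read family; three error
channels operate at different stages:

* ``seq_error`` — introduced independently in every read copy (sequencer /
  late-PCR noise);
* ``ss_damage`` — introduced once on ONE strand of the molecule before
  amplification (e.g. base damage), so all reads of that strand share it;
* ``ds_artifact`` — introduced on BOTH strands of the molecule (e.g.
  fragmentase/end-repair nick-translation artifacts), so it survives duplex
  consensus.

Spike-in variants model known SNPs mixed at a defined allele fraction; with
``heterozygous_spike`` the carrier genotype is heterozygous, so the fraction
of molecules by mass drawn from the carrier genotype is twice the allele
fraction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .records import AlignedReadRecord, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {c: i for i, c in enumerate(b"ACGT")}


class ConfigError(ValueError):
    pass


@dataclass(slots=True)
class SpikeVariant:
    """A known variant spiked into a defined fraction of molecules."""

    position: int  # 0-based on the reference
    alt: str
    allele_fraction: float
    ref: str = ""  # filled from the reference at simulation time


@dataclass
class SimulatorConfig:
    reference_length: int = 432
    gc_fraction: float = 0.5
    chrom: str = "sim1"
    n_duplexes: int = 1000
    fragment_mean: float = 150.0
    fragment_sd: float = 15.0
    read_length: int = 100
    umi_length: int = 6
    umi_alphabet: str = "CGT"  # dA-free adapters
    reads_per_strand_mean: float = 5.0
    reads_per_strand_min: int = 1
    spike_variants: List[SpikeVariant] = field(default_factory=list)
    heterozygous_spike: bool = False
    seq_error_rate: float = 0.0
    umi_seq_errors: bool = True
    ss_damage_rate: float = 0.0
    ds_artifact_rate: float = 0.0
    # scalar (same for both strands) or (top, bottom)
    strand_dropout_prob: Union[float, Tuple[float, float]] = 0.0
    seed: int = 0

    def spike_mass_fraction(self, sv: SpikeVariant) -> float:
        """Fraction of molecules (by mass) drawn from the carrier genotype.

        Heterozygous carriers contribute two alleles per genome but only one
        carries the variant, so the genotype's mass fraction is exactly
        twice the allele fraction."""
        return 2.0 * sv.allele_fraction if self.heterozygous_spike \
            else sv.allele_fraction

    def dropout_probs(self) -> Tuple[float, float]:
        p = self.strand_dropout_prob
        if isinstance(p, (tuple, list)):
            return float(p[0]), float(p[1])
        return float(p), float(p)

    def validate(self) -> None:
        if self.reference_length <= 0:
            raise ConfigError("reference_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ConfigError("gc_fraction must be in [0, 1]")
        for name in ("seq_error_rate", "ss_damage_rate", "ds_artifact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for p in self.dropout_probs():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("strand_dropout_prob must be in [0, 1]")
        if self.umi_length < 0:
            raise ConfigError("umi_length must be >= 0")
        if self.reads_per_strand_min < 1:
            raise ConfigError("reads_per_strand_min must be >= 1")
        if self.reads_per_strand_mean < self.reads_per_strand_min:
            raise ConfigError("reads_per_strand_mean below its minimum")
        for sv in self.spike_variants:
            if not 0 <= sv.position < self.reference_length:
                raise ConfigError(f"spike position {sv.position} outside reference")
            if not 0.0 <= sv.allele_fraction <= 1.0:
                raise ConfigError("allele_fraction must be in [0, 1]")
            if self.heterozygous_spike and sv.allele_fraction > 0.5:
                raise ConfigError("heterozygous spike allele_fraction must be <= 0.5")


@dataclass(slots=True)
class DuplexTruthRecord:
    """Ground truth for one simulated duplex molecule.

    ``events`` holds (position, channel, strand) with channel in
    {seq_error is NOT recorded here — it is per read copy — ss_damage,
    ds_artifact, spike} and strand in {top, bottom, both}.
    """

    molecule_id: int
    chrom: str
    start: int
    end: int
    umi_top: str  # UMI at the fragment's left end (read 1 of the top strand)
    umi_bottom: str  # UMI at the fragment's right end
    events: List[Tuple[int, str, str]] = field(default_factory=list)
    strands_surviving: Tuple[str, ...] = ("top", "bottom")


def simulate_reference(config: SimulatorConfig) -> str:
    """Random reference sequence with the configured GC fraction."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.reference_length
    is_gc = rng.random(n) < config.gc_fraction
    pick = rng.integers(0, 2, size=n)
    # AT -> A/T, GC -> G/C
    codes = np.where(is_gc, np.where(pick == 0, ord("G"), ord("C")),
                     np.where(pick == 0, ord("A"), ord("T")))
    return codes.astype(np.uint8).tobytes().decode()


def _random_umi(rng: np.random.Generator, alphabet: str, k: int) -> str:
    idx = rng.integers(0, len(alphabet), size=k)
    return "".join(alphabet[i] for i in idx)


def _mutate(rng: np.random.Generator, arr: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Replace bases at ``positions`` with a uniformly chosen different base.

    Returns the new base codes (uint8)."""
    cur = arr[positions]
    shift = rng.integers(1, 4, size=positions.size)
    cur_idx = np.searchsorted(BASES, cur)
    new = BASES[(cur_idx + shift) % 4]
    arr[positions] = new
    return new


def simulate_duplexes(
    config: SimulatorConfig, reference: str
) -> Tuple[List[AlignedReadRecord], List[DuplexTruthRecord]]:
    """Simulate duplex molecules and their read pairs.

    Returns aligned read records (in molecule order, not coordinate order)
    and one truth record per emitted molecule. Molecules whose fragment is
    shorter than the UMI handling window are skipped; use :func:`simulate`
    for the full bundle including the skip count.
    """
    records, truth, _ = _simulate(config, reference)
    return records, truth


@dataclass
class SimulationResult:
    reference: str
    records: List[AlignedReadRecord]
    truth: List[DuplexTruthRecord]
    n_skipped_short: int


def simulate(config: SimulatorConfig) -> SimulationResult:
    """Full simulation bundle: reference, reads, truth, skip count."""
    reference = simulate_reference(config)
    records, truth, skipped = _simulate(config, reference)
    return SimulationResult(reference, records, truth, skipped)


def _simulate(config, reference):
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ref = np.frombuffer(reference.encode(), dtype=np.uint8).copy()
    L = len(ref)
    k = config.umi_length
    p_top, p_bottom = config.dropout_probs()
    spikes = []
    for sv in config.spike_variants:
        refbase = chr(ref[sv.position])
        if sv.ref and sv.ref != refbase:
            raise ConfigError(
                f"spike ref {sv.ref} at {sv.position} does not match reference {refbase}")
        spikes.append((sv.position, ord(sv.alt),
                       config.spike_mass_fraction(sv), refbase))

    records: List[AlignedReadRecord] = []
    truth: List[DuplexTruthRecord] = []
    n_skipped = 0

    frag_lens = np.maximum(
        1, np.rint(rng.normal(config.fragment_mean, config.fragment_sd,
                              size=config.n_duplexes)).astype(int))
    frag_lens = np.minimum(frag_lens, L)

    for mid in range(config.n_duplexes):
        flen = int(frag_lens[mid])
        if flen < max(1, k):
            n_skipped += 1
            continue
        start = int(rng.integers(0, L - flen + 1))
        end = start + flen
        umi_top = _random_umi(rng, config.umi_alphabet, k)
        umi_bottom = _random_umi(rng, config.umi_alphabet, k)
        events: List[Tuple[int, str, str]] = []

        mol = ref[start:end].copy()
        # spike-in variants (double-stranded, real biology)
        for pos, alt, mass_fraction, _refbase in spikes:
            if not (start <= pos < end):
                continue
            # molecule drawn from the carrier genotype by mass; heterozygous
            # carriers transmit the variant allele half the time
            carrier = rng.random() < mass_fraction
            if carrier and config.heterozygous_spike:
                carrier = rng.random() < 0.5
            if carrier:
                mol[pos - start] = alt
                events.append((pos, "spike", "both"))

        # double-strand artifacts: both strands changed consistently
        if config.ds_artifact_rate > 0:
            hits = np.nonzero(rng.random(flen) < config.ds_artifact_rate)[0]
            if hits.size:
                _mutate(rng, mol, hits)
                events.extend((start + int(p), "ds_artifact", "both") for p in hits)

        # single-strand damage: each hit lands on exactly one strand
        top_view = mol
        bottom_view = mol
        if config.ss_damage_rate > 0:
            hits = np.nonzero(rng.random(flen) < config.ss_damage_rate)[0]
            if hits.size:
                on_top = rng.random(hits.size) < 0.5
                if on_top.any():
                    top_view = mol.copy()
                    _mutate(rng, top_view, hits[on_top])
                if (~on_top).any():
                    bottom_view = mol.copy()
                    _mutate(rng, bottom_view, hits[~on_top])
                events.extend(
                    (start + int(p), "ss_damage", "top" if t else "bottom")
                    for p, t in zip(hits, on_top))

        surviving = []
        if rng.random() >= p_top:
            surviving.append("top")
        if rng.random() >= p_bottom:
            surviving.append("bottom")

        truth.append(DuplexTruthRecord(
            molecule_id=mid, chrom=config.chrom, start=start, end=end,
            umi_top=umi_top, umi_bottom=umi_bottom, events=events,
            strands_surviving=tuple(surviving)))

        rl = min(config.read_length, flen)
        r1_span = (start, start + rl)
        r2_span = (end - rl, end)
        for strand in surviving:
            view = top_view if strand == "top" else bottom_view
            # UMI adjacent to read 1's sequencing start: top reads start at
            # the left end (umi_top); bottom reads start at the right end.
            u1, u2 = (umi_top, umi_bottom) if strand == "top" else (umi_bottom, umi_top)
            n_pairs = config.reads_per_strand_min + (
                rng.poisson(config.reads_per_strand_mean - config.reads_per_strand_min)
                if config.reads_per_strand_mean > config.reads_per_strand_min else 0)
            for i in range(int(n_pairs)):
                pair = _emit_pair(rng, config, view, start, rl, r1_span, r2_span,
                                  strand, u1, u2, mid, i)
                records.extend(pair)
    return records, truth, n_skipped


def _read_bases(rng, config, view, frag_start, span):
    seq = view[span[0] - frag_start: span[1] - frag_start].copy()
    qual = np.full(seq.size, 37, dtype=np.uint8)
    e = config.seq_error_rate
    if e > 0:
        hits = np.nonzero(rng.random(seq.size) < e)[0]
        if hits.size:
            _mutate(rng, seq, hits)
            low = hits[rng.random(hits.size) < 0.5]
            qual[low] = 20
    return seq.tobytes().decode(), qual.tobytes()


def _umi_with_errors(rng, config, umi: str) -> str:
    if not (config.umi_seq_errors and config.seq_error_rate > 0 and umi):
        return umi
    arr = np.frombuffer(umi.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < config.seq_error_rate)[0]
    if hits.size:
        _mutate(rng, arr, hits)
        return arr.tobytes().decode()
    return umi


def _emit_pair(rng, config, view, frag_start, rl, r1_span, r2_span,
               strand, u1, u2, mid, copy_idx):
    frag_end = frag_start + (view.size)
    name = f"mol{mid}:{strand}:{copy_idx}"
    seq1, q1 = _read_bases(rng, config, view, frag_start, r1_span)
    seq2, q2 = _read_bases(rng, config, view, frag_start, r2_span)
    umi1 = _umi_with_errors(rng, config, u1)
    umi2 = _umi_with_errors(rng, config, u2)
    combined = umi1 + umi2
    if strand == "top":
        r1_pos, r1_rev = r1_span[0], False
        r2_pos, r2_rev = r2_span[0], True
        orientation = "FR"
    else:
        # the bottom-strand molecule is sequenced from the right end first
        seq1, seq2 = seq2, seq1
        q1, q2 = q2, q1
        r1_pos, r1_rev = r2_span[0], True
        r2_pos, r2_rev = r1_span[0], False
        orientation = "RF"
    common = dict(chrom=config.chrom, mapq=60,
                  fragment_start=frag_start, fragment_end=frag_end,
                  umi_combined=combined, orientation=orientation)
    rec1 = AlignedReadRecord(
        read_id=name, pos=r1_pos, is_reverse=r1_rev, read_number=1,
        sequence=seq1, base_qualities=q1, mate_chrom=config.chrom,
        mate_pos=r2_pos, umi_self=umi1, **common)
    rec2 = AlignedReadRecord(
        read_id=name, pos=r2_pos, is_reverse=r2_rev, read_number=2,
        sequence=seq2, base_qualities=q2, mate_chrom=config.chrom,
        mate_pos=r1_pos, umi_self=umi2, **common)
    return rec1, rec2


class UnsortedStreamError(ValueError):
    pass


def write_sam(records: Sequence[AlignedReadRecord], path: str, chrom: str,
              reference_length: int, coordinate_sorted: bool = False) -> None:
    """Write records as SAM with correct FLAG/POS/PNEXT/TLEN for the pairs.

    With ``coordinate_sorted`` the input must already be sorted by position
    (an :class:`UnsortedStreamError` is raised otherwise) and the header
    declares ``SO:coordinate``.
    """
    if coordinate_sorted:
        last = -1
        for r in records:
            if r.pos < last:
                raise UnsortedStreamError("records not coordinate-sorted")
            last = r.pos
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate" if coordinate_sorted else "unsorted"},
        "SQ": [{"SN": chrom, "LN": int(reference_length)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.cigar = [(0, len(r.sequence))]
            a.query_sequence = r.sequence
            a.query_qualities = list(r.base_qualities)
            flag = 0x1 | 0x2
            flag |= 0x40 if r.read_number == 1 else 0x80
            if r.is_reverse:
                flag |= 0x10
            else:
                flag |= 0x20  # mate reverse for convergent pairs
            a.flag = flag
            a.next_reference_id = 0
            a.next_reference_start = r.mate_pos
            tlen = r.fragment_end - r.fragment_start
            a.template_length = tlen if r.pos == r.fragment_start else -tlen
            a.set_tag("RX", r.umi_combined)
            a.set_tag("OX", r.umi_self)
            out.write(a)


def write_fastq(records: Sequence[AlignedReadRecord], prefix: str) -> Tuple[str, str]:
    """Emit raw-mode paired FASTQ: each read begins with its own UMI.

    Reads are written in sequencing orientation (reverse-strand records are
    reverse-complemented back), with the UMI prepended at constant Q37.
    """
    paths = (f"{prefix}_R1.fastq", f"{prefix}_R2.fastq")
    handles = [open(p, "w") for p in paths]
    try:
        for r in records:
            seq = revcomp(r.sequence) if r.is_reverse else r.sequence
            qual = r.base_qualities[::-1] if r.is_reverse else r.base_qualities
            qstr = "".join(chr(q + 33) for q in qual)
            umi_q = chr(37 + 33) * len(r.umi_self)
            h = handles[r.read_number - 1]
            h.write(f"@{r.read_id}\n{r.umi_self}{seq}\n+\n{umi_q}{qstr}\n")
    finally:
        for h in handles:
            h.close()
    return paths


def write_truth(truth: Sequence[DuplexTruthRecord], path: str) -> None:
    with open(path, "w") as out:
        out.write("molecule_id\tchrom\tstart\tend\tumi_top\tumi_bottom\t"
                  "events\tstrands_surviving\n")
        for t in truth:
            ev = ",".join(f"{p}:{c}:{s}" for p, c, s in t.events) or "."
            ss = ",".join(t.strands_surviving) or "."
            out.write(f"{t.molecule_id}\t{t.chrom}\t{t.start}\t{t.end}\t"
                      f"{t.umi_top}\t{t.umi_bottom}\t{ev}\t{ss}\n")


def read_truth(path: str) -> List[DuplexTruthRecord]:
    out: List[DuplexTruthRecord] = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            events = []
            if f[6] != ".":
                for item in f[6].split(","):
                    p, c, s = item.split(":")
                    events.append((int(p), c, s))
            strands = tuple(f[7].split(",")) if f[7] != "." else ()
            out.append(DuplexTruthRecord(
                int(f[0]), f[1], int(f[2]), int(f[3]), f[4], f[5],
                events, strands))
    return out


def write_bed(path: str, chrom: str, start: int, end: int, name: str = "target") -> None:
    with open(path, "w") as out:
        out.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_fasta(path: str, chrom: str, sequence: str) -> None:
    with open(path, "w") as out:
        out.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            out.write(sequence[i:i + 70] + "\n")
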