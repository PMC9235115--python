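"""Tag families, SSCS/DCS calling, duplex pairing and recovery."""

import itertools
import math
from fractions import Fraction

import pytest
from scipy.stats import binom

from opusdup import (SimulatorConfig, call_dcs, call_sscs, compute_recovery,
                     group_families, pad_family, pair_sscs, partner_key,
                     simulate)
from opusdup.consensus import (ConsensusParams, DisjointFootprintsError,
                               call_all_dcs, call_all_sscs,
                               consensus_read_name, family_size_histogram,
                               parse_consensus_name, write_consensus_fastq)
from opusdup.records import AlignedReadRecord, ConsensusRead, TagFamilyKey
from tests.conftest import run_consensus_pipeline


def fam_read(sequence, pos=100, number=1, reverse=False, umi="CGTCGTCGTCGT",
             boundary=(100, 250), rid="r"):
    return AlignedReadRecord(
        read_id=rid, chrom="sim1", pos=pos, mapq=60, is_reverse=reverse,
        read_number=number, sequence=sequence,
        base_qualities=bytes([37] * len(sequence)),
        fragment_start=boundary[0], fragment_end=boundary[1],
        umi_combined=umi, orientation="FR")


KEY = TagFamilyKey("sim1", 100, 250, "CGTCGTCGTCGT", "FR", 1)


class TestGroupFamilies:
    def test_one_duplex_gives_four_families_of_three(self, one_duplex):
        assert len(one_duplex.families) == 4
        assert sorted(len(v) for v in one_duplex.families.values()) == [3] * 4
        # two families per combined-UMI order (one per read number)
        umis = {k.umi_combined for k in one_duplex.families}
        assert len(umis) == 2

    def test_single_read_forms_singleton_family(self):
        fams, rejects = group_families([fam_read("A" * 10)])
        assert len(fams) == 1 and not rejects
        (members,) = fams.values()
        assert len(members) == 1

    def test_shared_boundary_different_umis_gives_eight_families(self):
        cfg = SimulatorConfig(reference_length=300, n_duplexes=2,
                              fragment_mean=150, fragment_sd=0,
                              reads_per_strand_mean=3, reads_per_strand_min=3,
                              seed=101)
        res = simulate(cfg)
        # force identical boundaries
        for r in res.records:
            r.pos = r.pos - r.fragment_start + 50
            r.fragment_start, r.fragment_end = 50, 200
        fams, _ = group_families(res.records)
        assert len(fams) == 8

    def test_record_without_umi_rejected(self):
        r = fam_read("ACGT")
        r.umi_combined = ""
        fams, rejects = group_families([r])
        assert not fams and rejects == [r]


class TestPadFamily:
    def test_shorter_read_padded_with_n(self):
        reads = [fam_read("A" * 98), fam_read("A" * 100), fam_read("A" * 100)]
        padded, start = pad_family(reads)
        assert start == 100
        assert [len(s) for s in padded] == [100, 100, 100]
        assert padded[0].endswith("NN") and padded[0][:98] == "A" * 98

    def test_equal_lengths_unchanged(self):
        reads = [fam_read("ACGT"), fam_read("TTTT")]
        padded, _ = pad_family(reads)
        assert padded == ["ACGT", "TTTT"]

    def test_single_read_unchanged(self):
        padded, start = pad_family([fam_read("ACGTACGT", pos=42)])
        assert padded == ["ACGTACGT"] and start == 42

    def test_reverse_family_pads_genomic_left(self):
        # reverse-strand reads share their genomic end; the shorter read is
        # missing bases on the genomic left
        reads = [fam_read("C" * 100, pos=150, reverse=True),
                 fam_read("C" * 98, pos=152, reverse=True)]
        padded, start = pad_family(reads)
        assert start == 150
        assert padded[1].startswith("NN")


class TestCallSscs:
    def test_two_of_three_is_not_over_two_thirds(self):
        reads = [fam_read("A"), fam_read("A"), fam_read("T")]
        c = call_sscs(KEY, reads)
        assert c.sequence == "N"

    def test_unanimous_family(self):
        reads = [fam_read("ACGT")] * 3
        c = call_sscs(KEY, reads)
        assert c.sequence == "ACGT"
        assert c.level == "SSCS" and c.family_size == 3

    def test_family_below_minimum_gives_none(self):
        assert call_sscs(KEY, [fam_read("A"), fam_read("A")]) is None

    def test_three_of_four_is_over_two_thirds(self):
        reads = [fam_read("A")] * 3 + [fam_read("T")]
        assert call_sscs(KEY, reads).sequence == "A"

    def test_n_counts_in_denominator_but_never_wins_as_base(self):
        # 2 A + 1 N of 3: A is 2/3, not strictly over -> N
        reads = [fam_read("A"), fam_read("A"), fam_read("N")]
        assert call_sscs(KEY, reads).sequence == "N"
        # 3 A + 1 N of 4: 3/4 > 2/3 -> A
        reads = [fam_read("A")] * 3 + [fam_read("N")]
        assert call_sscs(KEY, reads).sequence == "A"


class TestDuplexPairing:
    def test_error_free_duplex_pairs_into_two_dcs(self, one_duplex):
        assert len(one_duplex.sscs) == 4
        assert len(one_duplex.pairing.pairs) == 2
        assert len(one_duplex.dcs) == 2
        assert not one_duplex.pairing.unpaired

    def test_partner_key_swaps_umi_halves_and_read_number(self):
        key = TagFamilyKey("sim1", 10, 60, "AAACCCGGGTTT", "FR", 1)
        pk = partner_key(key)
        assert pk.umi_combined == "GGGTTTAAACCC"
        assert pk.read_number == 2 and pk.orientation == "RF"
        assert partner_key(pk) == key  # involution

    def test_dropped_strand_leaves_sscs_unpaired(self, one_duplex_cfg):
        one_duplex_cfg.strand_dropout_prob = (0.0, 1.0)
        out = run_consensus_pipeline(one_duplex_cfg)
        assert len(out.sscs) == 2
        assert not out.pairing.pairs and len(out.pairing.unpaired) == 2
        assert len(out.dcs) == 0

    def test_swapped_umis_with_different_boundaries_not_paired(self):
        a = ConsensusRead("SSCS", TagFamilyKey("sim1", 10, 60, "AAATTT", "FR", 1),
                          "sim1", 10, False, "A" * 50, 3)
        b = ConsensusRead("SSCS", TagFamilyKey("sim1", 20, 70, "TTTAAA", "RF", 2),
                          "sim1", 20, False, "A" * 50, 3)
        res = pair_sscs([a, b])
        assert not res.pairs and len(res.unpaired) == 2


class TestCallDcs:
    def _cons(self, seq, pos=100, umi="AAACCC", rn=1, orient="FR"):
        return ConsensusRead("SSCS", TagFamilyKey("sim1", 100, 250, umi,
                                                  orient, rn),
                             "sim1", pos, False, seq, 3)

    def test_identical_sscs_give_identical_dcs(self):
        d = call_dcs(self._cons("ACGT"), self._cons("ACGT", umi="CCCAAA", rn=2))
        assert d.sequence == "ACGT" and d.level == "DCS"

    def test_disagreement_becomes_n(self):
        d = call_dcs(self._cons("ACGT"), self._cons("AGGT", umi="CCCAAA", rn=2))
        assert d.sequence == "ANGT"

    def test_n_propagates(self):
        d = call_dcs(self._cons("ANGT"), self._cons("ANGT", umi="CCCAAA", rn=2))
        assert d.sequence == "ANGT"

    def test_disjoint_footprints_raise(self):
        with pytest.raises(DisjointFootprintsError):
            call_dcs(self._cons("ACGT", pos=100),
                     self._cons("ACGT", pos=500, umi="CCCAAA", rn=2))


class TestRecovery:
    def test_perfect_pairing_gives_one(self):
        assert compute_recovery(4, 2).recovery == 1.0

    def test_published_regime_arithmetic(self):
        assert compute_recovery(10000, 1100).recovery == pytest.approx(0.22)

    def test_zero_dcs(self):
        assert compute_recovery(10, 0).recovery == 0.0

    def test_zero_sscs_undefined(self):
        rep = compute_recovery(0, 0)
        assert rep.undefined and math.isnan(rep.recovery)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_recovery(-1, 0)


def test_sscs_error_suppression_matches_binomial_tail():
    """P(per-read error rate e fixes a wrong base into the SSCS) equals the
    binomial tail P(Bin(k, e/3) > 2k/3), checked by full enumeration of
    per-read outcomes through call_sscs for k in {3, 4, 5}."""
    e = 0.1
    ref, wrong = "A", "C"
    for k in (3, 4, 5):
        p_via_rule = 0.0
        # each read independently shows ref (1-e) or one of 3 wrong bases e/3
        for outcome in itertools.product([ref, "C", "G", "T"], repeat=k):
            prob = 1.0
            for b in outcome:
                prob *= (1 - e) if b == ref else e / 3
            reads = [fam_read(b) for b in outcome]
            if call_sscs(KEY, reads).sequence == wrong:
                p_via_rule += prob
        thresh = math.floor(2 * k / 3)  # consensus needs count > 2k/3
        p_closed = binom.sf(thresh, k, e / 3)
        assert p_via_rule == pytest.approx(p_closed, rel=1e-9)


def test_dcs_never_exceeds_half_sscs():
    cfg = SimulatorConfig(n_duplexes=300, strand_dropout_prob=0.4,
                          seq_error_rate=0.005, seed=77)
    out = run_consensus_pipeline(cfg)
    assert len(out.dcs) <= len(out.sscs) / 2
    # every SSCS consumed by at most one DCS
    consumed = [d.key for d in out.dcs] + [d.key_b for d in out.dcs]
    assert len(consumed) == len(set(consumed))


def test_family_size_histogram():
    cfg = SimulatorConfig(n_duplexes=100, seed=3)
    out = run_consensus_pipeline(cfg)
    hist = family_size_histogram(out.families)
    assert sum(k * v for k, v in hist.items()) == len(out.kept)


def test_consensus_name_round_trip(one_duplex, tmp_path):
    for c in one_duplex.sscs + one_duplex.dcs:
        parsed = parse_consensus_name(consensus_read_name(c))
        assert parsed["level"] == c.level
        assert parsed["key"] == c.key
        assert parsed["family_sizes"][0] == c.family_size
    path = str(tmp_path / "out.fastq")
    write_consensus_fastq(one_duplex.dcs, path)
    lines = open(path).read().splitlines()
    assert len(lines) == 4 * len(one_duplex.dcs)
    assert set(lines[3]) <= {"I", "#"}  # Q40 called / Q2 for N


def test_empty_consensus_fastq(tmp_path):
    path = str(tmp_path / "empty.fastq")
    write_consensus_fastq([], path)
    assert open(path).read() == ""


def test_configurable_threshold_uses_exact_arithmetic():
    params = ConsensusParams(agreement_threshold=Fraction(1, 2))
    reads = [fam_read("A"), fam_read("A"), fam_read("T"), fam_read("T")]
    # 2/4 is not strictly over 1/2
    assert call_sscs(KEY, reads, params).sequence == "N"
    reads = [fam_read("A")] * 3 + [fam_read("T")]
    assert call_sscs(KEY, reads, params).sequence == "A"
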