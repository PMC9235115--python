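import pytest

from opusdup import (SimulatorConfig, call_all_dcs, call_all_sscs,
                     group_families, prepare_pairs, simulate)
from opusdup.consensus import ConsensusParams
from opusdup.umi import UmiCorrectionParams, correct_umis


def run_consensus_pipeline(cfg: SimulatorConfig,
                           consensus_params: ConsensusParams | None = None,
                           umi_params: UmiCorrectionParams | None = None):
    """Simulate and collapse to SSCS/DCS; returns a simple namespace."""
    res = simulate(cfg)
    kept, fstats = prepare_pairs(res.records)
    correct_umis(kept, umi_params)
    families, rejects = group_families(kept)
    sscs = call_all_sscs(families, consensus_params)
    dcs, pairing = call_all_dcs(sscs)
    ns = pytest.Namespace if hasattr(pytest, "Namespace") else None
    class NS:
        pass
    out = NS()
    out.sim = res
    out.kept = kept
    out.filter_stats = fstats
    out.families = families
    out.rejects = rejects
    out.sscs = sscs
    out.dcs = dcs
    out.pairing = pairing
    return out


@pytest.fixture
def one_duplex_cfg():
    """One duplex, both strands, 3 error-free read pairs per strand."""
    return SimulatorConfig(
        reference_length=432, n_duplexes=1, fragment_mean=150, fragment_sd=0,
        read_length=100, reads_per_strand_mean=3, reads_per_strand_min=3,
        seed=7)


@pytest.fixture
def one_duplex(one_duplex_cfg):
    return run_consensus_pipeline(one_duplex_cfg)
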