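"""Canonical in-silico experiments for validating the duplex workflow.

Each scenario fixes the simulator to a defined error regime and runs the
full collapse (pair filter -> UMI correction -> families -> SSCS -> DCS ->
base counts), returning the measured quantities. They encode the study
conditions the method is meant to handle:

* ``channel_separation`` — realistic per-read error and single-strand
  damage rates, no double-strand artifacts: duplex consensus must remove
  every non-spike variant.
* ``all_channels`` — the same plus a 0.1% per-base double-strand artifact
  rate (the fragmentase regime): only those survive into DCS.
* ``vaf_series`` — spike-in dilution series at 1%, 0.1%, 0.05% and 0.01%
  VAF against a variant-free background, sized so the lowest level is
  detectable (expected >= ~10 alternate molecules at duplex level).
* ``dropout_recovery`` — per-strand survival s with guaranteed family
  sizes, where DCS recovery has closed form s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .consensus import call_all_dcs, call_all_sscs, compute_recovery, group_families
from .readprep import prepare_pairs
from .sim import SimulatorConfig, SpikeVariant, simulate, simulate_reference
from .umi import correct_umis
from .variants import (BaseCountTable, build_base_counts, test_vs_background,
                       vaf, variant_incidence)


@dataclass
class CollapseResult:
    reference: str
    n_records: int
    n_families: int
    family_sizes: List[int]
    sscs: list
    dcs: list
    recovery: object
    tables: Dict[str, BaseCountTable]


def collapse(cfg: SimulatorConfig,
             reference: Optional[str] = None) -> CollapseResult:
    """Simulate under ``cfg`` and run the full consensus workflow.

    ``reference`` lets several samples (e.g. a dilution series and its
    background) share one reference sequence."""
    if reference is None:
        res = simulate(cfg)
    else:
        from .sim import simulate_duplexes

        class _Res:
            pass
        res = _Res()
        res.reference = reference
        res.records, res.truth = simulate_duplexes(cfg, reference)
    kept, _ = prepare_pairs(res.records)
    correct_umis(kept)
    families, _ = group_families(kept)
    sscs = call_all_sscs(families)
    dcs, _ = call_all_dcs(sscs)
    tables = {
        "filtered": build_base_counts(kept, res.reference, "filtered"),
        "SSCS": build_base_counts(sscs, res.reference, "SSCS"),
        "DCS": build_base_counts(dcs, res.reference, "DCS"),
    }
    return CollapseResult(res.reference, len(res.records), len(families),
                          [len(v) for v in families.values()], sscs, dcs,
                          compute_recovery(len(sscs), len(dcs)), tables)


def one_duplex_config(seed: int = 7) -> SimulatorConfig:
    """One error-free duplex, both strands, three read pairs per strand."""
    return SimulatorConfig(reference_length=432, n_duplexes=1,
                           fragment_mean=150, fragment_sd=0, read_length=100,
                           reads_per_strand_mean=3, reads_per_strand_min=3,
                           seed=seed)


def error_regime_config(seed: int, n_duplexes: int = 10_000,
                        ds_artifact_rate: float = 0.0) -> SimulatorConfig:
    """A realistic short-read error regime: 0.3% per-read sequencing error,
    0.5% single-strand damage, and an optional double-strand artifact rate."""
    return SimulatorConfig(reference_length=432, n_duplexes=n_duplexes,
                           fragment_mean=150, fragment_sd=10, read_length=100,
                           seq_error_rate=0.003, ss_damage_rate=0.005,
                           ds_artifact_rate=ds_artifact_rate, seed=seed)


def channel_separation(seed: int, n_duplexes: int = 10_000) -> dict:
    """Single-strand-only errors: DCS must contain zero non-spike variants."""
    out = collapse(error_regime_config(seed, n_duplexes, ds_artifact_rate=0.0))
    inc = {lvl: variant_incidence(t) for lvl, t in out.tables.items()}
    return {
        "dcs_variant_bases": inc["DCS"].variant_bases,
        "dcs_total_bases": inc["DCS"].total_bases,
        "incidence": {lvl: r.incidence for lvl, r in inc.items()},
    }


def all_channels(seed: int, n_duplexes: int = 10_000,
                 ds_artifact_rate: float = 0.001) -> dict:
    """All three channels active; DCS incidence estimates the double-strand
    artifact rate."""
    out = collapse(error_regime_config(seed, n_duplexes, ds_artifact_rate))
    inc = {lvl: variant_incidence(t) for lvl, t in out.tables.items()}
    return {
        "incidence": {lvl: r.incidence for lvl, r in inc.items()},
        "total_bases": {lvl: r.total_bases for lvl, r in inc.items()},
        "dcs_total_bases": inc["DCS"].total_bases,
        "ds_artifact_rate": ds_artifact_rate,
    }


# dilution series: allele fraction -> number of simulated duplexes; the
# lowest level is sized for ~10 expected alternate molecules at duplex level
VAF_SERIES_LEVELS: Dict[float, int] = {
    0.01: 16_000,
    0.001: 16_000,
    0.0005: 16_000,
    0.0001: 100_000,
}
VAF_BACKGROUND_DUPLEXES = 60_000
_SPIKE_POS = 40


def _vaf_series_config(seed: int, n_duplexes: int,
                       spike: Optional[SpikeVariant]) -> SimulatorConfig:
    cfg = SimulatorConfig(reference_length=90, n_duplexes=n_duplexes,
                          fragment_mean=55, fragment_sd=3, read_length=50,
                          reads_per_strand_mean=3, reads_per_strand_min=3,
                          seed=seed)
    if spike is not None:
        cfg.spike_variants = [spike]
    return cfg


def vaf_series(seed: int, scale: float = 1.0, fdr: float = 0.05) -> dict:
    """Run the spike-in dilution series and the per-position significance
    test of each level against a variant-free background.

    ``scale`` multiplies every sample size (tests use 1.0; smaller values
    give a quick smoke run). Returns per-level observed VAF, duplex-level
    coverage, significance call, and the false-positive count."""
    base_cfg = _vaf_series_config(seed, 1, None)
    ref = simulate_reference(base_cfg)
    refbase = ref[_SPIKE_POS]
    alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[refbase]

    bg_cfg = _vaf_series_config(seed, max(2, int(VAF_BACKGROUND_DUPLEXES * scale)),
                                None)
    bg = collapse(bg_cfg, reference=ref)
    bg_table = bg.tables["DCS"]

    levels = {}
    false_positives = 0
    for i, (af, n) in enumerate(sorted(VAF_SERIES_LEVELS.items(), reverse=True)):
        cfg = _vaf_series_config(seed + 1000 * (i + 1), max(2, int(n * scale)),
                                 SpikeVariant(position=_SPIKE_POS, alt=alt,
                                              allele_fraction=af))
        out = collapse(cfg, reference=ref)
        table = out.tables["DCS"]
        cov = int(table.coverage()[_SPIKE_POS])
        observed = vaf(table, _SPIKE_POS, alt) if cov else float("nan")
        results = test_vs_background(table, bg_table, fdr=fdr)
        flagged = any(r.position == _SPIKE_POS and r.alt == alt and r.significant
                      for r in results)
        false_positives += sum(r.significant for r in results
                               if not (r.position == _SPIKE_POS and r.alt == alt))
        levels[af] = {
            "expected_vaf": af,
            "observed_vaf": observed,
            "dcs_coverage": cov,
            "alt_count": int(table.counts[_SPIKE_POS, "ACGT".index(alt)]),
            "flagged": flagged,
            "n_tests": len(results),
        }
    return {"levels": levels, "false_positives": false_positives,
            "background_dcs_coverage": int(bg_table.coverage()[_SPIKE_POS])}


def dropout_recovery(seed: int, survival: float = 0.6,
                     n_duplexes: int = 4000) -> dict:
    """Per-strand survival s with >= 3 reads guaranteed per surviving
    strand; expected DCS recovery equals s."""
    cfg = SimulatorConfig(reference_length=300, n_duplexes=n_duplexes,
                          fragment_mean=120, fragment_sd=8, read_length=80,
                          reads_per_strand_mean=3, reads_per_strand_min=3,
                          strand_dropout_prob=1.0 - survival, seed=seed)
    out = collapse(cfg)
    return {"survival": survival, "recovery": out.recovery.recovery,
            "n_sscs": out.recovery.n_sscs, "n_dcs": out.recovery.n_dcs}
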