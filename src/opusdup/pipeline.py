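"""End-to-end orchestration: simulate/load -> filter -> UMI-correct ->
consensus -> base counts -> incidence -> coverage QC, with a run manifest.

The pipeline runs either in ``simulate`` mode (inputs generated with ground
truth) or ``real-bam`` mode (coordinate-sorted SAM/BAM with UMI tags plus a
reference FASTA and target BED)."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pysam
import yaml

from . import __version__
from .consensus import (ConsensusParams, call_all_dcs, call_all_sscs,
                        compute_recovery, family_size_histogram,
                        group_families, write_consensus_fastq)
from .coverage import CoverageParams, bin_coverage, read_bed
from .readprep import PairFilterParams, prepare_pairs, records_from_sam
from .sim import (SimulatorConfig, simulate, write_bed, write_fasta,
                  write_sam, write_truth)
from .umi import UmiCorrectionParams, correct_umis
from .variants import (PileupParams, build_base_counts, results_to_dataframe,
                       test_vs_background, variant_incidence)

log = logging.getLogger("opusdup")


@dataclass
class PipelineConfig:
    mode: str = "simulate"  # or "real-bam"
    out_dir: str = "opusdup_out"
    seed: int = 0
    sim: SimulatorConfig = field(default_factory=SimulatorConfig)
    pair_filter: PairFilterParams = field(default_factory=PairFilterParams)
    umi: UmiCorrectionParams = field(default_factory=UmiCorrectionParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    pileup: PileupParams = field(default_factory=PileupParams)
    coverage: CoverageParams = field(default_factory=CoverageParams)
    excluded_positions: List[int] = field(default_factory=list)
    input_bam: Optional[str] = None
    reference_fasta: Optional[str] = None
    target_bed: Optional[str] = None
    write_outputs: bool = True
    write_raw_fastq: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, sub in (("sim", SimulatorConfig),
                         ("pair_filter", PairFilterParams),
                         ("umi", UmiCorrectionParams),
                         ("consensus", ConsensusParams),
                         ("pileup", PileupParams),
                         ("coverage", CoverageParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = dict(kwargs[key])
                if key == "sim":
                    from .sim import SpikeVariant
                    sub_kwargs["spike_variants"] = [
                        SpikeVariant(**sv) if isinstance(sv, dict) else sv
                        for sv in sub_kwargs.get("spike_variants", [])]
                kwargs[key] = sub(**sub_kwargs)
        cfg = cls(**kwargs)
        if "seed" in raw and "sim" not in raw:
            cfg.sim.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        def enc(x):
            if dataclasses.is_dataclass(x) and not isinstance(x, type):
                return {k: enc(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, (set, frozenset)):
                return sorted(x)
            if isinstance(x, (list, tuple)):
                return [enc(v) for v in x]
            if hasattr(x, "numerator") and not isinstance(x, (int, bool)):
                return str(x)
            return x
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


@dataclass
class PipelineResult:
    config: PipelineConfig
    reference: str
    tables: Dict[str, object]          # level -> BaseCountTable
    incidence: Dict[str, object]       # level -> IncidenceReport
    recovery: object
    coverage: object                   # DataFrame
    manifest: dict
    sscs: list
    dcs: list
    truth: list


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    manifest: dict = {
        "opusdup_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    out = config.out_dir
    if config.write_outputs:
        os.makedirs(out, exist_ok=True)

    # --- stage: inputs -----------------------------------------------------
    truth = []
    if config.mode == "simulate":
        if config.seed and not config.sim.seed:
            config.sim.seed = config.seed
        simres = simulate(config.sim)
        reference = simres.reference
        records = simres.records
        truth = simres.truth
        chrom = config.sim.chrom
        targets = [(chrom, 0, len(reference))]
        manifest["stages"]["simulate"] = {
            "n_duplexes": config.sim.n_duplexes,
            "n_records": len(records),
            "n_truth": len(truth),
            "n_skipped_short": simres.n_skipped_short,
        }
        if config.write_outputs:
            write_fasta(os.path.join(out, "reference.fa"), chrom, reference)
            srt = sorted(records, key=lambda r: r.pos)
            write_sam(srt, os.path.join(out, "simulated.sam"), chrom,
                      len(reference), coordinate_sorted=True)
            write_truth(truth, os.path.join(out, "truth.tsv"))
            write_bed(os.path.join(out, "target.bed"), chrom, 0, len(reference))
            if config.write_raw_fastq:
                from .sim import write_fastq
                write_fastq(records, os.path.join(out, "raw"))
    elif config.mode == "real-bam":
        if not config.input_bam:
            raise PipelineError("consensus", "real-bam mode requires input_bam")
        if not config.reference_fasta:
            raise PipelineError("counts", "real-bam mode requires reference_fasta")
        records = records_from_sam(config.input_bam)
        with pysam.FastaFile(config.reference_fasta) as fa:
            chrom = fa.references[0]
            reference = fa.fetch(chrom)
        targets = read_bed(config.target_bed) if config.target_bed \
            else [(chrom, 0, len(reference))]
        manifest["stages"]["load"] = {"n_records": len(records)}
    else:
        raise PipelineError("config", f"unknown mode {config.mode!r}")

    # --- stage: pair filtering --------------------------------------------
    kept, fstats = prepare_pairs(records, config.pair_filter)
    manifest["stages"]["pair_filter"] = fstats.as_dict()
    log.info("pair filter: %s", fstats.as_dict())

    # --- stage: UMI correction --------------------------------------------
    cstats = correct_umis(kept, config.umi)
    manifest["stages"]["umi_correction"] = vars(cstats)

    # --- stage: consensus --------------------------------------------------
    families, rejects = group_families(kept)
    sscs = call_all_sscs(families, config.consensus)
    dcs, pairing = call_all_dcs(sscs)
    recovery = compute_recovery(len(sscs), len(dcs))
    hist = family_size_histogram(families)
    manifest["stages"]["consensus"] = {
        "n_families": len(families),
        "n_rejected_records": len(rejects),
        "n_sscs": len(sscs),
        "n_dcs": len(dcs),
        "n_unpaired_sscs": len(pairing.unpaired),
        "recovery": None if recovery.undefined else recovery.recovery,
    }
    if config.write_outputs:
        write_consensus_fastq(sscs, os.path.join(out, "sscs.fastq"))
        write_consensus_fastq(dcs, os.path.join(out, "dcs.fastq"))
        with open(os.path.join(out, "family_sizes.tsv"), "w") as fh:
            fh.write("family_size\tn_families\n")
            for k, v in hist.items():
                fh.write(f"{k}\t{v}\n")
        with open(os.path.join(out, "recovery.tsv"), "w") as fh:
            fh.write("n_sscs\tn_dcs\trecovery\n")
            fh.write(f"{recovery.n_sscs}\t{recovery.n_dcs}\t{recovery.recovery}\n")

    # --- stage: base counts & incidence ------------------------------------
    region = (targets[0][1], targets[0][2])
    tables = {
        "filtered": build_base_counts(kept, reference, "filtered",
                                      config.pileup, chrom, region),
        "SSCS": build_base_counts(sscs, reference, "SSCS",
                                  config.pileup, chrom, region),
        "DCS": build_base_counts(dcs, reference, "DCS",
                                 config.pileup, chrom, region),
    }
    excluded = set(config.excluded_positions)
    excluded.update(sv.position for sv in config.sim.spike_variants)
    incidence = {lvl: variant_incidence(t, sorted(excluded))
                 for lvl, t in tables.items()}
    manifest["stages"]["counts"] = {
        lvl: {"total_bases": rep.total_bases, "variant_bases": rep.variant_bases,
              "incidence": None if rep.undefined else rep.incidence}
        for lvl, rep in incidence.items()}
    if config.write_outputs:
        for lvl, t in tables.items():
            t.write_tsv(os.path.join(out, f"counts_{lvl.lower()}.tsv"))
        with open(os.path.join(out, "incidence.tsv"), "w") as fh:
            fh.write("level\tvariant_bases\ttotal_bases\tincidence\n")
            for lvl, rep in incidence.items():
                fh.write(f"{lvl}\t{rep.variant_bases}\t{rep.total_bases}\t"
                         f"{rep.incidence}\n")

    # --- stage: coverage QC -------------------------------------------------
    cov = bin_coverage(kept, targets, config.coverage, {chrom: reference})
    manifest["stages"]["coverage_qc"] = {
        "n_bins": len(cov), "reads_assigned": int(cov["raw"].sum())}
    if config.write_outputs:
        cov.to_csv(os.path.join(out, "coverage_bins.tsv"), sep="\t", index=False)
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(config, reference, tables, incidence, recovery,
                          cov, manifest, sscs, dcs, truth)
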