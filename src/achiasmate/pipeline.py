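"""End-to-end orchestration of the synthetic study pipeline.

Runs, from a single seed: tetrad simulation and category fractions;
parameter re-fitting of (Pa, Pb) from the simulated ascus fractions; a
viable-spore cohort; synthetic spore resequencing and karyotype calling;
a mitotic-passage stability experiment; and cohort aneuploidy statistics.
Every stage derives its random stream from the top-level seed, the
configuration is serialized next to the outputs, and a manifest records a
content hash of every artifact so a run is fully re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aneuploidy_stats as stats_mod
from . import io as io_mod
from .genome import ChromosomeTable, mini_table
from .meiosis_model import (
    LossParams,
    compute_bias,
    fit_pa,
    fit_pb,
    sample_viable_spores,
    simulate,
)
from .ploidy_caller import (
    CODE_TO_STATE,
    CallerConfig,
    call_karyotype,
    classify_stability,
    recombination_per_chromosome,
)
from .synthetic_wgs import (
    GroundTruth,
    generate_snp_table,
    simulate_passage,
    simulate_reads,
)

logger = logging.getLogger("achiasmate")

__all__ = ["RunConfig", "run_end_to_end"]


@dataclass
class RunConfig:
    """Configuration of a demonstration run (all stages)."""

    seed: int = 1
    out_dir: str = "demo_out"
    chrom_table_path: str | None = None  # default: built-in miniature genome
    pa: float = 0.017
    pb: float = 0.013
    x_min: float = 0.5
    x_max: float = 0.5
    mode: str = "disjunction"
    n_tetrads: int = 200_000
    n_spores: int = 60
    snp_density: float = 0.007
    mean_depth_per_copy: float = 30.0
    error_rate: float = 0.002
    bin_size: int = 1000
    fit_grid_step: float = 0.001
    fit_n_per_point: int = 200_000
    passage_loss_rate: float = 0.15
    passage_gain_rate: float = 0.01
    caller: CallerConfig = field(default_factory=CallerConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full synthetic pipeline; returns the report dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = (
        ChromosomeTable.from_tsv(config.chrom_table_path)
        if config.chrom_table_path
        else mini_table()
    )
    seeds = np.random.SeedSequence(config.seed).spawn(8)
    streams = [np.random.default_rng(s) for s in seeds]
    bias = compute_bias(table, config.x_min, config.x_max, config.mode)
    loss = LossParams(pa=config.pa, pb=config.pb)

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")

    # 1. Tetrad simulation (conditional on a full MI daughter).
    logger.info("simulating %d conditional tetrads", config.n_tetrads)
    summary = simulate(
        config.n_tetrads, bias, loss, seed=streams[0], conditional=True
    )
    summary.to_json(out / "simulation_summary.json")

    # 2. Re-fit Pb and Pa from the simulated ascus fractions.
    logger.info("re-fitting Pb and Pa from simulated fractions")
    pb_grid = np.arange(0.0, 0.030 + 1e-12, config.fit_grid_step)
    fit_b = fit_pb(
        summary.identity_fraction, bias, pb_grid,
        n_per_point=config.fit_n_per_point,
        seed=int(streams[1].integers(2**31)),
    )
    pa_grid = np.arange(0.0, 0.040 + 1e-12, config.fit_grid_step)
    fit_a = fit_pa(
        fit_b.value, summary.pair_fraction, bias, pa_grid,
        n_per_point=config.fit_n_per_point,
        seed=int(streams[2].integers(2**31)),
    )

    # 3. Viable-spore cohort and synthetic resequencing.
    logger.info("sequencing %d synthetic viable spores", config.n_spores)
    cohort = sample_viable_spores(config.n_spores, bias, loss, seed=streams[3])
    io_mod.write_karyotypes_tsv(cohort, table, out / "true_karyotypes.tsv")
    snps = generate_snp_table(
        table, config.snp_density, seed=int(streams[4].integers(2**31))
    )
    call_frames = []
    profiles = {}
    rng_reads = streams[5]
    for i, states in enumerate(cohort):
        truth = GroundTruth(states=states)
        profile = simulate_reads(
            truth, snps, table,
            mean_depth_per_copy=config.mean_depth_per_copy,
            error_rate=config.error_rate,
            bin_size=config.bin_size,
            seed=int(rng_reads.integers(2**31)),
        )
        profiles[i] = profile
        calls = call_karyotype(profile, config.caller)
        calls.insert(0, "sample", f"spore{i + 1}")
        call_frames.append(calls)
    all_calls = pd.concat(call_frames, ignore_index=True)
    all_calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    truth_states = [CODE_TO_STATE[int(s)] for s in cohort.ravel()]
    call_accuracy = float(np.mean(all_calls["state"].to_numpy() == truth_states))

    # 4. Mitotic-passage stability on a subcohort.
    n_passage = min(20, config.n_spores)
    logger.info("passaging %d clones", n_passage)
    stab_frames = []
    rng_pass = streams[6]
    for i in range(n_passage):
        g0_truth = GroundTruth(states=cohort[i])
        g110_truth = simulate_passage(
            g0_truth, table,
            loss_rate=config.passage_loss_rate,
            gain_rate=config.passage_gain_rate,
            seed=int(rng_pass.integers(2**31)),
        )
        g110_profile = simulate_reads(
            g110_truth, snps, table,
            mean_depth_per_copy=config.mean_depth_per_copy,
            error_rate=config.error_rate,
            bin_size=config.bin_size,
            seed=int(rng_pass.integers(2**31)),
        )
        g0_calls = all_calls[all_calls["sample"] == f"spore{i + 1}"]
        stab = classify_stability(profiles[i], g0_calls, g110_profile)
        stab.insert(0, "sample", f"spore{i + 1}")
        stab_frames.append(stab)
    stability = pd.concat(stab_frames, ignore_index=True)
    stability.to_csv(out / "stability.tsv", sep="\t", index=False)

    # 5. Recombination scan (the achiasmate model has no recombination).
    recomb = []
    for i in range(min(10, config.n_spores)):
        g0_calls = all_calls[all_calls["sample"] == f"spore{i + 1}"]
        with warnings.catch_warnings():
            # disomic chromosomes are skipped there by design
            warnings.simplefilter("ignore", UserWarning)
            rec = recombination_per_chromosome(
                profiles[i].allele_depths, g0_calls
            )
        rec.insert(0, "sample", f"spore{i + 1}")
        recomb.append(rec)
    recomb_df = pd.concat(recomb, ignore_index=True)
    recomb_df.to_csv(out / "recombination.tsv", sep="\t", index=False)

    # 6. Cohort statistics.  Per-Mbp normalization uses real chromosome
    # lengths: the miniature genome is a scaled stand-in for read-level
    # stages only, and would inflate counts/Mbp by the scale factor.
    from .genome import default_table

    stats_table = table if config.chrom_table_path else default_table()
    counts = stats_mod.count_aneuploidies(cohort, stats_table)
    counts.to_frame().to_csv(out / "aneuploidy_counts.tsv", sep="\t", index=False)
    band = stats_mod.band_subset(counts)
    corr = None
    if len(band) >= 3:
        try:
            corr = stats_mod.length_correlation(counts, band)
        except ValueError:  # degenerate counts in a tiny cohort
            corr = None
    dsgs = stats_mod.make_synthetic_dsg_table(
        stats_table, seed=int(streams[7].integers(2**31))
    )
    impact = stats_mod.dsg_impact(dsgs, stats_table)
    try:
        log_r, log_n = stats_mod.log_association(counts, impact)
    except ValueError:
        log_r, log_n = float("nan"), 0
    bias_df = stats_mod.parental_bias(cohort, stats_table)
    bias_df.to_csv(out / "parental_bias.tsv", sep="\t", index=False)

    report = {
        "seed": config.seed,
        "category_fractions": summary.category_fractions(),
        "identity_fraction": summary.identity_fraction,
        "pair_fraction": summary.pair_fraction,
        "fitted_pb": fit_b.value,
        "fitted_pa": fit_a.value,
        "generating_pb": config.pb,
        "generating_pa": config.pa,
        "call_accuracy": call_accuracy,
        "n_stability_loss": int((stability["verdict"] == "loss").sum()),
        "n_stability_gain": int((stability["verdict"] == "gain").sum()),
        "total_crossovers": int(recomb_df["crossovers"].sum()),
        "total_gene_conversions": int(recomb_df["gene_conversions"].sum()),
        "band_subset": band,
        "length_correlation_r": corr.r_subset if corr else float("nan"),
        "length_correlation_r_all": corr.r_all if corr else float("nan"),
        "dsg_log_association_r": log_r,
        "dsg_log_association_n": log_n,
        "overall_parent_A_fraction": float(
            bias_df.loc[bias_df["chrom"] == "overall", "frac_A"].iloc[0]
        ),
        "outputs": {},
    }
    def _null_nan(obj):
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        if isinstance(obj, dict):
            return {k: _null_nan(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [_null_nan(v) for v in obj]
        return obj

    report = _null_nan(report)
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    manifest = {
        p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report["outputs"] = manifest
    return report
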