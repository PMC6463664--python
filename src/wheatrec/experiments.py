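"""End-to-end experiment drivers over the simulator and both callers.

These functions define the study conditions used throughout the analysis
scripts and the acceptance checks: an F8 single-seed-descent population on
three 600-Mbp chromosomes, observed through the array panel and through
skim sequencing at ~6.4x coverage, with every call evaluated against the
planted truth ledger.
"""

from __future__ import annotations

import numpy as np

from .array_caller import CallerConfig, call_line
from .skim_caller import (
    SkimConfig,
    build_parental_snps,
    classify_event_lengths,
    classify_line_positions,
    segment_marker_track,
)
from .io_formats import UNDETERMINED
from .synthetic_data import (
    SimConfig,
    emit_array_genotypes,
    emit_parental_variants,
    emit_skim_observations,
    evaluate_calls_against_truth,
    sample_array_markers,
    sample_discrimination_sites,
    simulate_ssd_population,
)


def run_array_recovery(
    config: SimConfig, rng=None, truth=None, caller_config: CallerConfig | None = None
) -> dict:
    """Simulate (unless given), call array COs/GCs for every line and compare
    the called CO counts with the planted post-SSD breakpoint counts."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if truth is None:
        truth = simulate_ssd_population(config, rng)
    markers = sample_array_markers(config, rng)
    gm = emit_array_genotypes(truth, markers, config, rng)
    layout = config.layout
    results = [call_line(gm, lt.line, layout, caller_config) for lt in truth.lines]
    called = np.array([r["co_count"] for r in results], dtype=float)
    planted = np.array([lt.co_count for lt in truth.lines], dtype=float)
    events_by_line = {r["line"]: r["events"] for r in results}
    co_eval = evaluate_calls_against_truth(events_by_line, truth, kind="CO")
    return {
        "truth": truth,
        "genotypes": gm,
        "per_line": results,
        "events_by_line": events_by_line,
        "planted_mean_co": float(planted.mean()),
        "called_mean_co": float(called.mean()),
        "relative_error": float(abs(called.mean() - planted.mean()) / planted.mean()),
        "mae_per_line": float(np.abs(called - planted).mean()),
        "co_eval": co_eval,
        "mean_het_fraction": float(np.mean([lt.het_fraction for lt in truth.lines])),
    }


def run_skim_recovery(
    config: SimConfig, rng=None, truth=None, skim_config: SkimConfig | None = None
) -> dict:
    """Simulate (unless given), build the discrimination SNP set, emit skim
    observations line by line, call GC tracts and evaluate against truth."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    skim_config = skim_config or SkimConfig()
    if truth is None:
        truth = simulate_ssd_population(config, rng)
    sites = sample_discrimination_sites(config, rng)
    parental = emit_parental_variants(sites, config, rng)
    snps = build_parental_snps(parental, skim_config)
    events_by_line = {}
    informative = {}
    for lt in truth.lines:
        vt, coverage = emit_skim_observations(lt, snps.df, config, rng)
        track = classify_line_positions(vt, coverage, snps, skim_config, line=lt.line)
        events = classify_event_lengths(segment_marker_track(track, skim_config), skim_config)
        events_by_line[lt.line] = events
        informative[lt.line] = track.n_informative()
        # fill per-tract classified-marker counts while the track is in memory
        for t in lt.tracts:
            p = track.positions.get(t.chrom)
            if p is None:
                t.n_markers = 0
                continue
            lo = int(np.searchsorted(p, t.start, side="left"))
            hi = int(np.searchsorted(p, t.end, side="right"))
            t.n_markers = int((track.labels[t.chrom][lo:hi] != UNDETERMINED).sum())
    gc_eval = evaluate_calls_against_truth(events_by_line, truth, kind="GC")
    return {
        "truth": truth,
        "snps": snps,
        "n_sites": len(snps),
        "events_by_line": events_by_line,
        "informative_sites": informative,
        "gc_eval": gc_eval,
    }


def run_parameter_recovery(seed: int, n_lines: int = 100) -> dict:
    """The full parameter-recovery experiment at the default study
    conditions: one population, array and skim observation layers sharing
    the same planted truth."""
    config = SimConfig(seed=seed, n_lines=n_lines)
    rng = np.random.default_rng(seed)
    truth = simulate_ssd_population(config, rng)
    arr = run_array_recovery(config, rng=rng, truth=truth)
    skim = run_skim_recovery(config, rng=rng, truth=truth)
    return {"config": config, "truth": truth, "array": arr, "skim": skim}
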