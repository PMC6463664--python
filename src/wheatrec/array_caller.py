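"""Window-collapsed crossover calling and per-marker shift counting.

The array pipeline bins genotyping-array SNP calls into fixed windows
(default 20 Mbp, derived from genome size over map length times the shared
haplotype factor), assigns each window the majority parental allele, and
records a crossover (CO) at each change of the predominant parent between
consecutive informative windows. Gene conversions (GCs) are estimated without
windows: every change of the encountered parent-specific allele from one SNP
to the next is a shift, and GC = shifts - COs.

The TILLING variant applies the same machinery to EMS-induced mutations:
records are filtered to EMS-type substitutions with mapping-quality, depth
and allele-fraction thresholds, classified homozygous/heterozygous, and COs
are called on homozygous<->heterozygous window transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io_formats import (
    HET,
    KIND_CO,
    MISSING,
    PARENT_A,
    PARENT_B,
    GenomeLayout,
    GenotypeMatrix,
    RecombinationEvent,
    VariantTable,
)

logger = logging.getLogger(__name__)

EMS_SUBSTITUTIONS = frozenset({("G", "A"), ("C", "T")})


def derive_window_size(
    genome_bp: float = 16e9,
    map_cm: float = 3894.0,
    haplotype_factor: float = 5.0,
    round_to: int = 10_000_000,
) -> int:
    """Window size = genome size / map length x shared-haplotype factor,
    rounded to the nearest ``round_to`` (default 10 Mbp). The wheat defaults
    give 16e9 / 3894 * 5 = 20.5 Mbp -> 20 Mbp."""
    raw = genome_bp / map_cm * haplotype_factor
    return int(round(raw / round_to) * round_to)


@dataclass
class CallerConfig:
    window: int = 20_000_000
    tilling_norm_target: int = 5000
    tilling_min_mq: float = 50.0
    tilling_hom_fraction: float = 0.85  # strict > for homozygous-mutant
    tilling_min_alt_depth: int = 4
    ems_substitutions: frozenset = field(default_factory=lambda: EMS_SUBSTITUTIONS)

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window size must be positive")
        if not (0 < self.tilling_hom_fraction < 1):
            raise ValueError("homozygous fraction threshold must lie in (0, 1)")


@dataclass
class WindowStateTrack:
    """Per-window majority states for one line; window k covers
    [k*W+1, (k+1)*W] in 1-based coordinates."""

    line: str
    window: int
    states: dict[str, np.ndarray]  # chrom -> int8 array of window states

    def n_windows(self, chrom: str) -> int:
        return len(self.states[chrom])


def _window_majority(a: int, b: int, h: int) -> int:
    """Majority rule for one window: strict parent majority, ties or
    HET-dominated windows are HET, uninformative windows MISSING."""
    if a + b + h == 0:
        return MISSING
    if h > a + b:
        return HET
    if a > b:
        return PARENT_A
    if b > a:
        return PARENT_B
    return HET  # a == b with at least one informative call


def bin_markers(
    genotypes: GenotypeMatrix,
    line: str,
    layout: GenomeLayout,
    config: CallerConfig | None = None,
) -> WindowStateTrack:
    """Collapse a line's marker calls into per-window majority states."""
    config = config or CallerConfig()
    W = config.window
    calls = genotypes.line_calls(line)
    chroms = genotypes.markers["chrom"].to_numpy()
    pos = genotypes.markers["pos"].to_numpy()
    states: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        n_win = max(1, int(np.ceil(layout.lengths[chrom] / W)))
        mask = chroms == chrom
        widx = (pos[mask] - 1) // W
        c = calls[mask]
        counts = np.zeros((n_win, 3), dtype=np.int64)  # A, B, H per window
        for state, col in ((PARENT_A, 0), (PARENT_B, 1), (HET, 2)):
            np.add.at(counts[:, col], widx[c == state], 1)
        states[chrom] = np.array(
            [_window_majority(*counts[k]) for k in range(n_win)], dtype=np.int8
        )
    return WindowStateTrack(line=line, window=W, states=states)


def call_window_events(
    track: WindowStateTrack,
    mode: Literal["parental", "zygosity"] = "parental",
) -> list[RecombinationEvent]:
    """Record one CO per qualifying state change between consecutive
    informative windows.

    MISSING windows are skipped entirely. In ``parental`` mode, HET windows
    are also transparent: an A->HET->B traversal emits exactly one CO (at
    the first B window) and A->HET->A emits none. In ``zygosity`` mode
    (TILLING), transitions between homozygous (A/B) and HET windows count.
    Each CO is positioned at the start coordinate of the later window.
    """
    events: list[RecombinationEvent] = []
    W = track.window
    for chrom, states in track.states.items():
        idx = np.nonzero(states != MISSING)[0]
        st = states[idx]
        if mode == "parental":
            keep = st != HET
            idx, st = idx[keep], st[keep]
        elif mode == "zygosity":
            st = np.where(st == HET, HET, PARENT_A)  # collapse A/B -> HOM
        else:
            raise ValueError(f"unknown mode: {mode}")
        if len(idx) < 2:
            continue
        change = np.nonzero(st[1:] != st[:-1])[0] + 1
        for j in change:
            w = int(idx[j])
            pos = w * W + 1  # start of the later window, 1-based
            events.append(
                RecombinationEvent(
                    line=track.line, chrom=chrom, start=pos, end=pos,
                    donor=int(st[j]), kind=KIND_CO, support=1,
                )
            )
    return events


def count_marker_shifts(genotypes: GenotypeMatrix, line: str) -> dict[str, int]:
    """Per-chromosome count of adjacent parent-allele changes along the
    marker order, after dropping HET and MISSING calls. No transition is
    counted across a chromosome boundary."""
    calls = genotypes.line_calls(line)
    chroms = genotypes.markers["chrom"].to_numpy()
    out: dict[str, int] = {}
    for chrom in pd.unique(chroms):
        c = calls[chroms == chrom]
        c = c[(c == PARENT_A) | (c == PARENT_B)]
        out[str(chrom)] = int(np.count_nonzero(c[1:] != c[:-1]))
    return out


def derive_gc_count(total_shifts: int, co_count: int) -> int:
    """GC estimate = shifts - COs, clamped at zero (a CO spanning a marker
    desert can make the raw difference negative; the clamp is logged)."""
    if total_shifts < 0 or co_count < 0:
        raise ValueError("counts must be non-negative")
    raw = total_shifts - co_count
    if raw < 0:
        logger.warning(
            "shift count %d below CO count %d; clamping GC estimate to 0",
            total_shifts, co_count,
        )
        return 0
    return raw


def filter_tilling_snps(
    variants: VariantTable,
    config: CallerConfig | None = None,
    chromosomes: tuple[str, ...] | None = None,
    line: str = "line",
) -> GenotypeMatrix:
    """Filter exome-capture SNPs of an EMS line to high-confidence mutation
    markers and classify zygosity.

    Retained records are EMS-type substitutions (G>A or C>T as recorded on
    the reference strand), mapping quality >= 50, alternate-allele depth
    >= 4, and on a named chromosome. State is homozygous-mutant (coded
    PARENT_A) when the alternate fraction exceeds 0.85, else HET. Records
    without mapping quality are dropped and counted.
    """
    config = config or CallerConfig()
    df = variants.df
    frac = variants.alt_fraction
    no_mq = df["mq"].isna().to_numpy()
    if no_mq.any():
        logger.info("dropped %d records without mapping quality", int(no_mq.sum()))
    is_ems = np.array(
        [(r, a) in config.ems_substitutions for r, a in zip(df["ref"], df["alt"])]
    )
    keep = (
        is_ems
        & ~no_mq
        & (df["mq"].to_numpy(dtype=float) >= config.tilling_min_mq)
        & (df["alt_depth"].to_numpy() >= config.tilling_min_alt_depth)
    )
    if chromosomes is not None:
        keep &= df["chrom"].isin(chromosomes).to_numpy()
    sub = df[keep]
    hom = frac[keep] > config.tilling_hom_fraction
    markers = pd.DataFrame(
        {
            "chrom": sub["chrom"].astype(str).to_numpy(),
            "pos": sub["pos"].to_numpy(),
            "marker_id": [f"ems_{c}_{p}" for c, p in zip(sub["chrom"], sub["pos"])],
        }
    )
    calls = np.where(hom, PARENT_A, HET).astype(np.int8)[:, None]
    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].to_numpy()))
    return GenotypeMatrix(
        markers=markers.iloc[order].reset_index(drop=True),
        lines=[line],
        calls=calls[order],
    )


def normalize_tilling_gc(
    gc_count: int, n_snps: int, config: CallerConfig | None = None
) -> float:
    """Scale a line's GC count to the configured SNP-count target (default
    5000), compensating for uneven marker availability across EMS lines."""
    config = config or CallerConfig()
    if n_snps <= 0:
        raise ValueError("SNP count must be positive for normalization")
    return gc_count * config.tilling_norm_target / n_snps


def array_gc_candidates(genotypes: GenotypeMatrix, line: str) -> list[RecombinationEvent]:
    """Marker-level GC candidates for cross-platform validation.

    After dropping HET/MISSING calls, every maximal single-parent marker run
    flanked on both sides by the other parent is an island; each island is
    returned as a GC candidate whose defining SNP is its first marker.
    """
    calls = genotypes.line_calls(line)
    chroms = genotypes.markers["chrom"].to_numpy()
    pos = genotypes.markers["pos"].to_numpy()
    out: list[RecombinationEvent] = []
    for chrom in pd.unique(chroms):
        m = chroms == chrom
        c, p = calls[m], pos[m]
        keep = (c == PARENT_A) | (c == PARENT_B)
        c, p = c[keep], p[keep]
        if len(c) < 3:
            continue
        change = np.flatnonzero(c[1:] != c[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(c)]))
        for r in range(1, len(starts) - 1):  # internal runs only
            i, j = starts[r], ends[r] - 1
            out.append(
                RecombinationEvent(
                    line=line, chrom=str(chrom), start=int(p[i]), end=int(p[j]),
                    donor=int(c[i]), kind="GC", support=int(j - i + 1),
                    snp_pos=int(p[i]),
                )
            )
    return out


def call_line(
    genotypes: GenotypeMatrix,
    line: str,
    layout: GenomeLayout,
    config: CallerConfig | None = None,
    mode: Literal["parental", "zygosity"] = "parental",
) -> dict:
    """Full array pipeline for one line: window CO calls, shift counts and
    the derived GC estimate. Returns a summary dict plus the event list."""
    config = config or CallerConfig()
    track = bin_markers(genotypes, line, layout, config)
    cos = call_window_events(track, mode=mode)
    shifts = count_marker_shifts(genotypes, line)
    total_shifts = int(sum(shifts.values()))
    gc = derive_gc_count(total_shifts, len(cos))
    return {
        "line": line,
        "events": cos,
        "co_count": len(cos),
        "shift_count": total_shifts,
        "gc_count": gc,
        "shifts_by_chrom": shifts,
    }
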