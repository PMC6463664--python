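"""Single-seed-descent (SSD) population simulator with planted ground truth.

A recombinant inbred line is simulated as an F1 heterozygote selfed for
``generations - 1`` rounds, keeping one offspring per round. Each meiosis
draws a crossover count per chromosome (Poisson, conditioned >= 1 when the
obligate-CO flag is on) with distally biased positions, and stamps gene
conversion (GC) tracts — short non-reciprocal donor switches copied from the
homologous chromosome — with a configurable rate and length mixture.
Haplotypes are piecewise-constant mosaics over the two founder genomes.

Two observation layers emulate the real assays: an array emitter reads
genotype states off the final mosaic at a fixed marker panel, and a skim
emitter draws Poisson read depths and noisy allele counts at discrimination
SNP sites spaced ~540 bp apart. A shadow lineage without GC tracts is run
with the same crossover draws, so planted post-SSD CO breakpoints are
recorded independently of tract edges.

Calibration (see docs/methods.md): the conditioned mean CO per chromosome
per gamete is 1.1, chosen so that, with the ~2x junction-density expansion
of selfed RILs at fixation, a line shows ~2.2 surviving breakpoints per
chromosome — the per-chromosome rate implied by 40.8-51.9 COs per line over
21 wheat chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    HET,
    KIND_GC,
    MISSING,
    PARENT_A,
    PARENT_B,
    UNDETERMINED,
    GenomeLayout,
    GenotypeMatrix,
    RecombinationEvent,
    VariantTable,
)

Mosaic = tuple[np.ndarray, np.ndarray]  # (segment end positions, states)


# ---------------------------------------------------------------------------
# Mosaic arithmetic. A mosaic covers positions 1..L; segment i spans
# (ends[i-1], ends[i]] in 1-based inclusive coordinates.


def constant_mosaic(length: int, state: int) -> Mosaic:
    return np.array([length], dtype=np.int64), np.array([state], dtype=np.int8)


def simplify(m: Mosaic) -> Mosaic:
    ends, states = m
    if len(ends) <= 1:
        return m
    keep = np.concatenate((states[1:] != states[:-1], [True]))
    return ends[keep], states[keep]


def state_at(m: Mosaic, pos: np.ndarray | int) -> np.ndarray | int:
    ends, states = m
    idx = np.searchsorted(ends, pos, side="left")
    return states[idx]


def _slice(m: Mosaic, lo: int, hi: int) -> Mosaic:
    """Sub-mosaic covering (lo, hi]."""
    ends, states = m
    i0 = int(np.searchsorted(ends, lo + 1, side="left"))
    i1 = int(np.searchsorted(ends, hi, side="left"))
    new_ends = ends[i0 : i1 + 1].copy()
    new_ends[-1] = hi
    return new_ends, states[i0 : i1 + 1].copy()


def splice(target: Mosaic, source: Mosaic, start: int, end: int, length: int) -> Mosaic:
    """Replace target states over [start, end] with the source's."""
    parts = []
    if start > 1:
        parts.append(_slice(target, 0, start - 1))
    parts.append(_slice(source, start - 1, end))
    if end < length:
        parts.append(_slice(target, end, length))
    ends = np.concatenate([p[0] for p in parts])
    states = np.concatenate([p[1] for p in parts])
    return simplify((ends, states))


def recombine(h0: Mosaic, h1: Mosaic, co_positions: Sequence[int],
              start_hap: int, length: int) -> Mosaic:
    """Gamete mosaic: alternate between homologs, switching after each CO
    position (the breakpoint lies between x and x+1)."""
    haps = (h0, h1)
    cur = start_hap
    lo = 0
    parts = []
    for x in sorted(co_positions):
        parts.append(_slice(haps[cur], lo, int(x)))
        lo = int(x)
        cur = 1 - cur
    parts.append(_slice(haps[cur], lo, length))
    ends = np.concatenate([p[0] for p in parts])
    states = np.concatenate([p[1] for p in parts])
    return simplify((ends, states))


def zygosity_mosaic(h0: Mosaic, h1: Mosaic) -> Mosaic:
    """Combine the two homologs into an A/B/HET mosaic."""
    ends = np.union1d(h0[0], h1[0])
    s0 = state_at(h0, ends)
    s1 = state_at(h1, ends)
    states = np.where(s0 == s1, s0, HET).astype(np.int8)
    return simplify((ends, states))


def het_fraction(zyg: Mosaic) -> float:
    ends, states = zyg
    starts = np.concatenate(([0], ends[:-1]))
    seg_len = ends - starts
    return float(seg_len[states == HET].sum() / ends[-1])


def surviving_co_positions(zyg: Mosaic) -> list[int]:
    """Breakpoints of the HET-removed state string: each A<->B change counts
    once, HET runs between same-parent segments count zero."""
    ends, states = zyg
    hom = states != HET
    e, s = ends[hom], states[hom]
    if len(s) < 2:
        return []
    change = np.flatnonzero(s[1:] != s[:-1])
    return [int(e[i]) for i in change]


# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study conditions for the desk-scale SSD simulation."""

    n_chroms: int = 3
    chrom_length: int = 600_000_000
    generations: int = 8          # F8: the F1 is selfed generations-1 times
    n_lines: int = 100
    mean_cos_per_chrom: float = 1.1   # conditioned mean per gamete per chromosome
    obligate_co: bool = True
    distal_bias: float = 0.6      # mixture weight of the telomere-proximal component
    distal_beta: tuple[float, float] = (1.5, 4.0)
    gc_tracts_per_chrom: float = 1.0  # mean per chromosome per meiosis
    gc_class_weights: tuple[float, ...] = (0.15, 0.20, 0.25, 0.40)
    gc_class_bounds: tuple[tuple[int, int], ...] = (
        (20, 2_000), (2_000, 10_000), (10_000, 500_000), (3_000_000, 15_000_000),
    )
    array_markers: int = 618      # ~206 per chromosome, matching 4335/21 per wheat chromosome
    array_missing_rate: float = 0.0
    skim_spacing: float = 540.0   # mean discrimination-SNP spacing, bp
    coverage_mean: float = 6.42
    parental_coverage_mean: float = 20.0
    label_noise: float = 0.001    # per-read probability of reporting the wrong parent
    seed: int = 0

    def __post_init__(self):
        for r in (self.mean_cos_per_chrom, self.gc_tracts_per_chrom,
                  self.skim_spacing, self.coverage_mean):
            if r < 0:
                raise ValueError("rates must be non-negative")
        if abs(sum(self.gc_class_weights) - 1.0) > 1e-9:
            raise ValueError("GC class weights must sum to 1")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout.uniform(self.n_chroms, self.chrom_length)

    @property
    def poisson_rate(self) -> float:
        """Raw Poisson rate whose >=1-truncated mean equals mean_cos_per_chrom."""
        m = self.mean_cos_per_chrom
        if not self.obligate_co:
            return m
        if m <= 1.0:
            raise ValueError("conditioned mean must exceed 1 with obligate CO")
        return brentq(lambda lam: lam / (1 - math.exp(-lam)) - m, 1e-9, 50.0)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("distal_beta",):
            if key in data:
                data[key] = tuple(data[key])
        if "gc_class_weights" in data:
            data["gc_class_weights"] = tuple(data["gc_class_weights"])
        if "gc_class_bounds" in data:
            data["gc_class_bounds"] = tuple(tuple(b) for b in data["gc_class_bounds"])
        return cls(**data)


@dataclass
class Tract:
    """A planted gene-conversion tract."""

    generation: int
    chrom: str
    start: int
    end: int
    donor: int
    detectable: bool = False   # survives as a homozygous donor island at F_n
    n_markers: int = -1        # classified skim markers inside (filled later)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class LineTruth:
    """Ground-truth ledger for one simulated line."""

    line: str
    final: dict[str, Mosaic]          # A/B/HET zygosity mosaic at F_n
    shadow: dict[str, Mosaic]         # same, from the tract-free shadow lineage
    planted_cos: list[tuple[int, str, int]]  # (generation, chrom, position)
    tracts: list[Tract]
    het_fraction: float = 0.0
    co_positions: list[tuple[str, int]] = field(default_factory=list)

    @property
    def co_count(self) -> int:
        return len(self.co_positions)


@dataclass
class SimTruth:
    config: SimConfig
    lines: list[LineTruth]

    def mean_co_count(self) -> float:
        return float(np.mean([t.co_count for t in self.lines]))


def _draw_co_positions(n: int, length: int, config: SimConfig, rng) -> list[int]:
    pos = set()
    while len(pos) < n:
        if rng.random() < config.distal_bias:
            u = rng.beta(*config.distal_beta)
            frac = u / 2 if rng.random() < 0.5 else 1 - u / 2
        else:
            frac = rng.random()
        x = int(frac * (length - 1)) + 1
        pos.add(min(x, length - 1))
    return sorted(pos)


def _draw_tracts(length: int, config: SimConfig, rng) -> list[tuple[int, int]]:
    n = rng.poisson(config.gc_tracts_per_chrom)
    out = []
    for _ in range(n):
        k = rng.choice(len(config.gc_class_weights), p=config.gc_class_weights)
        lo, hi = config.gc_class_bounds[k]
        span = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        span = max(1, min(span, length))
        start = int(rng.integers(1, length - span + 2))
        out.append((start, start + span - 1))
    return out


def simulate_meiosis(
    h0: Mosaic, h1: Mosaic, length: int, config: SimConfig, rng
) -> tuple[Mosaic, list[int], list[tuple[int, int, int]], tuple[list[int], int]]:
    """One meiotic product of a plant's homolog pair on one chromosome.

    Returns the gamete mosaic, CO positions, stamped tracts as
    (start, end, donor state), and the raw (co_positions, start_hap) draw so
    a shadow lineage can replay the same crossovers.
    """
    if config.obligate_co:
        lam = config.poisson_rate
        n_co = 0
        while n_co == 0:
            n_co = rng.poisson(lam)
    else:
        n_co = rng.poisson(config.mean_cos_per_chrom)
    cos = _draw_co_positions(n_co, length, config, rng) if n_co else []
    start_hap = int(rng.integers(0, 2))
    gamete = recombine(h0, h1, cos, start_hap, length)

    tracts: list[tuple[int, int, int]] = []
    haps = (h0, h1)
    for s, e in _draw_tracts(length, config, rng):
        # the gamete currently carries some source at the tract; copy from the
        # homolog opposite to the gamete's state at the tract midpoint
        mid = (s + e) // 2
        cur_state = int(state_at(gamete, mid))
        other = h1 if int(state_at(h0, mid)) == cur_state else h0
        donor = int(state_at(other, mid))
        if donor == cur_state:
            continue  # homologs agree locally; conversion changes nothing
        gamete = splice(gamete, other, s, e, length)
        tracts.append((s, e, donor))
    return gamete, cos, tracts, (cos, start_hap)


def simulate_ssd_population(config: SimConfig, rng=None) -> SimTruth:
    """Simulate ``n_lines`` F_n lines by single-seed descent.

    Each selfing round draws two independent meioses of the same plant.
    A shadow lineage without GC tracts replays the identical crossover
    draws, so that surviving post-SSD CO breakpoints are recorded free of
    tract edges.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    layout = config.layout
    lines = []
    for i in range(config.n_lines):
        name = f"RIL{i:03d}"
        plant = {
            c: (constant_mosaic(layout.lengths[c], PARENT_A),
                constant_mosaic(layout.lengths[c], PARENT_B))
            for c in layout.names
        }
        shadow = {c: plant[c] for c in layout.names}
        planted_cos: list[tuple[int, str, int]] = []
        tracts: list[Tract] = []
        for gen in range(1, config.generations):
            new_plant = {}
            new_shadow = {}
            for c in layout.names:
                L = layout.lengths[c]
                gametes = []
                shadow_gametes = []
                for _ in range(2):
                    g, cos, trs, (cos_raw, start_hap) = simulate_meiosis(
                        plant[c][0], plant[c][1], L, config, rng
                    )
                    gametes.append(g)
                    shadow_gametes.append(
                        recombine(shadow[c][0], shadow[c][1], cos_raw, start_hap, L)
                    )
                    planted_cos.extend((gen, c, p) for p in cos)
                    tracts.extend(Tract(gen, c, s, e, d) for s, e, d in trs)
                new_plant[c] = (gametes[0], gametes[1])
                new_shadow[c] = (shadow_gametes[0], shadow_gametes[1])
            plant = new_plant
            shadow = new_shadow
        final = {c: zygosity_mosaic(*plant[c]) for c in layout.names}
        shadow_final = {c: zygosity_mosaic(*shadow[c]) for c in layout.names}
        total = sum(layout.lengths.values())
        hf = sum(
            het_fraction(final[c]) * layout.lengths[c] for c in layout.names
        ) / total
        co_pos = [
            (c, p) for c in layout.names for p in surviving_co_positions(shadow_final[c])
        ]
        for t in tracts:
            t.detectable = _tract_is_island(final[t.chrom], t, layout.lengths[t.chrom])
        lines.append(
            LineTruth(
                line=name, final=final, shadow=shadow_final,
                planted_cos=planted_cos, tracts=tracts,
                het_fraction=hf, co_positions=co_pos,
            )
        )
    return SimTruth(config=config, lines=lines)


def _tract_is_island(zyg: Mosaic, t: Tract, length: int) -> bool:
    """A tract survives as detectable iff the final line is homozygous for
    the donor inside it and homozygous for the other parent on both flanks."""
    if t.start <= 1 or t.end >= length:
        return False
    mid = (t.start + t.end) // 2
    other = PARENT_B if t.donor == PARENT_A else PARENT_A
    return (
        int(state_at(zyg, mid)) == t.donor
        and int(state_at(zyg, t.start - 1)) == other
        and int(state_at(zyg, t.end + 1)) == other
    )


# ---------------------------------------------------------------------------
# Observation emitters.


def sample_array_markers(config: SimConfig, rng) -> pd.DataFrame:
    """Marker panel shared by all lines: positions uniform per chromosome,
    counts proportional to chromosome length."""
    layout = config.layout
    total = layout.genome_size
    rows = []
    for c in layout.names:
        n = int(round(config.array_markers * layout.lengths[c] / total))
        pos = np.sort(rng.choice(layout.lengths[c], size=n, replace=False) + 1)
        for p in pos:
            rows.append((c, int(p), f"AX_{c}_{int(p)}"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "marker_id"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def emit_array_genotypes(
    truth: SimTruth, markers: pd.DataFrame, config: SimConfig, rng
) -> GenotypeMatrix:
    """Read each line's call off its final zygosity mosaic at the marker
    panel; an optional missing-call rate blanks calls at random."""
    n_m, n_l = len(markers), len(truth.lines)
    calls = np.empty((n_m, n_l), dtype=np.int8)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    for j, lt in enumerate(truth.lines):
        col = np.empty(n_m, dtype=np.int8)
        for c in set(chroms):
            m = chroms == c
            col[m] = state_at(lt.final[c], pos[m])
        calls[:, j] = col
    if config.array_missing_rate > 0:
        mask = rng.random(calls.shape) < config.array_missing_rate
        calls[mask] = MISSING
    return GenotypeMatrix(
        markers=markers.copy(), lines=[lt.line for lt in truth.lines], calls=calls
    )


def sample_discrimination_sites(config: SimConfig, rng) -> pd.DataFrame:
    """Candidate parent-discriminating SNP sites with exponential spacing
    (mean ``skim_spacing``) and random ref (parent-B) / alt (parent-A)
    alleles."""
    layout = config.layout
    bases = np.array(list("ACGT"))
    parts = []
    for c in layout.names:
        L = layout.lengths[c]
        n_est = int(L / config.skim_spacing * 1.1) + 10
        gaps = rng.exponential(config.skim_spacing, size=n_est)
        pos = np.unique(np.cumsum(gaps).astype(np.int64) + 1)
        pos = pos[pos <= L]
        ref_i = rng.integers(0, 4, size=len(pos))
        alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
        parts.append(
            pd.DataFrame(
                {"chrom": c, "pos": pos, "ref": bases[ref_i], "alt": bases[alt_i]}
            )
        )
    return pd.concat(parts, ignore_index=True)


def emit_parental_variants(sites: pd.DataFrame, config: SimConfig, rng) -> VariantTable:
    """Variant calls of error-free parent-A reads against the parent-B
    reference: every site is a true SNP, depth ~ Poisson(parental coverage)."""
    depth = rng.poisson(config.parental_coverage_mean, size=len(sites))
    df = pd.DataFrame(
        {
            "chrom": sites["chrom"], "pos": sites["pos"],
            "ref": sites["ref"], "alt": sites["alt"],
            "qual": 100.0, "depth": depth, "alt_depth": depth,
            "mq": 60.0,
        }
    )
    return VariantTable(df.reset_index(drop=True))


def emit_skim_observations(
    line_truth: LineTruth, snp_sites: pd.DataFrame, config: SimConfig, rng
) -> tuple[VariantTable, pd.DataFrame]:
    """Skim-sequencing observations of one line over the discrimination sites.

    Per site: depth ~ Poisson(coverage mean); alternate-read count ~
    Binomial(depth, p) with p = 1 - noise at parent-A sites, noise at
    parent-B sites and 0.5 inside residual heterozygous regions. Sites with
    at least one alternate read yield a variant record (QUAL grows with the
    alternate depth); the coverage track reports depth at every site.
    """
    chroms = snp_sites["chrom"].to_numpy()
    pos = snp_sites["pos"].to_numpy()
    donor = np.empty(len(pos), dtype=np.int8)
    for c in set(chroms):
        m = chroms == c
        donor[m] = state_at(line_truth.final[c], pos[m])
    depth = rng.poisson(config.coverage_mean, size=len(pos))
    p_alt = np.where(
        donor == PARENT_A, 1.0 - config.label_noise,
        np.where(donor == PARENT_B, config.label_noise, 0.5),
    )
    alt = rng.binomial(depth, p_alt)
    has_alt = alt >= 1
    vdf = pd.DataFrame(
        {
            "chrom": chroms[has_alt],
            "pos": pos[has_alt],
            "ref": snp_sites["ref"].to_numpy()[has_alt],
            "alt": snp_sites["alt"].to_numpy()[has_alt],
            "qual": 30.0 + 10.0 * alt[has_alt],
            "depth": depth[has_alt],
            "alt_depth": alt[has_alt],
            "mq": 60.0,
        }
    )
    coverage = pd.DataFrame({"chrom": chroms, "pos": pos, "depth": depth})
    return VariantTable(vdf.reset_index(drop=True)), coverage


# ---------------------------------------------------------------------------
# Truth evaluation harness.


def evaluate_calls_against_truth(
    called_by_line: dict[str, list[RecombinationEvent]],
    truth: SimTruth,
    co_tolerance: int = 20_000_000,
    kind: str = "CO",
) -> dict:
    """Recall/precision of called events against the planted ledger.

    ``kind='CO'``: a truth breakpoint is recovered when a called CO of the
    same line and chromosome lies within ``co_tolerance``; precision is the
    fraction of called COs within tolerance of some truth breakpoint, and
    the median positional error is reported over recovered pairs.

    ``kind='GC'``: a planted tract is recoverable when it survived SSD as a
    homozygous donor island and holds >= 3 classified skim markers (set by
    the caller in ``Tract.n_markers``; sparser tracts are undetectable by
    the break rule and excluded from the recall denominator). It is
    recovered when a called GC overlaps it with the correct donor.

    Precision scores each call against the true donor mosaic: a call is
    correct when its interval lies inside a single segment of the line's
    final mosaic with the called donor state — planted tract islands and
    crossover-bounded donor blocks both qualify, noise-induced runs and
    runs straddling a true junction do not. Calls whose midpoint falls in
    a residual heterozygous region, where no donor truth exists (the
    homozygous-only skim logic cannot represent HET), are tallied
    separately and excluded from the primary precision denominator; an
    overall precision including them is also returned. Tract-level
    precision (fraction of defined-truth calls overlapping a planted tract
    with matching donor) is reported as ``tract_precision``.
    """
    by_line = {t.line: t for t in truth.lines}
    unknown = set(called_by_line) - set(by_line)
    if unknown:
        raise ValueError(f"calls reference unknown lines: {sorted(unknown)}")
    if kind == "CO":
        n_truth = n_recovered = n_calls = n_matched = 0
        errors = []
        for line, events in called_by_line.items():
            lt = by_line[line]
            calls = [(e.chrom, e.start) for e in events if e.kind == "CO"]
            n_calls += len(calls)
            for chrom, tpos in lt.co_positions:
                n_truth += 1
                best = min(
                    (abs(cpos - tpos) for c, cpos in calls if c == chrom),
                    default=None,
                )
                if best is not None and best <= co_tolerance:
                    n_recovered += 1
                    errors.append(best)
            for chrom, cpos in calls:
                best = min(
                    (abs(cpos - tpos) for c, tpos in lt.co_positions if c == chrom),
                    default=None,
                )
                if best is not None and best <= co_tolerance:
                    n_matched += 1
        return {
            "recall": n_recovered / n_truth if n_truth else float("nan"),
            "precision": n_matched / n_calls if n_calls else float("nan"),
            "median_error": float(np.median(errors)) if errors else float("nan"),
            "n_truth": n_truth,
            "n_calls": n_calls,
        }
    if kind != "GC":
        raise ValueError(f"unknown evaluation kind: {kind}")

    n_recoverable = n_recovered = 0
    n_defined_calls = n_true_calls = n_het_calls = n_tract_calls = 0
    for line, events in called_by_line.items():
        lt = by_line[line]
        calls = [e for e in events if e.kind == KIND_GC]
        recoverable = [
            t for t in lt.tracts if t.detectable and t.n_markers >= 3
        ]
        n_recoverable += len(recoverable)
        for t in recoverable:
            hit = any(
                e.chrom == t.chrom and e.start <= t.end and e.end >= t.start
                and e.donor == t.donor
                for e in calls
            )
            n_recovered += hit
        for e in calls:
            mid = (e.start + e.end) // 2
            ends, states = lt.final[e.chrom]
            if int(states[np.searchsorted(ends, mid)]) == HET:
                n_het_calls += 1
                continue
            n_defined_calls += 1
            i_s = int(np.searchsorted(ends, e.start))
            i_e = int(np.searchsorted(ends, e.end))
            n_true_calls += i_s == i_e and int(states[i_s]) == e.donor
            n_tract_calls += any(
                t.chrom == e.chrom and e.start <= t.end and e.end >= t.start
                and t.donor == e.donor
                for t in lt.tracts
            )
    n_calls = n_defined_calls + n_het_calls
    return {
        "recall": n_recovered / n_recoverable if n_recoverable else float("nan"),
        "precision": n_true_calls / n_defined_calls if n_defined_calls else float("nan"),
        "precision_overall": n_true_calls / n_calls if n_calls else float("nan"),
        "tract_precision": n_tract_calls / n_defined_calls if n_defined_calls else float("nan"),
        "n_recoverable": n_recoverable,
        "n_calls": n_calls,
        "n_het_region_calls": n_het_calls,
    }


def count_markers_in_tracts(truth: SimTruth, tracks: dict[str, "object"]) -> None:
    """Fill ``Tract.n_markers`` with the number of informative classified
    markers inside each tract, given per-line MarkerTracks."""
    for lt in truth.lines:
        track = tracks.get(lt.line)
        if track is None:
            continue
        for t in lt.tracts:
            p = track.positions.get(t.chrom)
            if p is None:
                t.n_markers = 0
                continue
            lo = int(np.searchsorted(p, t.start, side="left"))
            hi = int(np.searchsorted(p, t.end, side="right"))
            lab = track.labels[t.chrom][lo:hi]
            t.n_markers = int((lab != UNDETERMINED).sum())
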