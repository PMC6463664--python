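"""CO/GC calling from low-coverage (skim) whole-genome sequencing.

The skim pipeline works in three stages. First, a set of parental
discrimination SNPs is built from variant calls of one parent's reads
against the other parent's reference assembly, with allele-fraction,
quality, depth and local-density filters. Second, each sequenced line is
classified at every discrimination site as parent-A (alternate), parent-B
(reference-confirmed) or undetermined. Third, the ordered label string is
segmented into maximal single-parent runs; a change of parent is only
believed when three or more consecutive markers support it, shorter blips
are discarded as noise, and each internal run bounded by the other parent
on both sides becomes a candidate gene-conversion tract (megabase-scale
runs are flagged as crossover proxies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import (
    KIND_GC,
    KIND_SHIFT,
    LENGTH_CLASSES,
    PARENT_A,
    PARENT_B,
    UNDETERMINED,
    RecombinationEvent,
    VariantTable,
)

logger = logging.getLogger(__name__)


@dataclass
class SkimConfig:
    # Parental discrimination-SNP build.
    parental_min_alt_fraction: float = 0.80  # strict >
    parental_min_qual: float = 30.0
    parental_min_depth: int = 3
    density_window: int = 10      # bp, inclusive sliding span
    density_max_snps: int = 3     # >= this many in a span -> all removed
    # Per-line classification.
    line_min_qual: float = 20.0
    line_min_alt_fraction: float = 0.80  # strict >
    min_ref_coverage: int = 3
    # Segmentation and event classification.
    min_run: int = 3
    length_bounds: tuple[int, ...] = (20, 2_000, 10_000, 500_000)
    co_proxy_20mb: int = 20_000_000
    co_proxy_40mb: int = 40_000_000
    conservation_majority: float = 0.5
    readpair_min_cov: int = 3

    def __post_init__(self):
        if list(self.length_bounds) != sorted(self.length_bounds):
            raise ValueError("length class boundaries must be increasing")
        for f in (self.parental_min_alt_fraction, self.line_min_alt_fraction,
                  self.conservation_majority):
            if not (0 < f < 1):
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class ParentalSNPSet:
    """Positions where the two parents are reliably discriminated.

    ``df`` columns: chrom, pos (1-based), ref (parent-B allele), alt
    (parent-A allele); sorted by (chrom, pos), unique positions.
    """

    df: pd.DataFrame

    def __post_init__(self):
        if len(self.df):
            if self.df.duplicated(subset=["chrom", "pos"]).any():
                raise ValueError("parental SNP positions must be unique")
            if (self.df["ref"] == self.df["alt"]).any():
                raise ValueError("parental alleles must differ")

    def __len__(self) -> int:
        return len(self.df)

    def by_chrom(self):
        for chrom, sub in self.df.groupby("chrom", sort=True):
            yield str(chrom), sub.reset_index(drop=True)


@dataclass
class MarkerTrack:
    """Per-line classified labels over the parental SNP positions.

    ``positions``/``labels``: dict chrom -> aligned arrays; labels are
    PARENT_A, PARENT_B or UNDETERMINED.
    """

    line: str
    positions: dict[str, np.ndarray]
    labels: dict[str, np.ndarray]

    def n_sites(self) -> int:
        return sum(len(v) for v in self.positions.values())

    def n_informative(self) -> int:
        return sum(int((v != UNDETERMINED).sum()) for v in self.labels.values())

    def label_at(self, chrom: str, pos: int) -> int:
        """Label at the parental SNP nearest to ``pos`` (exact match if one
        exists at the position)."""
        p = self.positions.get(chrom)
        if p is None or len(p) == 0:
            return UNDETERMINED
        i = int(np.clip(np.searchsorted(p, pos), 0, len(p) - 1))
        if i > 0 and abs(int(p[i - 1]) - pos) < abs(int(p[i]) - pos):
            i -= 1
        return int(self.labels[chrom][i])


def _density_filter(pos: np.ndarray, window: int, max_snps: int) -> np.ndarray:
    """Boolean keep-mask: drop every SNP that lies in any inclusive
    ``window``-bp sliding span containing >= ``max_snps`` retained SNPs."""
    keep = np.ones(len(pos), dtype=bool)
    if len(pos) < max_snps:
        return keep
    span = window - 1  # inclusive 10-bp span => max position difference 9
    k = max_snps
    tight = pos[k - 1 :] - pos[: len(pos) - k + 1] <= span
    bad = np.zeros(len(pos), dtype=bool)
    for off in range(k):  # mark all k members of each qualifying run
        bad[off : off + len(tight)] |= tight
    keep[bad] = False
    return keep


def build_parental_snps(
    parent_variants: VariantTable, config: SkimConfig | None = None
) -> ParentalSNPSet:
    """Build the discrimination SNP set from parent-A vs parent-B calls.

    Retains homozygous SNPs (alternate fraction strictly > 0.80) with
    quality >= 30 and depth >= 3, then removes every SNP falling in any
    inclusive 10-bp span that holds 3 or more retained SNPs (clustered
    calls are characteristic of misalignment).
    """
    config = config or SkimConfig()
    df = parent_variants.df
    frac = parent_variants.alt_fraction
    keep = (
        (frac > config.parental_min_alt_fraction)
        & (df["qual"].to_numpy(dtype=float) >= config.parental_min_qual)
        & (df["depth"].to_numpy() >= config.parental_min_depth)
    )
    sub = df[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)
    parts = []
    for chrom, grp in sub.groupby("chrom", sort=True):
        mask = _density_filter(
            grp["pos"].to_numpy(), config.density_window, config.density_max_snps
        )
        parts.append(grp[mask])
    out = (
        pd.concat(parts, ignore_index=True)[["chrom", "pos", "ref", "alt"]]
        if parts
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    )
    return ParentalSNPSet(out.reset_index(drop=True))


def classify_line_positions(
    line_variants: VariantTable,
    coverage: pd.DataFrame | Mapping[str, np.ndarray],
    snps: ParentalSNPSet,
    config: SkimConfig | None = None,
    line: str = "line",
) -> MarkerTrack:
    """Classify every discrimination site of one skim-sequenced line.

    Line variants below quality 20 are discarded first. At each parental SNP
    position the label is: PARENT_A if the line carries a SNP whose alternate
    allele matches the parent-A allele in strictly more than 80% of reads;
    UNDETERMINED if a SNP is present but fails the fraction or allele test;
    UNDETERMINED if no SNP is called and coverage is below the
    reference-confirmation minimum; PARENT_B if no SNP is called, coverage is
    sufficient and (by the absence of any variant call) the reference allele
    is what was observed.

    ``coverage`` is either a DataFrame (chrom, pos, depth) or a mapping
    chrom -> depth array aligned with the SNP set positions. Positions absent
    from the coverage track count as depth 0.
    """
    config = config or SkimConfig()
    vdf = line_variants.df
    qual_ok = ~vdf["qual"].isna().to_numpy() & (
        vdf["qual"].to_numpy(dtype=float) >= config.line_min_qual
    )
    vdf = vdf[qual_ok].assign(frac=line_variants.alt_fraction[qual_ok])
    v_by_chrom = {str(c): g for c, g in vdf.groupby("chrom", sort=False)}

    cov_is_df = isinstance(coverage, pd.DataFrame)
    if cov_is_df:
        c_by_chrom = {str(c): g for c, g in coverage.groupby("chrom", sort=False)}
    positions: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    for chrom, snp in snps.by_chrom():
        p = snp["pos"].to_numpy()
        lab = np.full(len(p), UNDETERMINED, dtype=np.int8)

        sub = v_by_chrom.get(chrom)
        if sub is not None and len(sub):
            # match line variants to parental positions
            vpos = sub["pos"].to_numpy()
            order = np.argsort(vpos, kind="stable")
            vpos_s = vpos[order]
            idx = np.searchsorted(vpos_s, p)
            hit = np.minimum(idx, len(vpos_s) - 1)
            has_snp = (idx < len(vpos_s)) & (vpos_s[hit] == p)
            vfrac = sub["frac"].to_numpy()[order]
            valt = sub["alt"].to_numpy()[order]
            ok = (
                has_snp
                & (vfrac[hit] > config.line_min_alt_fraction)
                & (valt[hit] == snp["alt"].to_numpy())
            )
            lab[ok] = PARENT_A
        else:
            has_snp = np.zeros(len(p), dtype=bool)

        # no SNP called: reference confirmation needs coverage
        if cov_is_df:
            csub = c_by_chrom.get(chrom)
            if csub is None:
                csub = coverage.iloc[:0]
            cpos = csub["pos"].to_numpy()
            depth = np.zeros(len(p), dtype=np.int64)
            if len(cpos):
                corder = np.argsort(cpos, kind="stable")
                cpos_s = cpos[corder]
                cdep_s = csub["depth"].to_numpy()[corder]
                ci = np.searchsorted(cpos_s, p)
                hit2 = np.minimum(ci, len(cpos_s) - 1)
                chit = (ci < len(cpos_s)) & (cpos_s[hit2] == p)
                depth[chit] = cdep_s[hit2][chit]
        else:
            depth = np.asarray(coverage.get(chrom, np.zeros(len(p))), dtype=np.int64)
            if len(depth) != len(p):
                raise ValueError("aligned coverage array length mismatch")
        ref_ok = ~has_snp & (depth >= config.min_ref_coverage)
        lab[ref_ok] = PARENT_B

        positions[chrom] = p
        labels[chrom] = lab
    return MarkerTrack(line=line, positions=positions, labels=labels)


def _rle(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: returns (run start indices incl. terminal sentinel,
    run values)."""
    if len(labels) == 0:
        return np.array([0], dtype=np.int64), np.array([], dtype=labels.dtype)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change, [len(labels)]))
    return starts, labels[starts[:-1]]


def segment_marker_track(
    track: MarkerTrack, config: SkimConfig | None = None
) -> list[RecombinationEvent]:
    """Segment a classified marker track into parental runs and emit events.

    Undetermined positions are removed. The determined label string is cut
    into maximal runs; any run shorter than ``min_run`` (3) markers is
    discarded — its markers are dropped and the flanking same-parent runs
    merge — iterating until stable. Each surviving internal run (bounded by
    the other parent on both sides) is emitted as a GC event spanning its
    first to last marker; terminal runs at chromosome ends are emitted as
    SHIFT boundaries, not GC tracts.
    """
    config = config or SkimConfig()
    events: list[RecombinationEvent] = []
    for chrom in sorted(track.positions):
        lab = track.labels[chrom]
        pos = track.positions[chrom]
        det = lab != UNDETERMINED
        lab, pos = lab[det], pos[det]
        # iterate: drop markers of sub-threshold runs, re-merge, repeat
        while len(lab):
            starts, values = _rle(lab)
            lengths = np.diff(starts)
            short = lengths < config.min_run
            if not short.any():
                break
            keep = np.ones(len(lab), dtype=bool)
            for r in np.flatnonzero(short):
                keep[starts[r] : starts[r + 1]] = False
            lab, pos = lab[keep], pos[keep]
        if len(lab) == 0:
            continue
        starts, values = _rle(lab)
        n_runs = len(values)
        for r in range(n_runs):
            i, j = starts[r], starts[r + 1] - 1
            kind = KIND_GC if 0 < r < n_runs - 1 else KIND_SHIFT
            events.append(
                RecombinationEvent(
                    line=track.line, chrom=chrom,
                    start=int(pos[i]), end=int(pos[j]),
                    donor=int(values[r]), kind=kind,
                    support=int(j - i + 1),
                )
            )
    return events


def donor_change_boundaries(
    events: Sequence[RecombinationEvent],
) -> list[tuple[str, int, int, int]]:
    """Inter-run gaps where the donor parent changes: (chrom, last marker of
    one run, first marker of the next, index of the later run's event).
    Events must be the ordered output of :func:`segment_marker_track`."""
    out = []
    by_chrom: dict[str, list[tuple[int, RecombinationEvent]]] = {}
    for i, e in enumerate(events):
        by_chrom.setdefault(e.chrom, []).append((i, e))
    for chrom, evs in by_chrom.items():
        evs.sort(key=lambda t: t[1].start)
        for (_, a), (j, b) in zip(evs, evs[1:]):
            out.append((chrom, a.end, b.start, j))
    return out


def classify_event_lengths(
    events: Sequence[RecombinationEvent], config: SkimConfig | None = None
) -> list[RecombinationEvent]:
    """Label each event's span with its length class (left-closed right-open
    bins [20, 2k), [2k, 10k), [10k, 500k), [500k, inf); spans < 20 bp are
    SUB_MINIMUM and excluded from GC tallies) and set the 20-/40-Mbp
    crossover-proxy flags."""
    config = config or SkimConfig()
    bounds = config.length_bounds
    for e in events:
        s = e.span
        if s < bounds[0]:
            e.length_class = LENGTH_CLASSES[0]
        else:
            k = int(np.searchsorted(np.asarray(bounds), s, side="right"))
            e.length_class = LENGTH_CLASSES[k]
        e.co20_flag = s >= config.co_proxy_20mb
        e.co40_flag = s >= config.co_proxy_40mb
    return list(events)


def conservation_filter(
    events_by_line: Mapping[str, Sequence[RecombinationEvent]],
    n_lines: int | None = None,
    config: SkimConfig | None = None,
) -> dict:
    """Flag event sharing across lines and report the sharing census.

    Two events in different lines are "shared" when their intervals overlap
    by >= 1 bp with the same donor parent. Per event the number of lines
    sharing it is recorded; events seen in a single line are flagged unique
    (high confidence), events conserved across a strict majority of lines
    are flagged as likely structural variants rather than meiotic events.
    """
    config = config or SkimConfig()
    lines = list(events_by_line)
    if n_lines is None:
        n_lines = len(lines)
    if n_lines < 2:
        logger.warning("conservation census over < 2 lines; all events unique")
    trees: dict[tuple[str, int], IntervalTree] = {}
    for line, evs in events_by_line.items():
        for e in evs:
            trees.setdefault((e.chrom, e.donor), IntervalTree()).addi(
                e.start, e.end + 1, line
            )
    total = 0
    n_unique = 0
    n_below_majority = 0
    for line, evs in events_by_line.items():
        for e in evs:
            tree = trees[(e.chrom, e.donor)]
            sharers = {iv.data for iv in tree.overlap(e.start, e.end + 1)}
            sharers.add(line)
            count = len(sharers)
            e.sharing_count = count
            e.unique_to_line = count == 1
            e.sv_flagged = n_lines >= 2 and count / n_lines > config.conservation_majority
            total += 1
            n_unique += count == 1
            n_below_majority += count / max(n_lines, 1) < config.conservation_majority
    return {
        "n_events": total,
        "fraction_unique": n_unique / total if total else float("nan"),
        "fraction_below_majority": n_below_majority / total if total else float("nan"),
    }


def validate_shifts_with_readpairs(
    observations: Sequence[Sequence[tuple[str, str]]],
    expected: Sequence[tuple[str, str]],
    config: SkimConfig | None = None,
) -> dict:
    """Estimate the shift-call accuracy from read pairs spanning both
    flanking SNPs of each donor change.

    Per shift site, ``observations[i]`` lists read pairs as (allele observed
    at the parent-B-side SNP, allele at the parent-A-side SNP) and
    ``expected[i]`` gives the two parental alleles. A site is assessable
    with >= 3 covering read pairs and supported when the majority of them
    report the expected discordant parent alleles. Accuracy = supported /
    assessable; an empty assessable set is an error.
    """
    config = config or SkimConfig()
    if len(observations) != len(expected):
        raise ValueError("observations and expected allele pairs differ in length")
    n_assessable = n_supported = 0
    for pairs, (b_allele, a_allele) in zip(observations, expected):
        if len(pairs) < config.readpair_min_cov:
            continue
        n_assessable += 1
        concordant = sum(1 for b, a in pairs if b == b_allele and a == a_allele)
        if concordant > len(pairs) / 2:
            n_supported += 1
    if n_assessable == 0:
        raise ValueError("no assessable shift sites; accuracy undefined")
    return {
        "n_assessable": n_assessable,
        "n_supported": n_supported,
        "accuracy": n_supported / n_assessable,
    }


def normalize_gc_by_informative_sites(
    gc_count: int, informative_sites: int, reference_sites: int
) -> float:
    """Scale a line's GC count to the full discrimination-site catalogue:
    normalized = gc_count x reference_sites / informative_sites."""
    if informative_sites <= 0:
        raise ValueError("informative site count must be positive")
    return gc_count * reference_sites / informative_sites
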