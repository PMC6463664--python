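"""Validation of array-called events against skim-sequencing events.

Array crossovers are resolved only to the intersection of two 20-Mbp
windows, so an array CO is accepted when the interval +-20 Mbp around its
window-start position overlaps a donor-change boundary in the skim data
(the gap between the last marker of one parental run and the first marker
of the next). Array gene conversions are point calls at a defining array
SNP; they are accepted when a 3-Mbp interval (by default +-1.5 Mbp) around
the call intersects a skim GC tract of the same line, and upgraded to
high confidence when the skim donor at the defining SNP matches the array
allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import KIND_GC, RecombinationEvent
from .skim_caller import donor_change_boundaries


@dataclass
class ValidationReport:
    """Per-event validation rows plus recomputable aggregates."""

    per_event: pd.DataFrame  # columns: line, chrom, pos, validated, matched_id, matched_length, allele_validated
    fraction_validated: float
    fraction_allele_validated: float | None
    mean_matched_length: float

    def __post_init__(self):
        if len(self.per_event):
            assert abs(
                self.per_event["validated"].mean() - self.fraction_validated
            ) < 1e-12


def _aggregate(rows: list[dict], with_allele: bool) -> ValidationReport:
    df = pd.DataFrame(
        rows,
        columns=[
            "line", "chrom", "pos", "validated", "matched_id",
            "matched_length", "allele_validated",
        ],
    )
    n = len(df)
    frac = float(df["validated"].mean()) if n else float("nan")
    frac_allele = float(df["allele_validated"].mean()) if (n and with_allele) else None
    matched = df.loc[df["validated"], "matched_length"].dropna()
    return ValidationReport(
        per_event=df,
        fraction_validated=frac,
        fraction_allele_validated=frac_allele,
        mean_matched_length=float(matched.mean()) if len(matched) else float("nan"),
    )


def validate_array_cos(
    array_cos: Sequence[RecombinationEvent],
    skim_events: Sequence[RecombinationEvent],
    flank: int = 20_000_000,
) -> ValidationReport:
    """Validate array COs against skim donor-change boundaries.

    An array CO at window-start position p is validated when [p - flank,
    p + flank] overlaps the boundary region of any skim donor change of the
    same line; the length of the run that begins at the matched boundary is
    recorded as the matched event length.
    """
    bounds = donor_change_boundaries(skim_events)
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for chrom, left, right, ev_idx in bounds:
        line = skim_events[ev_idx].line
        by_key.setdefault((line, chrom), []).append((left, right, ev_idx))
    rows = []
    for co in array_cos:
        lo, hi = co.start - flank, co.start + flank
        matched_id = None
        matched_len = np.nan
        for left, right, ev_idx in by_key.get((co.line, co.chrom), []):
            if left <= hi and right >= lo:  # interval overlap
                matched_id = ev_idx
                matched_len = skim_events[ev_idx].span
                break
        rows.append(
            {
                "line": co.line, "chrom": co.chrom, "pos": co.start,
                "validated": matched_id is not None,
                "matched_id": matched_id, "matched_length": matched_len,
                "allele_validated": False,
            }
        )
    return _aggregate(rows, with_allele=False)


def validate_array_gcs(
    array_gcs: Sequence[RecombinationEvent],
    skim_events: Sequence[RecombinationEvent],
    interval: int = 3_000_000,
    half_width: bool = False,
) -> ValidationReport:
    """Validate array GC calls against skim GC tracts.

    The window around the array call spans ``interval`` bp in total
    (+-interval/2), matching the typical genome space between array SNPs;
    set ``half_width=True`` to use +-interval instead. A call is validated
    when its window intersects a skim GC of the same line, and
    allele-validated (high confidence) when the matched tract's donor equals
    the array call's donor state at the defining SNP.
    """
    half = interval if half_width else interval // 2
    by_key: dict[tuple[str, str], list[RecombinationEvent]] = {}
    for i, e in enumerate(skim_events):
        if e.kind == KIND_GC:
            by_key.setdefault((e.line, e.chrom), []).append(e)
    rows = []
    for gc in array_gcs:
        pos = gc.snp_pos if gc.snp_pos is not None else gc.start
        lo, hi = pos - half, pos + half
        validated = False
        allele_ok = False
        matched_id = None
        matched_len = np.nan
        for e in by_key.get((gc.line, gc.chrom), []):
            if e.start <= hi and e.end >= lo:
                validated = True
                matched_id = id(e)
                matched_len = e.span
                if e.donor == gc.donor:
                    allele_ok = True
                    break
        rows.append(
            {
                "line": gc.line, "chrom": gc.chrom, "pos": pos,
                "validated": validated, "matched_id": matched_id,
                "matched_length": matched_len, "allele_validated": allele_ok,
            }
        )
    return _aggregate(rows, with_allele=True)
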