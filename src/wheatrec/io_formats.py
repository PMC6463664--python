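"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: all public coordinates are 1-based inclusive (as in
VCF/GFF3). Only BED serialization converts, at the boundary, to 0-based
half-open. Intervals such as a gene [start, end] or a recombination event
[start, end] therefore include both endpoints.

Call states for array genotypes are small integer codes shared across the
package (see :data:`PARENT_A` etc.); the TILLING zygosity track reuses
``PARENT_A`` for homozygous-mutant and ``HET`` for heterozygous calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

# Genotype call states.
PARENT_A = 0
PARENT_B = 1
HET = 2
MISSING = 3

STATE_NAMES = {PARENT_A: "A", PARENT_B: "B", HET: "H", MISSING: "N"}
DEFAULT_CODING = {"A": PARENT_A, "B": PARENT_B, "H": HET, "N": MISSING}

# Skim marker-track labels (UNDETERMINED is distinct from array MISSING only
# in name; both mean "no informative call at this position").
UNDETERMINED = 3


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths and optional centromere midpoints (bp)."""

    names: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, int] | None = None

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        for name in self.names:
            if self.lengths[name] <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            if self.centromeres and name in self.centromeres:
                if not (0 < self.centromeres[name] < self.lengths[name]):
                    raise ValueError(f"centromere of {name} outside chromosome")

    @property
    def genome_size(self) -> int:
        return sum(self.lengths[n] for n in self.names)

    @classmethod
    def uniform(cls, n_chroms: int, length: int, prefix: str = "chr") -> "GenomeLayout":
        names = tuple(f"{prefix}{i + 1}" for i in range(n_chroms))
        return cls(names=names, lengths={n: int(length) for n in names})


def read_genome_layout(path) -> GenomeLayout:
    """Read a layout TSV with columns: chrom, length[, centromere]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cent = None
    if "centromere" in df.columns and df["centromere"].notna().any():
        cent = {r.chrom: int(r.centromere) for r in df.itertuples() if pd.notna(r.centromere)}
    return GenomeLayout(
        names=tuple(df["chrom"].astype(str)),
        lengths={str(r.chrom): int(r.length) for r in df.itertuples()},
        centromeres=cent,
    )


def write_genome_layout(layout: GenomeLayout, path) -> None:
    rows = []
    for n in layout.names:
        cent = layout.centromeres.get(n) if layout.centromeres else None
        rows.append({"chrom": n, "length": layout.lengths[n], "centromere": cent})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Ordered markers x lines with per-call parental/zygosity states.

    ``markers`` is a DataFrame with columns (chrom, pos, marker_id) sorted by
    (chrom, pos); ``calls`` is an int8 array of shape (n_markers, n_lines)
    holding the state codes above.
    """

    markers: pd.DataFrame
    lines: list[str]
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.markers), len(self.lines)):
            raise ValueError("calls shape does not match markers x lines")
        if (self.markers["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        if not np.isin(self.calls, [PARENT_A, PARENT_B, HET, MISSING]).all():
            raise ValueError("calls contain states outside the four-state alphabet")
        dup = self.markers.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = self.markers[dup].iloc[0]
            raise ValueError(
                f"duplicate marker coordinate {row['chrom']}:{row['pos']}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def line_index(self, line: str) -> int:
        try:
            return self.lines.index(line)
        except ValueError:
            raise KeyError(f"unknown line id: {line}") from None

    def line_calls(self, line: str) -> np.ndarray:
        return self.calls[:, self.line_index(line)]


def read_genotype_matrix(path, coding: Mapping[str, int] | None = None) -> GenotypeMatrix:
    """Read a genotype TSV: chrom, pos, marker_id, then one column per line.

    Unknown codes are mapped to MISSING with a logged count. Unsorted input is
    sorted with a warning; a repeated (chrom, pos) coordinate is rejected.
    """
    coding = dict(DEFAULT_CODING if coding is None else coding)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[:3].tolist() != ["chrom", "pos", "marker_id"]:
        raise ValueError("expected leading columns: chrom, pos, marker_id")
    line_ids = df.columns[3:].tolist()
    markers = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": df["pos"].astype(np.int64),
            "marker_id": df["marker_id"].astype(str),
        }
    )
    raw = df[line_ids].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int8)
    unknown = 0
    for code, state in coding.items():
        calls[raw == code] = state
    known_codes = set(coding)
    unknown = int((~np.isin(raw, list(known_codes))).sum())
    if unknown:
        logger.info("mapped %d unknown genotype codes to MISSING", unknown)
    order = np.lexsort((markers["pos"].to_numpy(), markers["chrom"].to_numpy()))
    if not np.array_equal(order, np.arange(len(markers))):
        warnings.warn("genotype matrix was not coordinate-sorted; sorting")
        markers = markers.iloc[order].reset_index(drop=True)
        calls = calls[order]
    return GenotypeMatrix(markers=markers, lines=line_ids, calls=calls)


def write_genotype_matrix(gm: GenotypeMatrix, path, coding: Mapping[str, int] | None = None) -> None:
    coding = dict(DEFAULT_CODING if coding is None else coding)
    rev = {v: k for k, v in coding.items()}
    out = gm.markers.copy()
    sym = np.vectorize(rev.get)(gm.calls)
    for j, line in enumerate(gm.lines):
        out[line] = sym[:, j]
    out.to_csv(path, sep="\t", index=False)


@dataclass
class VariantTable:
    """Biallelic SNP records from a VCF: one row per retained record.

    Columns: chrom, pos, ref, alt, qual, depth, alt_depth, mq (NaN when the
    VCF carries no MQ). ``alt_fraction`` is derived on demand.
    """

    df: pd.DataFrame

    COLUMNS = ("chrom", "pos", "ref", "alt", "qual", "depth", "alt_depth", "mq")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if len(self.df) and (self.df["pos"] < 1).any():
            raise ValueError("variant positions must be >= 1")
        bad = (self.df["alt_depth"] > self.df["depth"]) | (self.df["alt_depth"] < 0)
        if len(self.df) and bad.any():
            raise ValueError("alt depth must satisfy 0 <= alt_depth <= depth")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def alt_fraction(self) -> np.ndarray:
        depth = self.df["depth"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = self.df["alt_depth"].to_numpy(dtype=float) / depth
        return np.where(depth > 0, frac, 0.0)

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "VariantTable":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        if len(df) == 0:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                cls.COLUMNS,
                [str, np.int64, str, str, float, np.int64, np.int64, float],
            )})
        return cls(df)


def read_variant_table(path) -> VariantTable:
    """Read a VCF into a :class:`VariantTable` of biallelic SNPs.

    Multiallelic records, indels and records without usable depth fields are
    dropped, with counts logged. QUAL defaults to NaN when absent; depth is
    taken from FORMAT/DP+AD of the first sample when present, else INFO/DP.
    """
    from cyvcf2 import VCF

    rows = []
    n_multi = n_indel = n_nodepth = 0
    vcf = VCF(str(path))
    has_sample = len(vcf.samples) > 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref == "." or alt == ".":
            n_indel += 1
            continue
        depth = alt_depth = None
        if has_sample:
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is not None and ad.shape[-1] >= 2 and ad[0][0] >= 0:
                depth = int(ad[0][0]) + int(ad[0][1])
                alt_depth = int(ad[0][1])
        if depth is None:
            info_dp = rec.INFO.get("DP")
            info_ad = rec.INFO.get("AD")
            if info_dp is not None and info_ad is not None:
                depth = int(info_dp)
                alt_depth = int(info_ad if np.isscalar(info_ad) else info_ad[-1])
        if depth is None:
            n_nodepth += 1
            continue
        mq = rec.INFO.get("MQ")
        rows.append(
            (rec.CHROM, rec.POS, ref, alt,
             float(rec.QUAL) if rec.QUAL is not None else np.nan,
             depth, alt_depth, float(mq) if mq is not None else np.nan)
        )
    if n_multi or n_indel or n_nodepth:
        logger.info(
            "dropped VCF records: %d multiallelic, %d non-SNP, %d without depth",
            n_multi, n_indel, n_nodepth,
        )
    return VariantTable.from_records(rows)


def write_variant_table(vt: VariantTable, path, sample: str | None = "sample") -> None:
    """Write a VariantTable as an uncompressed VCF 4.2 file via pysam.

    Depth is emitted both as INFO/DP+AD and, when ``sample`` is given, as a
    FORMAT field so that :func:`read_variant_table` round-trips.
    """
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">')
    header.add_line('##INFO=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    for chrom in pd.unique(vt.df["chrom"]):
        header.contigs.add(str(chrom))
    if sample:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in vt.df.itertuples():
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            if not np.isnan(row.qual):
                rec.qual = float(row.qual)
            rec.info["DP"] = int(row.depth)
            rec.info["AD"] = (int(row.depth) - int(row.alt_depth), int(row.alt_depth))
            if not (row.mq is None or np.isnan(row.mq)):
                rec.info["MQ"] = float(row.mq)
            if sample:
                rec.samples[sample]["GT"] = (1, 1)
                rec.samples[sample]["AD"] = (
                    int(row.depth) - int(row.alt_depth), int(row.alt_depth))
            out.write(rec)


@dataclass
class GeneIndex:
    """Gene intervals per chromosome, queryable by window (1-based inclusive)."""

    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int, str]]) -> "GeneIndex":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end, gene_id in intervals:
            if start > end:
                raise ValueError(f"gene {gene_id}: start > end")
            # IntervalTree is half-open; store [start, end] as [start, end+1).
            trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)
        return cls(trees)

    def query(self, chrom: str, start: int, end: int) -> list[str]:
        """Gene ids overlapping [start, end] by at least 1 bp."""
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end + 1))

    def count(self, chrom: str, start: int, end: int) -> int:
        tree = self.trees.get(chrom)
        return 0 if tree is None else len(tree.overlap(start, end + 1))


def read_gene_index(path, fmt: str | None = None) -> GeneIndex:
    """Read gene intervals from BED (0-based half-open) or GFF3 'gene' features."""
    path = str(path)
    if fmt is None:
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "bed"
    intervals = []
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"])
        for r in df.itertuples():
            intervals.append((str(r.chrom), int(r.start) + 1, int(r.end), str(r.name)))
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique")
        for feat in db.features_of_type("gene"):
            intervals.append((feat.seqid, feat.start, feat.end, feat.id))
    else:
        raise ValueError(f"unknown gene annotation format: {fmt}")
    return GeneIndex.from_intervals(intervals)


# Event kinds and donor states for recombination events.
KIND_CO = "CO"
KIND_GC = "GC"
KIND_SHIFT = "SHIFT"

LENGTH_CLASSES = ("SUB_MINIMUM", "20bp-2kbp", "2-10kbp", "10-500kbp", ">500kbp")


@dataclass
class RecombinationEvent:
    """A called CO, GC tract or run-boundary shift.

    ``donor`` is a state code (PARENT_A/PARENT_B/HET); confidence flags are
    set by downstream filters.
    """

    line: str
    chrom: str
    start: int
    end: int
    donor: int
    kind: str
    support: int = 1
    length_class: str | None = None
    co20_flag: bool = False
    co40_flag: bool = False
    unique_to_line: bool = False
    allele_validated: bool = False
    sv_flagged: bool = False
    sharing_count: int | None = None
    snp_pos: int | None = None  # defining array SNP for array GC calls

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("event start > end")
        if self.support < 1:
            raise ValueError("marker support must be >= 1")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


_FLAGS = ("co20", "co40", "unique", "allele", "sv")


def write_events(events: Sequence[RecombinationEvent], path) -> None:
    """Write events as BED6+: 0-based half-open, name = line|kind|donor|class,
    score = marker support, deterministic (chrom, start, line) sort order."""
    rows = sorted(events, key=lambda e: (e.chrom, e.start, e.end, e.line, e.kind))
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tflags\n")
        for e in rows:
            flags = ",".join(
                name for name, on in zip(
                    _FLAGS,
                    (e.co20_flag, e.co40_flag, e.unique_to_line,
                     e.allele_validated, e.sv_flagged),
                ) if on
            ) or "."
            name = f"{e.line}|{e.kind}|{STATE_NAMES[e.donor]}|{e.length_class or '.'}"
            fh.write(
                f"{e.chrom}\t{e.start - 1}\t{e.end}\t{name}\t{e.support}\t.\t{flags}\n"
            )


def read_events(path) -> list[RecombinationEvent]:
    rev_state = {v: k for k, v in STATE_NAMES.items()}
    events = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            chrom, start, end, name, score, _strand, flags = raw.rstrip("\n").split("\t")
            line, kind, donor, lclass = name.split("|")
            flagset = set(flags.split(",")) if flags != "." else set()
            events.append(
                RecombinationEvent(
                    line=line, chrom=chrom, start=int(start) + 1, end=int(end),
                    donor=rev_state[donor], kind=kind, support=int(score),
                    length_class=None if lclass == "." else lclass,
                    co20_flag="co20" in flagset, co40_flag="co40" in flagset,
                    unique_to_line="unique" in flagset,
                    allele_validated="allele" in flagset,
                    sv_flagged="sv" in flagset,
                )
            )
    return events
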