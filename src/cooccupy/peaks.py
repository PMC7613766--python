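"""Peak containers, MACS2 dialect I/O, filtering, ranking, cohorts and annotation.

Internal coordinates are 0-based, half-open throughout.  The two supported
input dialects are ENCODE narrowPeak (BED6+4) and the MACS2 ``_peaks.xls``
table; the 1-based conventions of the latter are converted at the boundary.
Peak strength is the MACS2 *pileup* statistic (read depth at the summit) and
*fold enrichment* is signal relative to the input library.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "Peak",
    "PeakSet",
    "CohortTable",
    "AnnotationResult",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_macs2_xls",
    "write_macs2_xls",
    "read_bed",
    "filter_peaks",
    "select_top",
    "assign_cohorts",
    "annotate_peaks",
]

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "pileup", "fold_enrichment", "name"]

#: annotation categories in order of decreasing precedence
ANNOTATION_PRECEDENCE = ["promoter", "5'UTR", "3'UTR", "exon", "intron", "TTS", "intergenic"]


@dataclass(frozen=True)
class Peak:
    """A single called binding site.

    ``summit`` is the absolute (chromosome-level, 0-based) position of maximal
    pileup within the peak, not an offset from ``start``.
    """

    chrom: str
    start: int
    end: int
    summit: int
    pileup: float
    fold_enrichment: float
    name: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"peak {self.name}: end {self.end} <= start {self.start}")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"peak {self.name}: summit {self.summit} outside [{self.start}, {self.end})"
            )
        if self.pileup < 0 or self.fold_enrichment < 0:
            raise ValueError(f"peak {self.name}: negative pileup or fold enrichment")


class PeakSet:
    """An ordered collection of peaks for one factor, with unique names."""

    def __init__(self, peaks: Iterable[Peak] | pd.DataFrame, factor: str = ""):
        if isinstance(peaks, pd.DataFrame):
            df = peaks.loc[:, PEAK_COLUMNS].reset_index(drop=True).copy()
        else:
            df = pd.DataFrame(
                [(p.chrom, p.start, p.end, p.summit, p.pileup, p.fold_enrichment, p.name)
                 for p in peaks],
                columns=PEAK_COLUMNS,
            )
        if len(df) and df["name"].duplicated().any():
            dup = df.loc[df["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate peak name {dup!r} in set {factor!r}")
        self.factor = factor
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Peak(row.chrom, int(row.start), int(row.end), int(row.summit),
                       float(row.pileup), float(row.fold_enrichment), row.name)

    def __repr__(self) -> str:
        return f"PeakSet(factor={self.factor!r}, n={len(self)})"

    @property
    def pileups(self) -> np.ndarray:
        return self.df["pileup"].to_numpy(float)

    def subset(self, mask) -> "PeakSet":
        return PeakSet(self.df.loc[np.asarray(mask)], factor=self.factor)


@dataclass
class CohortTable:
    """Strength-ranked assignment of peaks into equal-size cohorts.

    Cohort 1 holds the strongest peaks.  With ``N`` input peaks and ``K``
    cohorts, cohort size is ``N // K`` and the ``N mod K`` weakest peaks are
    discarded so that every retained cohort has identical size.
    """

    assignments: pd.Series  # peak name -> cohort index (1..K)
    n_cohorts: int
    cohort_size: int
    discarded: list[str]

    def members(self, cohort: int) -> list[str]:
        if not 1 <= cohort <= self.n_cohorts:
            raise ValueError(f"cohort index {cohort} outside 1..{self.n_cohorts}")
        return list(self.assignments.index[self.assignments == cohort])

    @property
    def retained(self) -> list[str]:
        return list(self.assignments.index)


@dataclass
class AnnotationResult:
    """Genomic category of each peak summit plus pie-chart-ready counts."""

    categories: pd.Series  # peak name -> category
    counts: pd.Series      # category -> number of peaks


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path, factor: str = "", sidecar_xls=None) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Column 10 is the summit offset from ``start``; ``-1`` means no summit was
    called and the interval midpoint is used.  Pileup is taken from the
    signalValue column.  narrowPeak carries no fold-enrichment field: when a
    MACS2 ``.xls`` sidecar is given, fold enrichment is merged in by peak
    name; otherwise it is set to ``+inf`` so it never excludes a peak.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
                )
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                signal = float(fields[6])
                offset = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed narrowPeak line: {exc}") from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            records.append((chrom, start, end, summit, signal, math.inf, name))
    df = pd.DataFrame(records, columns=PEAK_COLUMNS)
    if sidecar_xls is not None:
        fe = read_macs2_xls(sidecar_xls).df.set_index("name")["fold_enrichment"]
        df["fold_enrichment"] = df["name"].map(fe).fillna(math.inf).to_numpy()
    return PeakSet(df, factor=factor)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peaks.df.itertuples(index=False):
            score = int(min(1000, round(p.pileup)))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{score}\t.\t"
                f"{float(p.pileup)!r}\t-1\t-1\t{p.summit - p.start}\n"
            )


_XLS_REQUIRED = ["chr", "start", "end", "abs_summit", "pileup", "fold_enrichment"]


def read_macs2_xls(path, factor: str = "") -> PeakSet:
    """Read a MACS2 ``_peaks.xls`` table (tab-separated, '#' comments).

    MACS2 reports 1-based inclusive intervals and a 1-based ``abs_summit``;
    both are converted to the internal 0-based half-open convention.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS), factor=factor)
    if len(df) == 0:
        return PeakSet(pd.DataFrame(columns=PEAK_COLUMNS), factor=factor)
    missing = [c for c in _XLS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required MACS2 xls column(s) {missing}")
    out = pd.DataFrame({
        "chrom": df["chr"].astype(str),
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "summit": df["abs_summit"].astype(int) - 1,
        "pileup": df["pileup"].astype(float),
        "fold_enrichment": df["fold_enrichment"].astype(float),
        "name": df["name"].astype(str) if "name" in df.columns
                else [f"peak_{i + 1}" for i in range(len(df))],
    })
    return PeakSet(out, factor=factor)


def write_macs2_xls(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# peaks table, MACS2 xls dialect (1-based inclusive coordinates)\n")
        fh.write("chr\tstart\tend\tlength\tabs_summit\tpileup\t-log10(pvalue)\t"
                 "fold_enrichment\t-log10(qvalue)\tname\n")
        for p in peaks.df.itertuples(index=False):
            fe = p.fold_enrichment
            fe_s = "inf" if math.isinf(fe) else repr(float(fe))
            fh.write(
                f"{p.chrom}\t{p.start + 1}\t{p.end}\t{p.end - p.start}\t{p.summit + 1}\t"
                f"{float(p.pileup)!r}\t-1\t{fe_s}\t-1\t{p.name}\n"
            )


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file (e.g. a blacklist) into chrom/start/end."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            records.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(records, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# Filtering, ranking, cohorts
# ---------------------------------------------------------------------------

def _blacklist_trees(blacklist: pd.DataFrame | None) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    if blacklist is None or len(blacklist) == 0:
        return trees
    for chrom, grp in blacklist.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    return trees


def filter_peaks(
    peaks: PeakSet,
    blacklist: pd.DataFrame | None = None,
    min_pileup: float = 50.0,
    min_fe: float = 5.0,
) -> PeakSet:
    """Apply the stringent peak thresholds: pileup >= ``min_pileup`` AND fold
    enrichment over input >= ``min_fe``, after excluding any peak whose
    interval shares even one base with a blacklisted region.

    Order-preserving and idempotent.
    """
    if min_pileup < 0 or min_fe < 0:
        raise ValueError("thresholds must be >= 0")
    df = peaks.df
    mask = (df["pileup"].to_numpy() >= min_pileup) & (
        df["fold_enrichment"].to_numpy() >= min_fe
    )
    trees = _blacklist_trees(blacklist)
    if trees:
        clear = np.array(
            [not (t := trees.get(c)) or not t.overlap(s, e)
             for c, s, e in zip(df["chrom"], df["start"], df["end"])],
            dtype=bool,
        )
        mask &= clear
    return peaks.subset(mask)


def select_top(peaks: PeakSet, pileup_threshold: float) -> tuple[PeakSet, float]:
    """Retain peaks with pileup >= threshold; also report the retained
    percentage rounded to one decimal (e.g. 3797 of 18385 at >=110 -> 20.7)."""
    n = len(peaks)
    if n == 0:
        raise ValueError("select_top: empty peak set")
    kept = peaks.subset(peaks.pileups >= pileup_threshold)
    return kept, round(100.0 * len(kept) / n, 1)


def assign_cohorts(peaks: PeakSet, n_cohorts: int = 10) -> CohortTable:
    """Group peaks into ``n_cohorts`` equal cohorts by descending strength.

    Sort key: pileup desc, then fold enrichment desc, then chromosome, then
    start (a fixed tie order so the grouping is reproducible).  Cohort 1 is
    the strongest; the ``N mod n_cohorts`` weakest peaks are discarded.
    """
    n = len(peaks)
    if n < n_cohorts:
        raise ValueError(f"cannot form {n_cohorts} cohorts from {n} peaks")
    order = peaks.df.sort_values(
        ["pileup", "fold_enrichment", "chrom", "start"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    size = n // n_cohorts
    retained = order.iloc[: size * n_cohorts]
    discarded = list(order.iloc[size * n_cohorts:]["name"])
    idx = np.repeat(np.arange(1, n_cohorts + 1), size)
    assignments = pd.Series(idx, index=retained["name"].to_numpy(), name="cohort")
    return CohortTable(assignments, n_cohorts, size, discarded)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
TTS_UPSTREAM = 100
TTS_DOWNSTREAM = 1000


def _parse_int_list(value) -> list[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return []
    if isinstance(value, str):
        return [int(x) for x in value.split(",") if x != ""]
    return [int(x) for x in value]


def annotate_peaks(peaks: PeakSet, genes: pd.DataFrame) -> AnnotationResult:
    """Classify each peak summit into a genomic category.

    Category precedence (a summit in several windows gets the first match):
    promoter > 5'UTR > 3'UTR > exon > intron > TTS > intergenic.

    The gene table needs ``gene_id, chrom, strand, tss, tes``; with optional
    ``exon_starts``/``exon_ends`` (comma lists) the exon/intron distinction is
    made, and with optional ``cds_lo``/``cds_hi`` exonic bases outside the CDS
    become 5'/3' UTR.  Without exon structure, the whole gene body counts as
    intron (gene-body fallback).  Promoter is strand-aware: 1 kb upstream to
    100 bp downstream of the TSS; the TTS window mirrors it around the TES.
    """
    trees: dict[str, dict[str, IntervalTree]] = {}

    def add(cat: str, chrom: str, lo: int, hi: int) -> None:
        if hi > lo:
            trees.setdefault(chrom, {}).setdefault(cat, IntervalTree()).addi(lo, hi)

    for g in genes.itertuples(index=False):
        chrom, strand = g.chrom, g.strand
        tss, tes = int(g.tss), int(g.tes)
        if strand == "+":
            add("promoter", chrom, tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM)
            add("TTS", chrom, tes - TTS_UPSTREAM, tes + TTS_DOWNSTREAM)
        else:
            add("promoter", chrom, tss - PROMOTER_DOWNSTREAM + 1, tss + PROMOTER_UPSTREAM + 1)
            add("TTS", chrom, tes - TTS_DOWNSTREAM + 1, tes + TTS_UPSTREAM + 1)
        lo, hi = min(tss, tes), max(tss, tes) + 1
        ex_starts = _parse_int_list(getattr(g, "exon_starts", None))
        ex_ends = _parse_int_list(getattr(g, "exon_ends", None))
        if ex_starts:
            exons = list(zip(ex_starts, ex_ends))
            cds_lo = getattr(g, "cds_lo", None)
            cds_hi = getattr(g, "cds_hi", None)
            for es, ee in exons:
                if cds_lo is not None and not pd.isna(cds_lo):
                    cds_lo_i, cds_hi_i = int(cds_lo), int(cds_hi)
                    left = (es, min(ee, cds_lo_i))     # exonic, below CDS
                    right = (max(es, cds_hi_i), ee)    # exonic, above CDS
                    low_cat, high_cat = ("5'UTR", "3'UTR") if strand == "+" else ("3'UTR", "5'UTR")
                    add(low_cat, chrom, *left)
                    add(high_cat, chrom, *right)
                    add("exon", chrom, max(es, cds_lo_i), min(ee, cds_hi_i))
                else:
                    add("exon", chrom, es, ee)
            # introns: gaps between consecutive exons
            for (_, ee), (ns, _) in zip(exons, exons[1:]):
                add("intron", chrom, ee, ns)
        else:
            add("intron", chrom, lo, hi)

    seen_chroms = set(genes["chrom"].astype(str)) if len(genes) else set()
    missing = sorted(set(peaks.df["chrom"].astype(str)) - seen_chroms)
    if missing:
        warnings.warn(
            f"peak chromosome(s) {missing} absent from gene table; "
            "their peaks are classified against the remaining genes",
            stacklevel=2,
        )

    cats = []
    for p in peaks.df.itertuples(index=False):
        chrom_trees = trees.get(p.chrom, {})
        cat = "intergenic"
        for candidate in ANNOTATION_PRECEDENCE[:-1]:
            t = chrom_trees.get(candidate)
            if t is not None and t.overlaps_point(int(p.summit)):
                cat = candidate
                break
        cats.append(cat)
    categories = pd.Series(cats, index=peaks.df["name"].to_numpy(), name="category")
    counts = categories.value_counts().reindex(ANNOTATION_PRECEDENCE, fill_value=0)
    return AnnotationResult(categories, counts)
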