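"""Genomic interval containers and peak–gene integration.

Direct androgen receptor (AR) target genes are nominated by requiring that a
gene (i) has an AR binding site (ARBS) whose midpoint lies within a fixed
window of one of its transcription start sites and (ii) appears in at least a
minimum number of independently published androgen-regulated gene lists.
Peaks are further annotated by genomic context (promoter / exon / intron /
intergenic) and by their overlap with a second peak set (e.g. an active
histone mark).

Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

#: Default ARBS–TSS assignment window (bp).
DEFAULT_WINDOW = 300_000

#: Default promoter window around a TSS, strand-oriented: (upstream, downstream).
PROMOTER_WINDOW = (3000, 500)


@dataclass(frozen=True)
class PeakSet:
    """A set of genomic intervals (ARBSs, histone-mark peaks, ...).

    Wraps a DataFrame with columns chrom, start, end, name, score, strand.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in ("chrom", "start", "end") if c not in df.columns]
        if missing:
            raise ValueError(f"PeakSet missing required columns: {missing}")
        df = df.copy()
        for col, default in (("name", ""), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[PEAK_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and not ((df["start"] >= 0) & (df["start"] < df["end"])).all():
            bad = df[~((df["start"] >= 0) & (df["start"] < df["end"]))]
            raise ValueError(f"invalid intervals (need 0 <= start < end):\n{bad}")
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def midpoints(self) -> np.ndarray:
        """Midpoint of [start, end): floor((start + end) / 2)."""
        return (self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2

    @property
    def names(self) -> pd.Series:
        """Peak identifiers: the name column, or the row index where blank."""
        names = self.df["name"].astype(str)
        blank = names == ""
        if blank.any():
            names = names.mask(blank, "peak_" + self.df.index.astype(str))
        return names

    @classmethod
    def from_records(
        cls, records: Iterable[tuple], columns: Sequence[str] | None = None
    ) -> "PeakSet":
        cols = list(columns) if columns is not None else PEAK_COLUMNS[: len(next(iter(records), ()))]
        return cls(pd.DataFrame.from_records(list(records), columns=cols))

    @classmethod
    def read_bed(cls, path) -> "PeakSet":
        """Read a 3–6 column BED file (track/browser lines skipped)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                rows.append(parts[:6] + [""] * (6 - len(parts[:6])))
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
        df["score"] = pd.to_numeric(df["score"], errors="coerce").fillna(0.0)
        df["strand"] = df["strand"].replace("", ".")
        return cls(df)

    def write_bed(self, path) -> None:
        df = self.df.copy()
        df["name"] = self.names
        df.to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class GeneAnnotation:
    """Per-gene annotation: chromosome, strand, TSS position(s), exons.

    ``df`` is indexed by gene_id with columns:
      chrom : str
      strand : '+' or '-'
      tss : tuple of int (a gene may have multiple TSSs)
      exons : tuple of (start, end) half-open intervals, sorted, non-overlapping
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col in ("chrom", "strand", "tss", "exons"):
            if col not in df.columns:
                raise ValueError(f"GeneAnnotation missing column {col!r}")
        if len(df) and not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        for gid, exons in df["exons"].items():
            prev_end = -1
            for s, e in exons:
                if not (0 <= s < e) or s < prev_end:
                    raise ValueError(f"gene {gid}: exons must be sorted, non-overlapping")
                prev_end = e

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    def tss_table(self) -> pd.DataFrame:
        """One row per (gene, TSS): columns gene_id, chrom, strand, tss."""
        rows = [
            (gid, row.chrom, row.strand, t)
            for gid, row in self.df.iterrows()
            for t in row.tss
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnotation":
        """Read the annotation TSV (gene_id, chrom, strand, tss, exons).

        ``tss`` is a comma-separated list of 0-based positions; ``exons`` is a
        comma-separated list of ``start-end`` half-open blocks.
        """
        raw = pd.read_csv(path, sep="\t", dtype=str)
        raw = raw.set_index("gene_id")
        df = pd.DataFrame(index=raw.index)
        df["chrom"] = raw["chrom"]
        df["strand"] = raw["strand"]
        df["tss"] = raw["tss"].map(lambda s: tuple(int(x) for x in str(s).split(",")))
        df["exons"] = raw["exons"].map(
            lambda s: tuple(
                tuple(int(x) for x in block.split("-")) for block in str(s).split(",")
            )
        )
        return cls(df)

    def write_tsv(self, path) -> None:
        out = pd.DataFrame(index=self.df.index)
        out["chrom"] = self.df["chrom"]
        out["strand"] = self.df["strand"]
        out["tss"] = self.df["tss"].map(lambda t: ",".join(str(x) for x in t))
        out["exons"] = self.df["exons"].map(
            lambda ex: ",".join(f"{s}-{e}" for s, e in ex)
        )
        out.to_csv(path, sep="\t", index_label="gene_id")


def assign_peaks_to_tss(
    peaks: PeakSet, annotation: GeneAnnotation, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Assign peaks to genes whose TSS lies within ``window`` bp of the peak midpoint.

    Emits one row per (peak, TSS) pair with |midpoint − TSS| <= window
    (boundary inclusive); a peak may map to many genes and a gene to many
    peaks. The reported distance is midpoint − TSS, strand-oriented (positive
    = downstream of the TSS in the gene's direction of transcription).

    Peaks on chromosomes absent from the annotation are skipped with a logged
    warning.

    Returns a DataFrame with columns peak_id, gene_id, tss, distance.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    tss = annotation.tss_table()
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values("tss").reset_index(drop=True)
        for c, g in tss.groupby("chrom")
    }
    mids = peaks.midpoints
    names = peaks.names.to_numpy()
    chroms = peaks.df["chrom"].to_numpy()

    out: list[tuple] = []
    missing_chroms: set[str] = set()
    for i in range(len(peaks)):
        chrom = str(chroms[i])
        if chrom not in by_chrom:
            missing_chroms.add(chrom)
            continue
        sub = by_chrom[chrom]
        pos = sub["tss"].to_numpy()
        mid = int(mids[i])
        lo = np.searchsorted(pos, mid - window, side="left")
        hi = np.searchsorted(pos, mid + window, side="right")
        for j in range(lo, hi):
            t = int(pos[j])
            d = mid - t
            if sub["strand"].iat[j] == "-":
                d = -d
            out.append((names[i], sub["gene_id"].iat[j], t, d))
    if missing_chroms:
        logger.warning(
            "skipped peaks on chromosomes absent from annotation: %s",
            sorted(missing_chroms),
        )
    return pd.DataFrame(out, columns=["peak_id", "gene_id", "tss", "distance"])


def nominate_targets(
    assignments: pd.DataFrame,
    regulated_lists: Sequence[Iterable[str]],
    min_lists: int = 1,
) -> set[str]:
    """Cross-match peak-assigned genes with androgen-regulated gene lists.

    Returns genes that have at least one peak assignment AND appear in at
    least ``min_lists`` of the regulated lists.
    """
    if min_lists < 1:
        raise ValueError("min_lists must be >= 1")
    if not regulated_lists:
        raise ValueError("regulated_lists must be nonempty: the cross-match is the point")
    assigned = set(assignments["gene_id"])
    counts: dict[str, int] = {}
    for lst in regulated_lists:
        for g in set(lst):
            counts[g] = counts.get(g, 0) + 1
    return {g for g in assigned if counts.get(g, 0) >= min_lists}


class PeakCategories(NamedTuple):
    labels: pd.Series  # per-peak category, indexed by peak id
    counts: dict[str, int]  # category -> count; sums to number of peaks


def categorize_peak_locations(
    peaks: PeakSet,
    annotation: GeneAnnotation,
    promoter_window: tuple[int, int] = PROMOTER_WINDOW,
) -> PeakCategories:
    """Classify each peak midpoint as promoter, exon, intron or intergenic.

    Precedence: promoter > exon > intron > intergenic. The promoter is
    [TSS − upstream, TSS + downstream], strand-oriented; introns are positions
    inside a gene's exon span that are not exonic. "Enhancer" is not callable
    from a gene table alone and is absorbed into intron/intergenic.
    """
    if len(annotation) == 0:
        raise ValueError("annotation must be nonempty")
    up, down = promoter_window

    promoters: dict[str, IntervalTree] = {}
    exons: dict[str, IntervalTree] = {}
    spans: dict[str, IntervalTree] = {}
    for gid, row in annotation.df.iterrows():
        chrom = str(row["chrom"])
        for t in row["tss"]:
            if row["strand"] == "+":
                lo, hi = t - up, t + down + 1  # inclusive of TSS+down
            else:
                lo, hi = t - down, t + up + 1
            promoters.setdefault(chrom, IntervalTree()).addi(lo, hi)
        ex = row["exons"]
        for s, e in ex:
            exons.setdefault(chrom, IntervalTree()).addi(s, e)
        if ex:
            spans.setdefault(chrom, IntervalTree()).addi(ex[0][0], ex[-1][1])

    labels = []
    for chrom, mid in zip(peaks.df["chrom"].astype(str), peaks.midpoints):
        mid = int(mid)
        if chrom in promoters and promoters[chrom].overlaps_point(mid):
            labels.append("promoter")
        elif chrom in exons and exons[chrom].overlaps_point(mid):
            labels.append("exon")
        elif chrom in spans and spans[chrom].overlaps_point(mid):
            labels.append("intron")
        else:
            labels.append("intergenic")
    ser = pd.Series(labels, index=peaks.names.to_numpy(), name="category")
    counts = {c: 0 for c in ("promoter", "exon", "intron", "intergenic")}
    for c in labels:
        counts[c] += 1
    return PeakCategories(ser, counts)


def overlap_fraction(peaks_a: PeakSet, peaks_b: PeakSet) -> float:
    """Fraction of peaks in A having >=1 bp overlap with any peak in B."""
    if len(peaks_a) == 0:
        warnings.warn("overlap_fraction: empty peak set A; returning 0.0")
        return 0.0
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in zip(
        peaks_b.df["chrom"].astype(str), peaks_b.df["start"], peaks_b.df["end"]
    ):
        trees.setdefault(chrom, IntervalTree()).addi(int(s), int(e))
    n_hit = 0
    for chrom, s, e in zip(
        peaks_a.df["chrom"].astype(str), peaks_a.df["start"], peaks_a.df["end"]
    ):
        if chrom in trees and trees[chrom].overlap(int(s), int(e)):
            n_hit += 1
    return n_hit / len(peaks_a)


def extend_peaks(
    peaks: PeakSet, pad: int = 1000, chrom_sizes: Mapping[str, int] | None = None
) -> PeakSet:
    """Expand each interval by ``pad`` bp on both ends, clipping at chromosome bounds.

    Left ends are clipped at 0. If ``chrom_sizes`` is provided, right ends are
    clipped at the chromosome length and every peak chromosome must be listed;
    without it no right clipping is applied.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    df = peaks.df.copy()
    if pad == 0:
        return PeakSet(df)
    df["start"] = np.maximum(0, df["start"] - pad)
    df["end"] = df["end"] + pad
    if chrom_sizes is not None:
        missing = sorted(set(df["chrom"].astype(str)) - set(chrom_sizes))
        if missing:
            raise KeyError(f"chromosome sizes missing for: {missing}")
        caps = df["chrom"].astype(str).map(chrom_sizes).to_numpy(dtype=np.int64)
        df["end"] = np.minimum(df["end"].to_numpy(), caps)
    return PeakSet(df)


def read_gene_list(path) -> list[str]:
    """Read a newline-delimited gene list (blank lines and '#' comments skipped)."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a 2-column chromosome-sizes TSV (chrom, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))
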