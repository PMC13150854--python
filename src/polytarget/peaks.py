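"""Replicate peak sets: narrowPeak I/O, enrichment filtering, replicate
matching and nested validation levels.

Validation levels are the nested confidence tiers used for reproducible
binding sites:

* VL1 — peak present in both biological replicates (>=1 bp overlap) with
  fold enrichment strictly > 2 and q-value strictly < 1e-3 in each;
* VL2 — VL1 plus replicate summits within <=200 bp and IDR <= 0.05;
* VL3 — VL1 plus summits within <=100 bp and IDR <= 0.05.

Read cumulatively, VL3 ⊆ VL2 ⊆ VL1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from .errors import DataError

__all__ = [
    "Peak",
    "ReproduciblePeak",
    "LEVELS",
    "read_narrowpeak",
    "write_narrowpeak",
    "filter_peaks",
    "overlap_replicates",
    "assign_validation_levels",
    "write_peaks_bed",
    "read_peaks_bed",
]

LEVELS = ("VL1", "VL2", "VL3")
LEVEL_RANK = {lvl: i + 1 for i, lvl in enumerate(LEVELS)}


@dataclass(frozen=True)
class Peak:
    """One called binding interval (0-based half-open, absolute summit)."""

    chrom: str
    start: int
    end: int
    summit: int
    fold_enrichment: float
    neg_log10_q: float
    name: str = "."
    score: int = 0
    neg_log10_p: float = -1.0

    def __post_init__(self):
        if not self.start < self.end:
            raise DataError(f"peak {self.name}: start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise DataError(
                f"peak {self.name}: summit {self.summit} outside [{self.start},{self.end})"
            )
        if self.fold_enrichment < 0:
            raise DataError(f"peak {self.name}: negative fold enrichment")

    @property
    def qvalue(self) -> float:
        return 10.0 ** (-self.neg_log10_q)


@dataclass(frozen=True)
class ReproduciblePeak:
    """A matched replicate peak pair.

    ``start``/``end`` span the union of the two replicate intervals;
    ``summit`` is the midpoint of the two replicate summits and is the
    position used by all downstream annotation.
    """

    rep1: Peak
    rep2: Peak
    idr: float = math.nan  # global IDR, filled by assign_validation_levels
    level: str = "VL1"

    def __post_init__(self):
        if self.rep1.chrom != self.rep2.chrom:
            raise DataError("replicate peaks on different chromosomes")
        if min(self.rep1.end, self.rep2.end) <= max(self.rep1.start, self.rep2.start):
            raise DataError(
                f"replicate peaks {self.rep1.name}/{self.rep2.name} do not overlap"
            )

    @property
    def chrom(self) -> str:
        return self.rep1.chrom

    @property
    def start(self) -> int:
        return min(self.rep1.start, self.rep2.start)

    @property
    def end(self) -> int:
        return max(self.rep1.end, self.rep2.end)

    @property
    def summit(self) -> int:
        return (self.rep1.summit + self.rep2.summit) // 2

    @property
    def summit_distance(self) -> int:
        return abs(self.rep1.summit - self.rep2.summit)

    @property
    def name(self) -> str:
        return f"{self.rep1.name}|{self.rep2.name}"

    def score(self, which="fold_enrichment"):
        if which == "fold_enrichment":
            return self.rep1.fold_enrichment, self.rep2.fold_enrichment
        if which == "neg_log10_q":
            return self.rep1.neg_log10_q, self.rep2.neg_log10_q
        raise DataError(f"unknown IDR score: {which!r}")


# ---------------------------------------------------------------------------
# narrowPeak I/O
# ---------------------------------------------------------------------------

def read_narrowpeak(path):
    """Read an ENCODE 10-column narrowPeak file.

    Column 10 is the summit offset from ``start``; it is converted to an
    absolute position. A ``-1`` offset (summit not called) is replaced by the
    interval midpoint with a warning.
    """
    peaks = []
    n_missing_summit = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 10:
                raise DataError(
                    f"{path}:{i}: narrowPeak needs 10 columns, got {len(parts)}"
                )
            chrom, start, end, name, score, _strand, fe, p, q, offset = parts
            start, end, offset = int(start), int(end), int(offset)
            if offset < 0:
                summit = (start + end) // 2
                n_missing_summit += 1
            else:
                summit = start + offset
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    summit=summit,
                    fold_enrichment=float(fe),
                    neg_log10_q=float(q),
                    neg_log10_p=float(p),
                    name=name,
                    score=int(score),
                )
            )
    if n_missing_summit:
        warnings.warn(
            f"{path}: {n_missing_summit} peaks without summit; used interval midpoints"
        )
    return peaks


def write_narrowpeak(peaks, path):
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        ".",
                        f"{p.fold_enrichment:.5f}",
                        f"{p.neg_log10_p:.5f}",
                        f"{p.neg_log10_q:.5f}",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Filtering and replicate matching
# ---------------------------------------------------------------------------

def filter_peaks(peaks, min_fold=2.0, max_q=1e-3):
    """Keep peaks with fold enrichment strictly > ``min_fold`` and q-value
    strictly < ``max_q``. A peak at exactly the threshold is excluded."""
    if min_fold < 0 or max_q <= 0:
        raise DataError("thresholds must be positive")
    min_nlq = -math.log10(max_q)
    return [
        p for p in peaks if p.fold_enrichment > min_fold and p.neg_log10_q > min_nlq
    ]


def _overlap_len(a: Peak, b: Peak) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def overlap_replicates(rep1, rep2):
    """Match peaks across two replicates into :class:`ReproduciblePeak` pairs.

    Candidate pairs are all cross-replicate peaks overlapping by >=1 bp.
    Matching is one-to-one and greedy over candidates sorted by summit
    distance, then larger overlap, then lexicographic peak names — so the
    result is independent of input order and symmetric in the two replicates
    (up to pair orientation).
    """
    trees = {}
    for j, p in enumerate(rep2):
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, j)
    candidates = []
    for i, a in enumerate(rep1):
        tree = trees.get(a.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(a.start, a.end):
            b = rep2[iv.data]
            candidates.append(
                (
                    abs(a.summit - b.summit),
                    -_overlap_len(a, b),
                    min(a.name, b.name),
                    max(a.name, b.name),
                    i,
                    iv.data,
                )
            )
    candidates.sort()
    used1, used2 = set(), set()
    pairs = []
    for _, _, _, _, i, j in candidates:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        pairs.append(ReproduciblePeak(rep1=rep1[i], rep2=rep2[j]))
    pairs.sort(key=lambda rp: (rp.chrom, rp.start, rp.name))
    return pairs


def assign_validation_levels(
    pairs, idr_values=None, d_vl2=200, d_vl3=100, idr_max=0.05
):
    """Assign VL1/VL2/VL3 to matched pairs.

    ``idr_values`` is a sequence of global IDRs aligned with ``pairs`` (e.g.
    ``IdrModelFit.global_idr``); if omitted, any existing per-pair ``idr`` is
    used and missing values are treated as passing (useful for noiseless
    synthetic data). Levels nest: VL3 implies the VL2 and VL1 criteria.
    """
    out = []
    for k, rp in enumerate(pairs):
        idr = idr_values[k] if idr_values is not None else rp.idr
        idr_ok = (idr <= idr_max) if not math.isnan(idr) else True
        if rp.summit_distance <= d_vl3 and idr_ok:
            level = "VL3"
        elif rp.summit_distance <= d_vl2 and idr_ok:
            level = "VL2"
        else:
            level = "VL1"
        out.append(replace(rp, idr=idr, level=level))
    return out


def peaks_at_level(pairs, level):
    """Cumulative view: pairs whose level is at least ``level``."""
    rank = LEVEL_RANK[level]
    return [p for p in pairs if LEVEL_RANK[p.level] >= rank]


# ---------------------------------------------------------------------------
# BED output for reproducible peaks
# ---------------------------------------------------------------------------

_BED_HEADER = "#chrom\tstart\tend\tname\tscore\tstrand\tlevel\tsummit_distance\tidr\tsummit"


def write_peaks_bed(pairs, path):
    """Write matched pairs as BED6+4 (level, summit distance, IDR, summit),
    0-based half-open coordinates spanning the merged interval."""
    with open(path, "w") as fh:
        fh.write(_BED_HEADER + "\n")
        for rp in pairs:
            idr = "NA" if math.isnan(rp.idr) else f"{rp.idr:.6f}"
            fh.write(
                f"{rp.chrom}\t{rp.start}\t{rp.end}\t{rp.name}\t0\t.\t"
                f"{rp.level}\t{rp.summit_distance}\t{idr}\t{rp.summit}\n"
            )


def read_peaks_bed(path):
    """Read the BED written by :func:`write_peaks_bed` into plain records."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, s, e, name, _score, _strand, level, sd, idr, summit = (
                line.rstrip("\n").split("\t")
            )
            rows.append(
                {
                    "chrom": c,
                    "start": int(s),
                    "end": int(e),
                    "name": name,
                    "level": level,
                    "summit_distance": int(sd),
                    "idr": math.nan if idr == "NA" else float(idr),
                    "summit": int(summit),
                }
            )
    return rows
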