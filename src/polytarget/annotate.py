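"""Peak annotation relative to gene models.

All positional logic runs on the reproducible-peak summit (midpoint of the
two replicate summits) and on strand-oriented signed distances to the TSS:
negative = upstream of the TSS in transcription direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .errors import DataError

__all__ = [
    "FeatureAssignment",
    "TssProfile",
    "CATEGORIES",
    "classify_feature",
    "classify_features",
    "tss_profile",
    "assign_target_genes",
]

# Fixed assignment priority: promoter tiers outrank genic features, UTRs
# outrank plain exon/intron, downstream outranks distal intergenic.
CATEGORIES = (
    "promoter_0_1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "five_prime_utr",
    "exon",
    "intron",
    "three_prime_utr",
    "downstream_0_3kb",
    "distal_intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class FeatureAssignment:
    peak_name: str
    category: str
    gene_id: str | None
    signed_tss_distance: int | None  # bp; negative = upstream


@dataclass(frozen=True)
class TssProfile:
    """Histogram of summit positions relative to the nearest TSS."""

    bin_edges: np.ndarray  # offsets, length n_bins + 1
    counts: np.ndarray

    @property
    def total_in_window(self) -> int:
        return int(self.counts.sum())


def _in_interval(pos, intervals):
    return any(a <= pos < b for a, b in intervals)


def _category_for_gene(summit, gene):
    """Candidate category of a summit w.r.t. one gene, or None."""
    d = gene.tss_distance(summit)
    if gene.start <= summit < gene.end:
        if _in_interval(summit, gene.utr5):
            return "five_prime_utr", d
        if _in_interval(summit, gene.utr3):
            return "three_prime_utr", d
        if _in_interval(summit, gene.exons):
            return "exon", d
        return "intron", d
    if -1000 <= d < 0:
        return "promoter_0_1kb", d
    if -2000 <= d < -1000:
        return "promoter_1_2kb", d
    if -3000 <= d < -2000:
        return "promoter_2_3kb", d
    # downstream of the gene 3' end, strand-oriented
    if gene.strand == "+":
        past = summit - (gene.end - 1)
    else:
        past = gene.start - summit
    if 0 < past <= 3000:
        return "downstream_0_3kb", d
    return None


def classify_feature(summit, genes_on_chrom, peak_name="."):
    """Classify a single summit against the genes of its chromosome.

    Among genes whose windows contain the summit the highest-priority
    category wins; within a category, the gene with the smaller |TSS
    distance| then lexicographic gene id.
    """
    best = None
    for g in genes_on_chrom:
        cat = _category_for_gene(summit, g)
        if cat is None:
            continue
        category, d = cat
        key = (_PRIORITY[category], abs(d), g.gene_id)
        if best is None or key < best[0]:
            best = (key, FeatureAssignment(peak_name, category, g.gene_id, d))
    if best is None:
        return FeatureAssignment(peak_name, "distal_intergenic", None, None)
    return best[1]


def classify_features(pairs, genes):
    """Vector version of :func:`classify_feature` over reproducible peaks.

    Returns one :class:`FeatureAssignment` per peak; the categories
    partition the peak set.
    """
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [
        classify_feature(rp.summit, by_chrom.get(rp.chrom, []), rp.name)
        for rp in pairs
    ]


def tss_profile(pairs, genes, half_window=3000, bin_size=50) -> TssProfile:
    """Histogram of summit-to-nearest-TSS signed distances in
    ``[-half_window, +half_window)``.

    Each peak contributes to the bin of its summit's strand-oriented
    distance to the nearest TSS; ties between equidistant TSSs resolve
    toward the upstream gene (negative distance), then lexicographic gene
    id. Peaks with no TSS inside the window are excluded from the total.
    """
    if bin_size <= 0:
        raise DataError("bin size must be positive")
    if (2 * half_window) % bin_size:
        raise DataError("bin size must divide the window span")
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    edges = np.arange(-half_window, half_window + bin_size, bin_size)
    counts = np.zeros(edges.size - 1, dtype=int)
    for rp in pairs:
        best = None
        for g in by_chrom.get(rp.chrom, []):
            d = g.tss_distance(rp.summit)
            if not (-half_window <= d < half_window):
                continue
            # upstream (negative d) wins ties at equal |d|
            key = (abs(d), 0 if d < 0 else 1, g.gene_id)
            if best is None or key < best[0]:
                best = (key, d)
        if best is not None:
            counts[(best[1] + half_window) // bin_size] += 1
    return TssProfile(bin_edges=edges, counts=counts)


def promoter_window(gene, up=2000, down=100):
    """Half-open genomic interval of the strand-oriented promoter window
    (``up`` bp upstream of the TSS to ``down`` bp downstream, inclusive of
    both endpoints in signed-distance terms)."""
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down + 1
    return gene.tss - down, gene.tss + up + 1


def assign_target_genes(pairs, genes, up=2000, down=100, by="summit"):
    """Map genes to the reproducible peaks in their promoter windows.

    A gene is a candidate target iff at least one peak falls within
    ``[-up, +down]`` of its TSS in transcription direction. By default
    containment is tested at the peak summit; ``by='interval'`` accepts any
    overlap of the merged peak interval with the window. One peak may
    support several genes (divergent promoters).

    Returns ``{gene_id: [ReproduciblePeak, ...]}`` (only genes with >=1
    peak).
    """
    if by not in ("summit", "interval"):
        raise DataError(f"unknown containment mode: {by!r}")
    trees = {}
    for g in genes:
        a, b = promoter_window(g, up, down)
        trees.setdefault(g.chrom, IntervalTree()).addi(max(a, 0), max(b, 1), g.gene_id)
    out = {}
    for rp in pairs:
        tree = trees.get(rp.chrom)
        if tree is None:
            continue
        if by == "summit":
            hits = tree.at(rp.summit)
        else:
            hits = tree.overlap(rp.start, rp.end)
        for iv in hits:
            out.setdefault(iv.data, []).append(rp)
    for v in out.values():
        v.sort(key=lambda rp: (rp.chrom, rp.start, rp.name))
    return out


def feature_distribution(assignments):
    """Category -> count summary of :func:`classify_features` output."""
    dist = {c: 0 for c in CATEGORIES}
    for a in assignments:
        dist[a.category] += 1
    return dist
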