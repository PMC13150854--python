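"""Polyploid genome layout, gene models and homoeolog relationships.

The genome is modelled as a set of chromosomes, each carrying a subgenome
label (one of the diploid ancestors of an allopolyploid) and a homoeologous
group index (chromosomes descending from the same ancestral chromosome, one
per subgenome). Gene models are read from GFF3.

Coordinate convention: everything held in memory is 0-based, half-open
``[start, end)``. GFF3 (1-based, inclusive) and BED/narrowPeak (0-based,
half-open) are converted at the I/O boundary, never inside the library.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import gffutils
import yaml

from .errors import DataError

__all__ = [
    "Chromosome",
    "GenomeLayout",
    "GeneModel",
    "HomoeologMap",
    "read_layout",
    "write_layout",
    "read_gff3",
    "write_gff3",
    "read_homoeolog_map",
    "write_homoeolog_map",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int  # bp
    subgenome: str
    group: int  # homoeologous chromosome group, 1..G


class GenomeLayout:
    """Chromosome complement of the genome.

    Parameters
    ----------
    chromosomes
        Iterable of :class:`Chromosome`. Names must be unique and lengths
        positive; each chromosome carries exactly one subgenome label and one
        group index (enforced by construction).
    """

    def __init__(self, chromosomes):
        chromosomes = list(chromosomes)
        names = [c.name for c in chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataError(f"duplicate chromosome names: {dupes}")
        for c in chromosomes:
            if c.length <= 0:
                raise DataError(f"chromosome {c.name} has non-positive length {c.length}")
        self.chromosomes = chromosomes
        self._by_name = {c.name: c for c in chromosomes}

    def __contains__(self, name):
        return name in self._by_name

    def __getitem__(self, name) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise DataError(f"unknown chromosome: {name!r}") from None

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)

    @property
    def groups(self):
        return sorted({c.group for c in self.chromosomes})

    @property
    def subgenomes(self):
        seen = []
        for c in self.chromosomes:
            if c.subgenome not in seen:
                seen.append(c.subgenome)
        return seen

    def group_chromosomes(self, group):
        return [c for c in self.chromosomes if c.group == group]

    def group_length(self, group):
        """Total size of a homoeologous chromosome set, in bp."""
        total = sum(c.length for c in self.group_chromosomes(group))
        if total == 0:
            raise DataError(f"group {group} has no chromosomes")
        return total


@dataclass(frozen=True)
class GeneModel:
    """One gene: 0-based half-open coordinates, strand, and sub-features.

    ``exons``, ``utr5`` and ``utr3`` are lists of ``(start, end)`` half-open
    intervals. The TSS is the strand-dependent first transcribed base.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str  # '+' or '-'
    subgenome: str = ""
    exons: tuple = field(default_factory=tuple)
    utr5: tuple = field(default_factory=tuple)
    utr3: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise DataError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    def tss_distance(self, pos: int) -> int:
        """Signed, strand-oriented distance from the TSS to ``pos``.

        Negative values are upstream of the TSS in transcription direction.
        """
        return pos - self.tss if self.strand == "+" else self.tss - pos


class HomoeologMap:
    """Mapping octoploid gene id -> homoeolog group id (diploid reference gene).

    The map may be partial; genes absent from it are reported as unmapped by
    downstream consumers rather than dropped.
    """

    def __init__(self, pairs: dict):
        self.pairs = dict(pairs)

    def __len__(self):
        return len(self.pairs)

    def __contains__(self, gene_id):
        return gene_id in self.pairs

    def get(self, gene_id, default=None):
        return self.pairs.get(gene_id, default)

    @property
    def groups(self):
        return set(self.pairs.values())

    def unmapped(self, gene_ids):
        return sorted(g for g in gene_ids if g not in self.pairs)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_layout(path) -> GenomeLayout:
    """Read a genome layout from TSV (name, length, subgenome, group) or YAML."""
    if str(path).endswith((".yaml", ".yml")):
        with open(path) as fh:
            entries = yaml.safe_load(fh)["chromosomes"]
        return GenomeLayout(
            Chromosome(e["name"], int(e["length"]), str(e["subgenome"]), int(e["group"]))
            for e in entries
        )
    chroms = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise DataError(f"{path}:{i}: expected 4 columns, got {len(parts)}")
            name, length, subg, group = parts
            chroms.append(Chromosome(name, int(length), subg, int(group)))
    return GenomeLayout(chroms)


def write_layout(layout: GenomeLayout, path):
    with open(path, "w") as fh:
        fh.write("#name\tlength\tsubgenome\tgroup\n")
        for c in layout:
            fh.write(f"{c.name}\t{c.length}\t{c.subgenome}\t{c.group}\n")


def _prevalidate_gff3(path):
    """Record-level validation with line numbers before structured parsing."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}:{i}: expected 9 GFF3 columns, got {len(parts)}")
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise DataError(f"{path}:{i}: non-integer coordinates") from None
            if start > end:
                raise DataError(f"{path}:{i}: start {start} > end {end}")
            if parts[2] == "gene" and parts[6] not in "+-":
                raise DataError(f"{path}:{i}: unknown strand {parts[6]!r} on gene feature")


def read_gff3(path, layout: GenomeLayout | None = None, on_unknown_chrom="error"):
    """Parse gene models from a GFF3 file.

    One :class:`GeneModel` per ``gene`` feature; exon and UTR sub-features are
    attached by traversing feature children. GFF3 1-based inclusive
    coordinates are converted to 0-based half-open.

    Parameters
    ----------
    layout
        Optional :class:`GenomeLayout`; genes on chromosomes absent from it
        are rejected (``on_unknown_chrom='error'``) or dropped with a warning
        (``'warn'``). Subgenome labels are taken from the layout.
    """
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path), ":memory:", keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if layout is not None and feat.seqid not in layout:
            if on_unknown_chrom == "warn":
                warnings.warn(
                    f"gene {gene_id} on unknown chromosome {feat.seqid}; dropped"
                )
                continue
            raise DataError(f"gene {gene_id} on unknown chromosome {feat.seqid}")

        def _sub(ftype):
            ivs = sorted(
                (c.start - 1, c.end) for c in db.children(feat, featuretype=ftype)
            )
            return tuple(ivs)

        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                subgenome=layout[feat.seqid].subgenome if layout is not None else "",
                exons=_sub("exon"),
                utr5=_sub("five_prime_UTR"),
                utr3=_sub("three_prime_UTR"),
            )
        )
    return genes


def write_gff3(genes, path, source="polytarget"):
    """Serialize gene models (with a single mRNA carrying sub-features) to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            s, e = g.start + 1, g.end
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for n, (ftype, ivs) in enumerate(
                [("exon", g.exons), ("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)]
            ):
                for k, (a, b) in enumerate(ivs, 1):
                    fh.write(
                        f"{g.chrom}\t{source}\t{ftype}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"ID={mrna}.{ftype}{k};Parent={mrna}\n"
                    )


def read_homoeolog_map(path) -> HomoeologMap:
    """Read a two-column TSV ``gene_id<TAB>group_id``.

    Duplicate gene ids mapping to conflicting groups raise a
    :class:`DataError` listing the offenders; consistent duplicates collapse.
    An empty file yields an empty map with a warning.
    """
    pairs = {}
    conflicts = []
    n_rows = 0
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise DataError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
            gene, group = parts
            n_rows += 1
            if gene in pairs and pairs[gene] != group:
                conflicts.append((gene, pairs[gene], group))
            pairs[gene] = group
    if conflicts:
        listing = "; ".join(f"{g}: {a} vs {b}" for g, a, b in conflicts)
        raise DataError(f"conflicting homoeolog assignments: {listing}")
    if n_rows == 0:
        warnings.warn(f"homoeolog map {path} is empty")
    return HomoeologMap(pairs)


def write_homoeolog_map(hmap: HomoeologMap, path):
    with open(path, "w") as fh:
        for gene in sorted(hmap.pairs):
            fh.write(f"{gene}\t{hmap.pairs[gene]}\n")


def _checked_path(path, what):
    if not os.path.exists(path):
        from .errors import ConfigError

        raise ConfigError(f"missing {what}: {path}")
    return path
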