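"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates an allo-octoploid genome — four subgenome labels
(one per diploid ancestor) times seven homoeologous chromosome groups, 28
chromosomes — with genes in complete homoeolog quartets, replicate ChIP
peak sets with planted reproducible peaks in promoter windows plus
irreproducible per-replicate noise, a differential-expression table with
planted direct/indirect targets, and a bait/control proximity-labeling
presence matrix with planted interactors.

Scale is reduced relative to a real octoploid (hundreds of genes per
chromosome group rather than thousands) while the structural ratios the
analysis cares about — the direct:indirect target ratio, the down:up
split, nested validation levels — are preserved.

All randomness flows from a single seed through named substreams, so
changing one stage's parameters does not perturb another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .genome import (
    Chromosome,
    GeneModel,
    GenomeLayout,
    HomoeologMap,
    write_gff3,
    write_homoeolog_map,
    write_layout,
)
from .peaks import Peak, write_narrowpeak

__all__ = [
    "SimulationConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_chip_replicates",
    "simulate_deg_table",
    "simulate_proteomics",
]

_STREAMS = {"genome": 0, "chip": 1, "deg": 2, "proteomics": 3}


def _rng(seed, stream):
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator, with the emulated study's conditions as
    defaults.

    Genome: 7 homoeologous groups x 4 subgenomes, 100 genes per chromosome
    on a fixed 6 kb spacing (2 kb gene bodies), so promoter windows of
    neighbouring genes never collide and planted assignments are
    unambiguous. Peaks: 150 planted reproducible peaks placed 1.5 kb
    upstream to 50 bp downstream of target TSSs with per-replicate summit
    jitter (sd 30 bp); irreproducible noise peaks added per replicate at
    30% of the planted count. DEGs: every planted-peak gene plus 830
    unbound genes are differentially expressed (direct:selected ratio
    150/980 ≈ 15%), 61% of effects downregulated, |log2FC| >= 1 guaranteed
    for the planted core, FDR <= 0.05 in both lines and both stages.
    Proteomics: 20 planted bait-exclusive interactor groups over a 60-group
    two-condition background, 3 replicates per condition.
    """

    seed: int = 0
    # genome
    n_groups: int = 7
    subgenomes: tuple = ("Fvb", "Fin", "Fnp", "Fvr")
    chrom_length: int = 600_000
    genes_per_chrom: int = 100
    gene_length: int = 2000
    # ChIP
    n_planted_peaks: int = 150
    summit_jitter_sd: float = 30.0
    peak_halfwidth: int = 150
    fold_excess_logmean: float = 0.5
    fold_excess_logsd: float = 0.6
    irreproducible_peak_rate: float = 0.3
    subgenome_bias_multiplier: tuple = (1.0, 1.0, 1.0, 1.0)
    # DEG
    lines: tuple = ("RNAi3", "RNAi11")
    stages: tuple = ("white", "red")
    n_planted_indirect: int = 830
    planted_direct_fraction: float = 1.0
    deg_effect_mean: float = 2.0
    deg_effect_sd: float = 0.5
    down_fraction: float = 0.61
    null_log2fc_sd: float = 0.2
    # proteomics
    n_background_groups: int = 60
    n_planted_interactors: int = 20
    n_bait_reps: int = 3
    n_control_reps: int = 3
    dropout_rate: float = 0.0

    def __post_init__(self):
        for name in ("irreproducible_peak_rate", "planted_direct_fraction",
                     "down_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if len(self.subgenome_bias_multiplier) != len(self.subgenomes):
            raise ConfigError("one bias multiplier per subgenome required")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("subgenomes", "subgenome_bias_multiplier", "lines", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimulatedGenome:
    layout: GenomeLayout
    genes: list
    hmap: HomoeologMap
    paths: dict = field(default_factory=dict)


def simulate_genome(config: SimulationConfig, outdir=None) -> SimulatedGenome:
    """Build the polyploid genome: layout, gene models and homoeolog map.

    Genes sit on a fixed slot grid (one gene per ``chrom_length /
    genes_per_chrom`` bp) with random strand; the gene at slot *i* of group
    *g* exists on all four subgenomes and shares homoeolog group
    ``HG<g>_<i>`` — quartets are complete by construction. If ``outdir`` is
    given, GFF3 / layout TSV / homoeolog TSV files are written there.
    """
    rng = _rng(config.seed, "genome")
    chroms, genes, pairs = [], [], {}
    slot = config.chrom_length // config.genes_per_chrom
    # 3 kb leading margin per slot keeps neighbouring promoter windows and
    # planted-peak placements provably disjoint
    if slot < config.gene_length + 4000:
        raise ConfigError("gene slots too small for gene bodies plus promoters")
    for g in range(1, config.n_groups + 1):
        # strands drawn once per group so homoeologs are syntenic
        strands = rng.choice(["+", "-"], size=config.genes_per_chrom)
        for s in config.subgenomes:
            name = f"chr{g}{s}"
            chroms.append(Chromosome(name, config.chrom_length, s, g))
            for i in range(config.genes_per_chrom):
                start = int(i * slot + 3000)
                end = start + config.gene_length
                gid = f"Fx{g:02d}{s}_{i:03d}"
                strand = strands[i]
                L = config.gene_length
                exons = ((start, start + int(L * 0.4)), (start + int(L * 0.6), end))
                if strand == "+":
                    utr5 = ((start, start + 150),)
                    utr3 = ((end - 150, end),)
                else:
                    utr5 = ((end - 150, end),)
                    utr3 = ((start, start + 150),)
                genes.append(
                    GeneModel(
                        gene_id=gid, chrom=name, start=start, end=end,
                        strand=strand, subgenome=s,
                        exons=exons, utr5=utr5, utr3=utr3,
                    )
                )
                pairs[gid] = f"HG{g:02d}_{i:03d}"
    layout = GenomeLayout(chroms)
    hmap = HomoeologMap(pairs)
    sim = SimulatedGenome(layout=layout, genes=genes, hmap=hmap)
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        sim.paths = {
            "gff3": os.path.join(outdir, "genome.gff3"),
            "layout": os.path.join(outdir, "layout.tsv"),
            "homoeolog_map": os.path.join(outdir, "homoeologs.tsv"),
        }
        write_gff3(genes, sim.paths["gff3"])
        write_layout(layout, sim.paths["layout"])
        write_homoeolog_map(hmap, sim.paths["homoeolog_map"])
    return sim


def _planted_positions(config, genome, rng):
    """Choose distinct target genes (subgenome-weighted) and true summits in
    their promoter windows (−1500..+50 of the TSS, transcription-oriented)."""
    mult = dict(zip(config.subgenomes, config.subgenome_bias_multiplier))
    weights = np.array([mult[g.subgenome] for g in genome.genes], dtype=float)
    if config.n_planted_peaks > len(genome.genes):
        raise ConfigError("more planted peaks than genes")
    idx = rng.choice(
        len(genome.genes),
        size=config.n_planted_peaks,
        replace=False,
        p=weights / weights.sum(),
    )
    rows = []
    for k, gi in enumerate(sorted(idx)):
        gene = genome.genes[gi]
        offset = int(rng.integers(-1500, 51))
        if gene.strand == "+":
            summit = gene.tss + offset
        else:
            summit = gene.tss - offset
        summit = int(np.clip(summit, config.peak_halfwidth + 1,
                             config.chrom_length - config.peak_halfwidth - 2))
        rows.append({"peak_idx": k, "gene_id": gene.gene_id,
                     "chrom": gene.chrom, "true_summit": summit})
    return pd.DataFrame(rows)


def _make_peak(chrom, summit, fold, nlq, name, halfwidth, chrom_len):
    start = max(0, summit - halfwidth)
    end = min(chrom_len, summit + halfwidth + 1)
    return Peak(chrom=chrom, start=start, end=end, summit=summit,
                fold_enrichment=fold, neg_log10_q=nlq, name=name)


def simulate_chip_replicates(config: SimulationConfig, genome: SimulatedGenome,
                             outdir=None):
    """Generate two replicate peak sets.

    Planted peaks share a per-peak enrichment level across replicates (so
    replicate scores are rank-correlated) and get independent per-replicate
    summit jitter ~ Normal(0, ``summit_jitter_sd``). Noise peaks are drawn
    independently per replicate at ``irreproducible_peak_rate`` x the
    planted count, uniformly over the genome; they pass the per-replicate
    enrichment filter but have no cross-replicate partner. The per-subgenome
    placement multiplier plants genome-wide binding bias.

    Returns ``(rep1, rep2, truth)`` where ``truth`` is a DataFrame of the
    planted peaks; files are written to ``outdir`` if given.
    """
    rng = _rng(config.seed, "chip")
    truth = _planted_positions(config, genome, rng)
    n = len(truth)
    base_excess = rng.lognormal(config.fold_excess_logmean,
                                config.fold_excess_logsd, size=n)
    reps = ([], [])
    for r in (0, 1):
        for k, row in truth.iterrows():
            jitter = rng.normal(0.0, config.summit_jitter_sd) if config.summit_jitter_sd > 0 else 0.0
            summit = int(np.clip(row.true_summit + round(jitter), 1,
                                 config.chrom_length - 2))
            fold = 2.0 + base_excess[k] * float(np.exp(rng.normal(0.0, 0.2)))
            nlq = 3.0 + 3.0 * base_excess[k] + abs(float(rng.normal(0.0, 1.0)))
            reps[r].append(
                _make_peak(row.chrom, summit, fold, nlq,
                           f"rep{r + 1}_planted{k:05d}",
                           config.peak_halfwidth, config.chrom_length)
            )
        n_noise = int(round(config.irreproducible_peak_rate * n))
        chrom_names = [c.name for c in genome.layout]
        for k in range(n_noise):
            chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
            summit = int(rng.integers(config.peak_halfwidth + 1,
                                      config.chrom_length - config.peak_halfwidth - 1))
            excess = rng.lognormal(config.fold_excess_logmean,
                                   config.fold_excess_logsd)
            fold = 2.0 + float(excess)
            nlq = 3.0 + 3.0 * float(excess)
            reps[r].append(
                _make_peak(chrom, summit, fold, nlq, f"rep{r + 1}_noise{k:05d}",
                           config.peak_halfwidth, config.chrom_length)
            )
    rep1 = sorted(reps[0], key=lambda p: (p.chrom, p.start, p.name))
    rep2 = sorted(reps[1], key=lambda p: (p.chrom, p.start, p.name))
    if outdir is not None:
        import os

        os.makedirs(outdir, exist_ok=True)
        p1 = os.path.join(outdir, "rep1.narrowPeak")
        p2 = os.path.join(outdir, "rep2.narrowPeak")
        write_narrowpeak(rep1, p1)
        write_narrowpeak(rep2, p2)
        truth.to_csv(os.path.join(outdir, "planted_peaks.tsv"), sep="\t", index=False)
        genome.paths.update({"rep1": p1, "rep2": p2})
    return rep1, rep2, truth


def simulate_deg_table(config: SimulationConfig, genome: SimulatedGenome,
                       planted_target_genes, outpath=None):
    """Generate the per-contrast differential-expression table.

    ``planted_target_genes`` (usually the genes of the planted peaks) become
    the direct targets: a ``planted_direct_fraction`` core gets |log2FC| >= 1
    and FDR <= 0.05 in every line and stage. ``n_planted_indirect`` unbound
    genes get the same treatment (the indirect targets). All other genes are
    nulls: log2FC ~ Normal(0, ``null_log2fc_sd``), FDR ~ Uniform(0, 1).

    Returns ``(deg DataFrame, truth DataFrame)`` with truth columns
    gene_id, role (direct/indirect), direction.
    """
    rng = _rng(config.seed, "deg")
    planted = sorted(set(planted_target_genes))
    n_core = int(round(config.planted_direct_fraction * len(planted)))
    core = list(rng.choice(planted, size=n_core, replace=False)) if planted else []
    unbound = sorted(set(g.gene_id for g in genome.genes) - set(planted))
    if config.n_planted_indirect > len(unbound):
        raise ConfigError("not enough unbound genes for planted indirect targets")
    indirect = list(rng.choice(unbound, size=config.n_planted_indirect,
                               replace=False))

    truth_rows, deg_rows = [], []

    def _planted_rows(gene, role):
        sign = -1.0 if rng.random() < config.down_fraction else 1.0
        m = 1.0 + abs(rng.normal(config.deg_effect_mean - 1.0,
                                 config.deg_effect_sd))
        truth_rows.append({"gene_id": gene, "role": role,
                           "direction": "down" if sign < 0 else "up"})
        for line in config.lines:
            for stage in config.stages:
                lfc = sign * max(1.0, m + rng.normal(0.0, 0.1))
                fdr = rng.uniform(1e-6, 0.05)
                deg_rows.append((gene, line, stage, lfc, fdr))

    for gene in sorted(core):
        _planted_rows(gene, "direct")
    for gene in sorted(indirect):
        _planted_rows(gene, "indirect")
    planted_set = set(core) | set(indirect)
    for gene in sorted(set(g.gene_id for g in genome.genes) - planted_set):
        for line in config.lines:
            for stage in config.stages:
                deg_rows.append(
                    (gene, line, stage,
                     float(rng.normal(0.0, config.null_log2fc_sd)),
                     float(rng.uniform(0.0, 1.0)))
                )
    deg = pd.DataFrame(deg_rows, columns=["gene_id", "line", "stage",
                                          "log2fc", "fdr"])
    deg = deg.sort_values(["gene_id", "line", "stage"], kind="stable").reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    if outpath is not None:
        deg.to_csv(outpath, sep="\t", index=False, float_format="%.6g")
    return deg, truth


def simulate_proteomics(config: SimulationConfig, outpath=None):
    """Generate the protein-group evidence matrix.

    Planted interactors are present in every bait replicate (each presence
    independently flipped absent with ``dropout_rate``) and absent from all
    controls; background groups are present in the controls (and usually in
    the baits too), so the exclusivity filter removes them.

    Returns ``(evidence DataFrame, planted group ids)``.
    """
    rng = _rng(config.seed, "proteomics")
    rows = []
    planted_ids = []
    bait_cols = [f"bait_{r + 1}" for r in range(config.n_bait_reps)]
    ctrl_cols = [f"control_{r + 1}" for r in range(config.n_control_reps)]

    def _members(gid, lo=1, hi=8):
        k = int(rng.integers(lo, hi + 1))
        return ";".join(f"{gid}p{j}" for j in range(k))

    def _peptides(gid, lo=5, hi=40):
        k = int(rng.integers(lo, hi + 1))
        return ";".join(f"{gid}pep{j}" for j in range(k))

    for i in range(config.n_planted_interactors):
        gid = f"PG_bait{i:03d}"
        planted_ids.append(gid)
        row = {"group_id": gid, "member_proteins": _members(gid),
               "peptide_ids": _peptides(gid)}
        for c in bait_cols:
            row[c] = 0 if rng.random() < config.dropout_rate else 1
        for c in ctrl_cols:
            row[c] = 0
        rows.append(row)
    for i in range(config.n_background_groups):
        gid = f"PG_bg{i:03d}"
        row = {"group_id": gid, "member_proteins": _members(gid),
               "peptide_ids": _peptides(gid)}
        in_bait = rng.random() < 0.7
        for c in bait_cols:
            row[c] = int(in_bait and rng.random() < 0.9)
        # background groups are detectable in at least one control
        present_ctrl = rng.random(config.n_control_reps) < 0.8
        if not present_ctrl.any():
            present_ctrl[int(rng.integers(0, config.n_control_reps))] = True
        for c, pc in zip(ctrl_cols, present_ctrl):
            row[c] = int(pc)
        rows.append(row)
    evidence = pd.DataFrame(rows)
    if outpath is not None:
        evidence.to_csv(outpath, sep="\t", index=False)
    return evidence, planted_ids
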