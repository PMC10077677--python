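"""Paired two-species synthetic datasets with planted ground truth.

The generator emulates the statistical structure of the real study inputs
so that every pipeline stage can be exercised without downloads: two
i.i.d.-background genomes with genes and an orthology map; enhancers
planted at controlled distances from TSSs with controlled AP-1/ETS motif
content; orthologous enhancer copies at controlled per-base divergence with
optional motif ablation (which is what makes an IRE species-specific);
replicated negative-binomial ChIP counts with planted injury fold changes;
bulk RNA counts with planted induction of IRE-linked genes; and an scRNA
matrix whose induction is concentrated in each gene's true cell type.

Everything planted is recorded in :class:`SimTruth`, and all outputs are
reproducible byte-for-byte under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .chip import RegionCountTable
from .expression import CANONICAL_CELL_TYPES
from .genome import Genome
from .intervals import GeneModel, GenomicInterval, nearest_feature
from .io import write_bed, write_gtf_genes, write_ortholog_table
from .motifs import AP1, ETS, IUPAC, scan_motif

__all__ = [
    "SimConfig",
    "EnhancerTruth",
    "GeneTruth",
    "SimTruth",
    "simulate_genome_pair",
    "simulate_chip_counts",
    "simulate_rna_counts",
    "simulate_sc_counts",
    "simulate_count_table",
    "simulate_expression_table",
    "simulate_sc_benchmark",
    "write_sc_mtx",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Knobs of the paired-genome simulation; defaults are sized so that a
    full pair generates in well under a minute."""

    seed: int
    species: tuple[str, str] = ("zebrafish", "mouse")
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    gc: float = 0.42
    n_genes: int = 200
    n_enhancers: int = 300
    ire_fraction: float = 0.3
    enhancer_length: tuple[int, int] = (500, 1500)
    tss_distance: tuple[int, int] = (4_000, 50_000)
    ap1_per_ire: int = 1
    ets_per_ire: int = 3
    ap1_per_nonire: int = 0
    ets_per_nonire: int = 1
    injury_fc_range: tuple[float, float] = (3.0, 6.0)
    nb_dispersion: float = 0.1
    replicates: int = 2
    base_region_mean: float = 50.0
    library_size: int = 1_000_000
    ortholog_fraction: float = 0.6
    divergence: float = 0.1
    motif_ablation_prob: float = 0.5
    rna_mean_log: float = 4.0
    rna_sd_log: float = 1.0
    rna_induced_fc: float = 3.0
    sc_n_genes: int = 50
    sc_n_cell_types: int = 5
    sc_cells_per_type: int = 40
    sc_baseline_mean: float = 2.0
    sc_induced_fc: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for frac in (self.gc, self.ire_fraction, self.ortholog_fraction,
                     self.divergence, self.motif_ablation_prob):
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.chrom_length <= 0 or self.n_chromosomes <= 0:
            raise ValueError("lengths must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("species", "enhancer_length", "tss_distance", "injury_fc_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("species", "enhancer_length", "tss_distance", "injury_fc_range"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class EnhancerTruth:
    """Everything planted about one enhancer (native or orthologous copy)."""

    species: str
    interval: GenomicInterval
    is_ire: bool
    fold_change: float
    linked_gene: str
    ap1_planted: int
    ets_planted: int
    motif_offsets: list[tuple[int, int, str]] = field(default_factory=list)
    # (offset, length, family) relative to interval.start
    ap1_count: int = 0  # scanner recount on the emitted genome
    ets_count: int = 0
    origin: str = "native"  # or "ortholog-copy"
    partner: Optional[GenomicInterval] = None
    partner_species: Optional[str] = None
    divergence: float = 0.0
    ablated: bool = False
    cross_class: Optional[str] = None  # shared | species-specific | unmapped


@dataclass
class GeneTruth:
    species: str
    gene: GeneModel
    transcript_length: int
    induced: bool = False
    fold_change: float = 1.0
    cell_type: Optional[str] = None


@dataclass
class SimTruth:
    config: SimConfig
    genomes: dict[str, Genome]
    genes: dict[str, list[GeneModel]]
    gene_truth: dict[str, dict[str, GeneTruth]]  # species -> gene_id -> truth
    enhancers: list[EnhancerTruth]
    ortholog_table: pd.DataFrame

    def species_enhancers(self, species: str) -> list[EnhancerTruth]:
        return [e for e in self.enhancers if e.species == species]

    def ires(self, species: str) -> list[EnhancerTruth]:
        return [e for e in self.species_enhancers(species) if e.is_ire]

    def enhancer_table(self) -> pd.DataFrame:
        rows = []
        for e in self.enhancers:
            rows.append(
                {
                    "species": e.species,
                    "name": e.interval.name,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "is_ire": e.is_ire,
                    "fold_change": e.fold_change,
                    "linked_gene": e.linked_gene,
                    "ap1_planted": e.ap1_planted,
                    "ets_planted": e.ets_planted,
                    "ap1_count": e.ap1_count,
                    "ets_count": e.ets_count,
                    "origin": e.origin,
                    "ablated": e.ablated,
                    "cross_class": e.cross_class or "",
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Emit FASTA/GTF/BED/TSV files for both species plus the truth."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in self.config.species:
            self.genomes[sp].to_fasta(out / f"{sp}.fa")
            write_gtf_genes(self.genes[sp], out / f"{sp}.gtf")
            enh = self.species_enhancers(sp)
            write_bed([e.interval for e in enh], out / f"{sp}_enhancers.bed")
            write_bed([e.interval for e in enh if e.is_ire], out / f"{sp}_ires.bed")
            write_bed(
                [e.interval for e in enh if not e.is_ire],
                out / f"{sp}_non_ires.bed",
            )
        write_ortholog_table(self.ortholog_table, out / "orthologs.tsv")
        self.enhancer_table().to_csv(out / "enhancer_truth.tsv", sep="\t", index=False)
        self.config.to_yaml(out / "sim_config.yaml")


def _random_genome(rng, config: SimConfig) -> dict[str, np.ndarray]:
    p = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    return {
        f"chr{i + 1}": _BASES[
            rng.choice(4, size=config.chrom_length, p=p)
        ].copy()
        for i in range(config.n_chromosomes)
    }


def _place_genes(rng, config: SimConfig, species: str) -> list[GeneModel]:
    genes = []
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    idx = 0
    for c, count in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        slot = config.chrom_length / (count + 1)
        for i in range(count):
            jitter = int(rng.integers(-int(slot // 5), int(slot // 5) + 1))
            tss = int((i + 1) * slot) + jitter
            tss = min(max(tss, 1000), config.chrom_length - 1000)
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"{species}_g{idx:04d}", chrom, strand, tss))
            idx += 1
    return genes


class _Occupancy:
    """Per-chromosome blocked intervals (promoter zones, placed enhancers)."""

    def __init__(self) -> None:
        self._blocks: dict[str, list[tuple[int, int]]] = {}

    def block(self, chrom: str, start: int, end: int) -> None:
        self._blocks.setdefault(chrom, []).append((start, end))

    def free(self, chrom: str, start: int, end: int) -> bool:
        for b0, b1 in self._blocks.get(chrom, []):
            if start < b1 and b0 < end:
                return False
        return True


def _place_near_tss(
    rng, config: SimConfig, gene: GeneModel, length: int, occ: _Occupancy
) -> Optional[GenomicInterval]:
    lo, hi = config.tss_distance
    for _ in range(200):
        side = -1 if rng.random() < 0.5 else 1
        dist = int(rng.integers(lo, hi + 1))
        center = gene.tss + side * dist
        start = center - length // 2
        end = start + length
        if start < 0 or end > config.chrom_length:
            continue
        if occ.free(gene.chrom, start - 10, end + 10):
            occ.block(gene.chrom, start, end)
            return GenomicInterval(gene.chrom, start, end)
    return None


def _realize_iupac(rng, code: str) -> bytes:
    out = bytearray()
    for letter in code:
        options = IUPAC[letter].replace("N", "") or "ACGT"
        out.append(ord(options[int(rng.integers(len(options)))]))
    return bytes(out)


def _plant_motifs(
    rng, seq: np.ndarray, start: int, end: int, n_ap1: int, n_ets: int
) -> list[tuple[int, int, str]]:
    """Write concrete AP-1/ETS realizations at non-overlapping offsets inside
    seq[start:end]; returns (offset, length, family) relative to start."""
    placed: list[tuple[int, int, str]] = []
    plan = [("AP-1", AP1.iupac)] * n_ap1 + [("ETS", ETS.iupac)] * n_ets
    for family, code in plan:
        length = len(code)
        for _ in range(100):
            off = int(rng.integers(0, end - start - length + 1))
            if all(
                off + length <= o or off >= o + l for o, l, _f in placed
            ):
                word = _realize_iupac(rng, code)
                seq[start + off : start + off + length] = np.frombuffer(
                    word, dtype=np.uint8
                )
                placed.append((off, length, family))
                break
        else:
            raise ValueError("infeasible motif placement: enhancer too crowded")
    return placed


def _diverge(rng, seq: np.ndarray, d: float) -> np.ndarray:
    """Per-base substitution at probability d (always to a different base)."""
    out = seq.copy()
    if d <= 0:
        return out
    hit = np.flatnonzero(rng.random(out.size) < d)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return out


def _ablate_motifs(
    rng, seq: np.ndarray, offsets: Sequence[tuple[int, int, str]]
) -> None:
    """Scramble each planted motif window until its family consensus no
    longer matches anywhere nearby; models the motif-frequency loss of
    non-responsive orthologous sequences without claiming its mechanism."""
    patterns = {"AP-1": AP1, "ETS": ETS}
    for off, length, family in offsets:
        pat = patterns[family]
        ctx0 = max(0, off - len(pat) + 1)
        ctx1 = min(seq.size, off + length + len(pat) - 1)
        window = seq[off : off + length]
        done = False
        for _ in range(30):
            rng.shuffle(window)
            ctx = seq[ctx0:ctx1].tobytes().decode()
            if scan_motif(ctx, pat, "both_dedup").count == 0:
                done = True
                break
        if not done:
            # poly-A cannot match either family consensus (both require
            # non-A positions); mirrors the experimental motif mutation
            seq[off : off + length] = ord("A")


def _rng(config: SimConfig, stage: int, extra: int = 0):
    return np.random.default_rng([config.seed % (2**31), stage, extra])


def simulate_genome_pair(config: SimConfig) -> SimTruth:
    """Build both genomes with genes, planted enhancers, orthologous copies
    and the complete ground-truth bookkeeping."""
    sp_a, sp_b = config.species
    genomes_arr: dict[str, dict[str, np.ndarray]] = {}
    genes: dict[str, list[GeneModel]] = {}
    occ: dict[str, _Occupancy] = {}
    enhancers: list[EnhancerTruth] = []

    for k, sp in enumerate(config.species):
        rng = _rng(config, 1, k)
        genomes_arr[sp] = _random_genome(rng, config)
        genes[sp] = _place_genes(rng, config, sp)
        occ[sp] = _Occupancy()
        for g in genes[sp]:
            occ[sp].block(g.chrom, g.tss - 2100, g.tss + 2100)

    # orthology map: pair the first fraction of each species' genes
    rng_o = _rng(config, 2)
    n_orth = int(round(config.ortholog_fraction * config.n_genes))
    a_orth = list(rng_o.permutation(len(genes[sp_a]))[:n_orth])
    b_orth = list(rng_o.permutation(len(genes[sp_b]))[:n_orth])
    records = []
    pair_of: dict[str, GeneModel] = {}
    for ia, ib in zip(a_orth, b_orth):
        ga, gb = genes[sp_a][ia], genes[sp_b][ib]
        pct = float(rng_o.uniform(60, 95))
        records.append((ga.gene_id, gb.gene_id, round(pct, 2)))
        pair_of[ga.gene_id] = gb
        # occasional weaker decoy candidate, so best-ortholog selection is
        # actually exercised on realistic input
        if rng_o.random() < 0.2:
            decoy = genes[sp_b][int(rng_o.integers(len(genes[sp_b])))]
            if decoy.gene_id != gb.gene_id:
                records.append(
                    (ga.gene_id, decoy.gene_id, round(pct - float(rng_o.uniform(5, 25)), 2))
                )
    ortholog_table = pd.DataFrame(
        records, columns=["query_gene_id", "target_gene_id", "pct_identity"]
    )

    # native enhancers per species
    for k, sp in enumerate(config.species):
        rng = _rng(config, 3, k)
        n = config.n_enhancers
        n_ire = int(round(config.ire_fraction * n))
        ire_flags = np.zeros(n, dtype=bool)
        ire_flags[list(rng.permutation(n)[:n_ire])] = True
        gene_cycle = list(rng.permutation(len(genes[sp])))
        for i in range(n):
            length = int(rng.integers(*config.enhancer_length))
            placed = None
            for attempt in range(50):
                gene = genes[sp][gene_cycle[(i + attempt * 37) % len(gene_cycle)]]
                placed = _place_near_tss(rng, config, gene, length, occ[sp])
                if placed is not None:
                    break
            if placed is None:
                raise ValueError("infeasible placement: too many enhancers")
            is_ire = bool(ire_flags[i])
            n_ap1 = config.ap1_per_ire if is_ire else config.ap1_per_nonire
            n_ets = config.ets_per_ire if is_ire else config.ets_per_nonire
            arr = genomes_arr[sp][placed.chrom]
            offsets = _plant_motifs(rng, arr, placed.start, placed.end, n_ap1, n_ets)
            fc = float(rng.uniform(*config.injury_fc_range)) if is_ire else 1.0
            iv = GenomicInterval(
                placed.chrom, placed.start, placed.end, name=f"{sp}_e{i:04d}"
            )
            linked, _dist = nearest_feature(iv, genes[sp])
            enhancers.append(
                EnhancerTruth(
                    species=sp,
                    interval=iv,
                    is_ire=is_ire,
                    fold_change=fc,
                    linked_gene=linked.gene_id if linked else "",
                    ap1_planted=n_ap1,
                    ets_planted=n_ets,
                    motif_offsets=offsets,
                )
            )

    # orthologous copies of species-A IREs in species B
    rng = _rng(config, 4)
    for e in [x for x in enhancers if x.species == sp_a and x.is_ire]:
        gb = pair_of.get(e.linked_gene)
        if gb is None:
            e.cross_class = "unmapped"
            continue
        length = len(e.interval)
        placed = _place_near_tss(rng, config, gb, length, occ[sp_b])
        if placed is None:
            e.cross_class = "unmapped"
            continue
        src = genomes_arr[sp_a][e.interval.chrom][
            e.interval.start : e.interval.end
        ]
        copy = _diverge(rng, src, config.divergence)
        ablated = bool(rng.random() < config.motif_ablation_prob)
        if ablated:
            _ablate_motifs(rng, copy, e.motif_offsets)
        arr = genomes_arr[sp_b][placed.chrom]
        arr[placed.start : placed.end] = copy
        partner_iv = GenomicInterval(
            placed.chrom, placed.start, placed.end, name=f"{e.interval.name}_orth"
        )
        e.partner = partner_iv
        e.partner_species = sp_b
        e.divergence = config.divergence
        e.ablated = ablated
        e.cross_class = "species-specific" if ablated else "shared"
        if not ablated:
            enhancers.append(
                EnhancerTruth(
                    species=sp_b,
                    interval=partner_iv,
                    is_ire=True,
                    fold_change=e.fold_change,
                    linked_gene=gb.gene_id,
                    ap1_planted=e.ap1_planted,
                    ets_planted=e.ets_planted,
                    motif_offsets=list(e.motif_offsets),
                    origin="ortholog-copy",
                    partner=e.interval,
                    partner_species=sp_a,
                    divergence=config.divergence,
                )
            )

    genomes = {sp: Genome({c: a.tobytes().decode() for c, a in genomes_arr[sp].items()})
               for sp in config.species}

    # self-consistency: recount family motifs on the emitted sequence
    for e in enhancers:
        seq = genomes[e.species].fetch(e.interval)
        e.ap1_count = scan_motif(seq, AP1, "both_dedup").count
        e.ets_count = scan_motif(seq, ETS, "both_dedup").count

    # gene-level truth: IRE-linked genes are induced
    rng_g = _rng(config, 5)
    sc_types = list(CANONICAL_CELL_TYPES[: config.sc_n_cell_types])
    gene_truth: dict[str, dict[str, GeneTruth]] = {}
    for sp in config.species:
        induced_genes = list(
            dict.fromkeys(
                e.linked_gene for e in enhancers if e.species == sp and e.is_ire
            )
        )
        truth = {}
        for g in genes[sp]:
            truth[g.gene_id] = GeneTruth(
                species=sp,
                gene=g,
                transcript_length=int(rng_g.integers(500, 3001)),
            )
        for j, gid in enumerate(induced_genes):
            truth[gid].induced = True
            truth[gid].fold_change = config.rna_induced_fc
            truth[gid].cell_type = sc_types[j % len(sc_types)]
        gene_truth[sp] = truth

    return SimTruth(config, genomes, genes, gene_truth, enhancers, ortholog_table)


def _nb_draw(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_chip_counts(
    truth: SimTruth, species: str, dispersion: Optional[float] = None
) -> RegionCountTable:
    """Replicated injured/control NB counts over the species' enhancers.

    Injured-sample means of planted IREs carry their truth fold change;
    everything else sits at the base enrichment.
    """
    config = truth.config
    phi = config.nb_dispersion if dispersion is None else dispersion
    rng = _rng(config, 6, config.species.index(species))
    enh = truth.species_enhancers(species)
    base = config.base_region_mean
    samples = []
    meta_rows = []
    for cond in ("injured", "control"):
        for rep in range(1, config.replicates + 1):
            means = np.array(
                [
                    base * (e.fold_change if (cond == "injured" and e.is_ire) else 1.0)
                    for e in enh
                ]
            )
            samples.append(_nb_draw(rng, means, phi))
            meta_rows.append(
                {
                    "sample": f"{cond}_{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "library_size": config.library_size,
                }
            )
    counts = np.column_stack(samples).astype(int)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return RegionCountTable([e.interval for e in enh], counts, meta)


def simulate_rna_counts(
    truth: SimTruth, species: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Bulk RNA NB counts (genes x samples) plus transcript lengths; genes
    linked to an IRE are induced by the configured fold change in injured
    samples."""
    config = truth.config
    rng = _rng(config, 7, config.species.index(species))
    gt = truth.gene_truth[species]
    gene_ids = [g.gene_id for g in truth.genes[species]]
    base = rng.lognormal(config.rna_mean_log, config.rna_sd_log, size=len(gene_ids))
    cols = {}
    for cond in ("injured", "control"):
        for rep in range(1, config.replicates + 1):
            means = base.copy()
            if cond == "injured":
                induced = np.array([gt[g].induced for g in gene_ids])
                means[induced] *= config.rna_induced_fc
            cols[f"{cond}_{rep}"] = _nb_draw(rng, means, config.nb_dispersion)
    counts = pd.DataFrame(cols, index=gene_ids)
    lengths = pd.Series(
        [gt[g].transcript_length for g in gene_ids], index=gene_ids, name="length"
    )
    return counts, lengths


def _sc_sample(
    rng,
    panel: list[str],
    truth_type: np.ndarray,
    types: list[str],
    cells_per_type: int,
    baseline_mean: float,
    induced_fc: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    cell_ids, cell_type_col, cond_col, columns = [], [], [], []
    for t_idx, ctype in enumerate(types):
        for cond in ("injured", "uninjured"):
            for i in range(cells_per_type):
                depth = rng.uniform(0.7, 1.3)
                means = np.full(len(panel), baseline_mean)
                if cond == "injured":
                    means[truth_type == t_idx] *= induced_fc
                columns.append(rng.poisson(means * depth))
                slug = ctype.replace(" ", "_")
                cell_ids.append(f"{slug}.{cond}.{i:03d}")
                cell_type_col.append(ctype)
                cond_col.append(cond)
    counts = pd.DataFrame(np.column_stack(columns), index=panel, columns=cell_ids)
    meta = pd.DataFrame(
        {"cell_type": cell_type_col, "condition": cond_col}, index=cell_ids
    )
    meta.index.name = "cell_id"
    return counts, meta


def simulate_sc_counts(
    truth: SimTruth, species: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-cell counts (genes x cells) and a cell annotation table.

    The gene panel is the species' induced (IRE-linked) genes capped at the
    configured size; each carries its truth cell type, and only injured
    cells of that type are elevated. Per-cell depth varies uniformly
    (0.7-1.3x), which the downstream normalization must cancel.
    """
    config = truth.config
    rng = _rng(config, 8, config.species.index(species))
    gt = truth.gene_truth[species]
    panel = [gid for gid, t in gt.items() if t.induced][: config.sc_n_genes]
    if not panel:
        raise ValueError("no induced genes to simulate")
    types = list(CANONICAL_CELL_TYPES[: config.sc_n_cell_types])
    truth_type = np.array([types.index(gt[g].cell_type) for g in panel])
    return _sc_sample(
        rng, panel, truth_type, types, config.sc_cells_per_type,
        config.sc_baseline_mean, config.sc_induced_fc,
    )


def simulate_sc_benchmark(
    n_genes: int = 50,
    n_cell_types: int = 5,
    cells_per_type: int = 40,
    baseline_mean: float = 2.0,
    induced_fc: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Standalone cell-type-assignment benchmark without a genome: each gene
    is induced in exactly one (round-robin) type. Returns (counts, cell
    annotations, truth type per gene)."""
    rng = np.random.default_rng(seed)
    panel = [f"g{i:04d}" for i in range(n_genes)]
    types = list(CANONICAL_CELL_TYPES[:n_cell_types])
    truth_type = np.arange(n_genes) % len(types)
    counts, meta = _sc_sample(
        rng, panel, truth_type, types, cells_per_type, baseline_mean, induced_fc
    )
    truth = pd.Series([types[t] for t in truth_type], index=panel, name="cell_type")
    return counts, meta, truth


def write_sc_mtx(counts: pd.DataFrame, meta: pd.DataFrame, outdir) -> None:
    """Emit MatrixMarket counts plus genes and cell-annotation TSVs."""
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="gene_id").to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    meta.to_csv(out / "cells.tsv", sep="\t")


def simulate_count_table(
    n_null: int,
    n_ire: int,
    fold_change: float,
    dispersion: float = 0.1,
    replicates: int = 2,
    base_mean: float = 50.0,
    library_size: int = 1_000_000,
    seed: int = 0,
) -> tuple[RegionCountTable, np.ndarray]:
    """Standalone differential-calling benchmark: ``n_null`` unchanged
    regions plus ``n_ire`` regions at the planted injury fold change.
    Returns the table and the boolean truth vector (True = planted IRE)."""
    rng = np.random.default_rng(seed)
    n = n_null + n_ire
    is_ire = np.zeros(n, dtype=bool)
    is_ire[n_null:] = True
    regions = [
        GenomicInterval("chrS", 2000 * i + 1, 2000 * i + 1001, name=f"r{i:05d}")
        for i in range(n)
    ]
    samples, meta_rows = [], []
    for cond in ("injured", "control"):
        for rep in range(1, replicates + 1):
            means = np.where(
                is_ire & (cond == "injured"), base_mean * fold_change, base_mean
            )
            samples.append(_nb_draw(rng, means, dispersion))
            meta_rows.append(
                {
                    "sample": f"{cond}_{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "library_size": library_size,
                }
            )
    counts = np.column_stack(samples).astype(int)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return RegionCountTable(regions, counts, meta), is_ire


def simulate_expression_table(
    n_genes: int,
    n_induced: int,
    fold_change: float,
    dispersion: float = 0.1,
    replicates: int = 2,
    mean_log: float = 4.0,
    sd_log: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Standalone DE benchmark: lognormal baseline means, the first
    ``n_induced`` genes induced in injured samples. Returns (counts table,
    induced gene ids)."""
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean_log, sd_log, size=n_genes)
    induced = np.zeros(n_genes, dtype=bool)
    induced[:n_induced] = True
    cols = {}
    for cond in ("injured", "control"):
        for rep in range(1, replicates + 1):
            means = np.where(induced & (cond == "injured"), base * fold_change, base)
            cols[f"{cond}_{rep}"] = _nb_draw(rng, means, dispersion)
    return pd.DataFrame(cols, index=gene_ids), list(np.array(gene_ids)[induced])
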