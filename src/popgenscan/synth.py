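"""Study-like synthetic fixtures: VCF + population map + toy GFF + truth BEDs.

The generator emulates the shape of the duck resequencing panel: three
diverged ingroup populations (19 wild, 25 Chinese-domestic, 21
Southeast/South-Asian) plus a small deep outgroup (4), two 5-Mb
chromosomes tiled from independent coalescent loci, domestication
bottlenecks, an optional contiguous introgressed tract copied from donor
haplotypes into a subset of recipient haplotypes, and an optional sweep
region homogenized to a founder haplotype. Every planted effect is
recorded in a truth set so each scan can be validated blind.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import msprime
import numpy as np

from .demography import DemographicModel, default_registry
from .popio import PopulationMap, VariantTable, write_vcf

__all__ = [
    "IntrogressionPlant",
    "SweepPlant",
    "ScenarioConfig",
    "Fixture",
    "generate_fixture",
    "plant_introgression",
    "plant_sweep",
    "write_fixture",
    "simulate_ld_locus",
]

# a concrete "true" demography for fixtures, anchored to field estimates
# for this system: wild mallard Ne ~ 1e5, a domestic group with a
# domestication bottleneck, a Southeast/South-Asian group reduced to
# Ne ~ 1e4 by a severe bottleneck; splits ~3500 (wild vs rest) and ~1700
# (domestic vs SEASA) generations ago at 1 year per generation
DEFAULT_TRUE_PARAMS: dict[str, float] = {
    "N_WILD": 1.0e5, "N_DOM": 6.0e4, "N_SEASA": 1.0e4,
    "N_ANC1": 1.0e5, "N_ANC0": 1.5e5,
    "T0": 3500.0, "T1": 1700.0,
    "BF_DOM": 0.15, "BF_SEASA": 0.1,
}


@dataclass(frozen=True)
class IntrogressionPlant:
    donor: str
    recipient: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    fraction: float  # of recipient haplotypes replaced


@dataclass(frozen=True)
class SweepPlant:
    deme: str
    chrom: str
    start: int
    end: int
    mu_new: float = 2e-6  # per bp: Poisson(mu_new * L) new mutations per hap


@dataclass
class ScenarioConfig:
    """The stated world of the fixture generator (defaults mirror the study)."""

    sample_sizes: dict[str, int] = field(default_factory=lambda: {
        "Wild": 19, "DomCN": 25, "SEASA": 21, "Outgroup": 4})
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {
        "chr1": 5_000_000, "chr2": 5_000_000})
    locus_bp: int = 10_000
    model_name: str = "M1"  # background demography; plants supply the signal
    params: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PARAMS))
    outgroup_ne: float = 5e4
    outgroup_split_gens: float = 500_000.0
    introgression: IntrogressionPlant | None = None
    sweep: SweepPlant | None = None
    seed: int = 1

    def model(self) -> DemographicModel:
        return default_registry()[self.model_name]


@dataclass
class Fixture:
    vt: VariantTable
    popmap: PopulationMap
    genes: "object"  # pd.DataFrame(chrom, start, end, gene_id)
    truth: dict


_POP_PREFIX = {"Wild": "W", "DomCN": "D", "SEASA": "S", "Outgroup": "O"}
_BASES = np.array(list("ACGT"))


def _sample_names(sizes: dict[str, int]) -> tuple[list[str], np.ndarray]:
    names, pops = [], []
    for pop, n in sizes.items():
        for i in range(n):
            names.append(f"{_POP_PREFIX.get(pop, pop[0])}{i + 1:02d}")
            pops.append(pop)
    return names, np.array(pops, dtype=object)


def _outgroup_demography(cfg: ScenarioConfig) -> msprime.Demography:
    dem = cfg.model().to_msprime(cfg.params)
    dem.add_population(name="Outgroup", initial_size=cfg.outgroup_ne)
    root_ne = cfg.params["N_ANC0"]
    dem.add_population(name="Root", initial_size=root_ne)
    dem.add_population_split(time=cfg.outgroup_split_gens,
                             derived=["Anc0", "Outgroup"], ancestral="Root")
    dem.sort_events()
    return dem


def _simulate_chromosome(cfg: ScenarioConfig, chrom: str, length: int,
                         rng: np.random.Generator):
    """Tile independent loci end-to-end; returns (pos, hap_matrix, pop_of_hap)."""
    dem = _outgroup_demography(cfg)
    n_loci = int(np.ceil(length / cfg.locus_bp))
    mu = cfg.model().mu
    reps = msprime.sim_ancestry(
        samples=cfg.sample_sizes, demography=dem, ploidy=2,
        sequence_length=cfg.locus_bp, num_replicates=n_loci,
        random_seed=int(rng.integers(1, 2**31 - 1)))
    mut_seeds = rng.integers(1, 2**31 - 1, size=n_loci)
    pos_all, hap_all, pop_of_hap = [], [], None
    for l, ts in enumerate(reps):
        mts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=int(mut_seeds[l]))
        if pop_of_hap is None:
            pop_names = {p.id: p.metadata["name"] for p in mts.populations()}
            pop_of_hap = np.array(
                [pop_names[mts.node(u).population] for u in mts.samples()],
                dtype=object)
        if not mts.num_sites:
            continue
        raw = np.array([s.position for s in mts.sites()])
        pos = np.floor(raw).astype(np.int64) + l * cfg.locus_bp + 1
        hap = mts.genotype_matrix().astype(np.int8)
        keep = np.concatenate([[True], np.diff(pos) > 0]) & (pos <= length)
        pos_all.append(pos[keep])
        hap_all.append(hap[keep])
    if pos_all:
        return np.concatenate(pos_all), np.vstack(hap_all), pop_of_hap
    return (np.empty(0, dtype=np.int64),
            np.empty((0, 2 * sum(cfg.sample_sizes.values())), dtype=np.int8),
            pop_of_hap)


def plant_introgression(haps: np.ndarray, pos: np.ndarray,
                        pop_of_hap: np.ndarray, plant: IntrogressionPlant,
                        rng: np.random.Generator) -> np.ndarray:
    """Copy donor haplotypes over a fraction of recipient haplotypes in the
    tract. Returns the modified matrix (sites stay unchanged outside)."""
    recip = np.flatnonzero(pop_of_hap == plant.recipient)
    donor = np.flatnonzero(pop_of_hap == plant.donor)
    n_replace = int(round(plant.fraction * len(recip)))
    if plant.fraction > 0 and n_replace < 1:
        raise ValueError("fraction * n_recipient < 1 haplotype")
    if n_replace == 0:
        return haps
    chosen = rng.choice(recip, size=n_replace, replace=False)
    sources = rng.choice(donor, size=n_replace, replace=True)
    in_tract = (pos >= plant.start) & (pos <= plant.end)
    out = haps.copy()
    out[np.ix_(in_tract, chosen)] = haps[np.ix_(in_tract, sources)]
    return out


def plant_sweep(haps: np.ndarray, pos: np.ndarray, pop_of_hap: np.ndarray,
                plant: SweepPlant, rng: np.random.Generator,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Homogenize the target deme in the interval to one founder haplotype,
    then sprinkle Poisson(mu_new * L) private new mutations per haplotype
    (new singleton sites). Returns (haps, pos) sorted by position."""
    target = np.flatnonzero(pop_of_hap == plant.deme)
    in_int = (pos >= plant.start) & (pos <= plant.end)
    out = haps.copy()
    founder = out[np.ix_(in_int, target[:1])]
    out[np.ix_(in_int, target)] = np.broadcast_to(
        founder, (int(in_int.sum()), len(target)))
    L = plant.end - plant.start + 1
    new_rows, new_pos = [], []
    existing = set(pos.tolist())
    for h in target:
        k = rng.poisson(plant.mu_new * L)
        for _ in range(k):
            p = int(rng.integers(plant.start, plant.end + 1))
            if p in existing:
                continue
            existing.add(p)
            row = np.zeros(haps.shape[1], dtype=np.int8)
            row[h] = 1
            new_rows.append(row)
            new_pos.append(p)
    if new_rows:
        out = np.vstack([out, np.array(new_rows, dtype=np.int8)])
        pos = np.concatenate([pos, np.array(new_pos, dtype=np.int64)])
        order = np.argsort(pos, kind="stable")
        out, pos = out[order], pos[order]
    return out, pos


def _toy_genes(cfg: ScenarioConfig, chrom: str, length: int,
               truth_intervals: list[tuple[int, int]],
               rng: np.random.Generator) -> list[tuple]:
    """3-10 genes per chromosome, one straddling each truth boundary."""
    rows = []
    counter = 1
    for start, end in truth_intervals:
        for edge in (start, end):
            g_start = max(1, edge - 5_000)
            g_end = min(length, edge + 5_000)
            rows.append((chrom, g_start, g_end, f"{chrom}_g{counter}"))
            counter += 1
    n_extra = int(rng.integers(3, 7))
    for _ in range(n_extra):
        g_start = int(rng.integers(1, max(2, length - 20_000)))
        g_end = min(length, g_start + int(rng.integers(2_000, 20_000)))
        rows.append((chrom, g_start, g_end, f"{chrom}_g{counter}"))
        counter += 1
    return sorted(rows, key=lambda r: r[1])[:10]


def generate_fixture(cfg: ScenarioConfig) -> Fixture:
    """Simulate the scenario and apply any planted effects.

    Deterministic under ``cfg.seed``; all coordinates 1-based inclusive.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    names, sample_pops = _sample_names(cfg.sample_sizes)
    popmap = PopulationMap(dict(zip(names, sample_pops)), {"Outgroup"})

    chroms_col, pos_col, gt_col, refs, alts = [], [], [], [], []
    gene_rows = []
    truth = {"model": cfg.model_name, "params": dict(cfg.params),
             "introgression": [], "sweep": []}
    expected_hap_pops = np.repeat(sample_pops, 2)
    for chrom, length in cfg.chrom_lengths.items():
        pos, haps, pop_of_hap = _simulate_chromosome(cfg, chrom, length, rng)
        if not np.array_equal(pop_of_hap, expected_hap_pops):
            raise RuntimeError("haplotype order does not match sample names")
        intervals = []
        if cfg.introgression and cfg.introgression.chrom == chrom:
            pl = cfg.introgression
            if not (1 <= pl.start <= pl.end <= length):
                raise ValueError("introgression tract outside chromosome")
            haps = plant_introgression(haps, pos, pop_of_hap, pl, rng)
            truth["introgression"].append(
                {"chrom": chrom, "start": pl.start, "end": pl.end,
                 "donor": pl.donor, "recipient": pl.recipient,
                 "fraction": pl.fraction})
            intervals.append((pl.start, pl.end))
        if cfg.sweep and cfg.sweep.chrom == chrom:
            pl = cfg.sweep
            if not (1 <= pl.start <= pl.end <= length):
                raise ValueError("sweep interval outside chromosome")
            haps, pos = plant_sweep(haps, pos, pop_of_hap, pl, rng)
            truth["sweep"].append({"chrom": chrom, "start": pl.start,
                                   "end": pl.end, "deme": pl.deme})
            intervals.append((pl.start, pl.end))
        gene_rows += _toy_genes(cfg, chrom, length, intervals, rng)

        # drop globally invariant sites, diploidize, assign alleles
        tot = haps.sum(axis=1)
        keep = (tot > 0) & (tot < haps.shape[1])
        pos, haps = pos[keep], haps[keep]
        gt = haps[:, 0::2] + haps[:, 1::2]
        base_idx = rng.integers(0, 4, size=(len(pos), 2))
        base_idx[:, 1] = (base_idx[:, 0] + 1 + base_idx[:, 1] % 3) % 4
        chroms_col.append(np.full(len(pos), chrom, dtype=object))
        pos_col.append(pos)
        gt_col.append(gt.astype(np.int8))
        refs.append(_BASES[base_idx[:, 0]])
        alts.append(_BASES[base_idx[:, 1]])

    # haplotype columns are ordered (pop-major) exactly like sample names
    vt = VariantTable(
        chrom=np.concatenate(chroms_col), pos=np.concatenate(pos_col),
        ref=np.concatenate(refs).astype(object),
        alt=np.concatenate(alts).astype(object),
        genotypes=np.vstack(gt_col), samples=names,
        contig_lengths=dict(cfg.chrom_lengths))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end",
                                             "gene_id"])
    return Fixture(vt=vt, popmap=popmap, genes=genes, truth=truth)


def write_fixture(fx: Fixture, outdir) -> dict[str, Path]:
    """Write fixture.vcf, popmap.tsv, genes.gff3, truth BEDs, truth_model.json."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["vcf"] = outdir / "fixture.vcf"
    write_vcf(fx.vt, paths["vcf"])
    paths["popmap"] = outdir / "popmap.tsv"
    fx.popmap.to_tsv(paths["popmap"])
    paths["gff"] = outdir / "genes.gff3"
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in fx.genes.iterrows():
            fh.write(f"{g['chrom']}\tsynth\tgene\t{g['start']}\t{g['end']}"
                     f"\t.\t+\t.\tID={g['gene_id']}\n")
    for key, fname in (("introgression", "truth_introgression.bed"),
                       ("sweep", "truth_sweep.bed")):
        paths[key] = outdir / fname
        with open(paths[key], "w") as fh:
            for r in fx.truth[key]:
                fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\n")
    paths["model"] = outdir / "truth_model.json"
    with open(paths["model"], "w") as fh:
        json.dump({"model": fx.truth["model"], "params": fx.truth["params"]},
                  fh, indent=1, sort_keys=True)
    return paths


def simulate_ld_locus(ne: float, length_bp: int, n_diploid: int, seed: int,
                      mu: float = 2.5e-8, recomb_rate: float = 1e-8,
                      chrom: str = "chr1") -> tuple[VariantTable, np.ndarray]:
    """Single panmictic locus WITH intra-locus recombination, for LD decay.

    The tiled multi-locus fixture has no within-locus recombination, so its
    LD structure is blocky; LD-decay behaviour is exercised on this
    dedicated single-locus simulation instead. Returns (VariantTable,
    phased haplotype matrix sites x haplotypes).
    """
    ts = msprime.sim_ancestry(samples=n_diploid, population_size=ne,
                              sequence_length=length_bp,
                              recombination_rate=recomb_rate, ploidy=2,
                              random_seed=seed)
    mts = msprime.sim_mutations(ts, rate=mu,
                                model=msprime.BinaryMutationModel(),
                                discrete_genome=False, random_seed=seed + 1)
    raw = np.array([s.position for s in mts.sites()])
    pos = np.floor(raw).astype(np.int64) + 1
    hap = mts.genotype_matrix().astype(np.int8)
    keep = np.concatenate([[True], np.diff(pos) > 0])
    pos, hap = pos[keep], hap[keep]
    tot = hap.sum(axis=1)
    seg = (tot > 0) & (tot < hap.shape[1])
    pos, hap = pos[seg], hap[seg]
    gt = hap[:, 0::2] + hap[:, 1::2]
    names = [f"I{i + 1:02d}" for i in range(n_diploid)]
    vt = VariantTable(
        chrom=np.full(len(pos), chrom, dtype=object), pos=pos,
        ref=np.full(len(pos), "A", dtype=object),
        alt=np.full(len(pos), "C", dtype=object),
        genotypes=gt.astype(np.int8), samples=names,
        contig_lengths={chrom: length_bp})
    return vt, hap
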