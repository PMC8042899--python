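"""Coalescent simulation of three-population-plus-outgroup demographies,
prior samplers, summary statistics, PLS-DA reduction and ABC model choice.

The demographic scaffold mirrors a domestication scenario: backward in
time, the two derived groups (Chinese-domestic ``DomCN`` and
Southeast/South-Asian ``SEASA``) merge at T1 into an ancestor that merges
with ``Wild`` at T0; each derived deme may pass through a bottleneck in the
older half of its existence, and migration edges connect coexisting demes.
Eight registry models differ only in which migration edges are active.

Loci are simulated independently (no intra-locus recombination,
fastsimcoal/arlsumstat style) with msprime as the coalescent engine and
infinite-sites mutations at mu = 1.91e-9 per bp per generation (generation
time 1 year); model choice follows the ABC-GLM construction of
Leuenberger & Wegmann after a PLS-DA compression of 37 summary statistics
to 9 components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .diversity import (hudson_fst_components, site_dxy, site_pi,
                        tajimas_d_from_sums)

__all__ = [
    "Param",
    "MigrationEdge",
    "DemographicModel",
    "default_registry",
    "draw_priors",
    "SimulatedDataset",
    "simulate_dataset",
    "SummaryInput",
    "summary_input_from_dataset",
    "summary_input_from_variant_table",
    "summarize",
    "summary_stat_names",
    "PLSReducer",
    "pls_reduce",
    "ABCResult",
    "abc_model_choice",
    "validate_model_choice",
]

MU_PER_BP_PER_GEN = 1.91e-9
GENERATION_TIME_YEARS = 1.0
INGROUP_DEMES = ("Wild", "DomCN", "SEASA")


@dataclass(frozen=True)
class Param:
    """One free parameter with its prior."""

    name: str
    dist: str  # "uniform" | "loguniform"
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)
                and self.lo < self.hi):
            raise ValueError(f"bad bounds for {self.name}")
        if self.dist == "uniform":
            return rng.uniform(self.lo, self.hi, size)
        if self.dist == "loguniform":
            return np.exp(rng.uniform(np.log(self.lo), np.log(self.hi), size))
        raise ValueError(f"unknown distribution {self.dist!r}")


@dataclass(frozen=True)
class MigrationEdge:
    """Symmetric migration between two coexisting demes.

    ``rate_param`` names the prior parameter holding the scaled rate
    4*N*m; the per-generation lineage rate in deme i is m = M/(4*N_i).
    ``recent_only`` restricts migration to the most recent T1/2 generations.
    """

    deme_a: str
    deme_b: str
    rate_param: str
    recent_only: bool = False


# base priors shared by every model (reconstructed defaults; swappable)
_BASE_PRIORS = [
    Param("N_WILD", "loguniform", 1e3, 1e6),
    Param("N_DOM", "loguniform", 1e3, 1e6),
    Param("N_SEASA", "loguniform", 1e3, 1e6),
    Param("N_ANC1", "loguniform", 1e3, 1e6),
    Param("N_ANC0", "loguniform", 1e3, 1e6),
    Param("T0", "uniform", 1000, 10000),
    Param("T1", "uniform", 100, 10000),  # accepted only when T1 < T0
    Param("BF_DOM", "loguniform", 0.01, 1.0),
    Param("BF_SEASA", "loguniform", 0.01, 1.0),
]


@dataclass
class DemographicModel:
    """A three-population-plus-outgroup scenario template.

    Splits: (DomCN, SEASA) -> Anc1 at T1; (Wild, Anc1) -> Anc0 at T0
    (backward in time, generations; T1 < T0 enforced by the priors).
    Bottlenecks: each derived deme runs at size BF*N during the older half
    of its post-split existence ([T1/2, T1] for DomCN and SEASA).
    """

    name: str
    migration_edges: tuple[MigrationEdge, ...] = ()
    priors: list[Param] = field(default_factory=lambda: list(_BASE_PRIORS))
    mu: float = MU_PER_BP_PER_GEN
    generation_time: float = GENERATION_TIME_YEARS

    def all_priors(self) -> list[Param]:
        extra = [Param(e.rate_param, "uniform", 0.0, 20.0)
                 for e in self.migration_edges]
        return list(self.priors) + extra

    def param_names(self) -> list[str]:
        return [p.name for p in self.all_priors()]

    def to_msprime(self, params: dict[str, float]) -> msprime.Demography:
        """Build the msprime demography for one parameter draw."""
        t1, t0 = float(params["T1"]), float(params["T0"])
        if not 0 < t1 < t0:
            raise ValueError("require 0 < T1 < T0")
        dem = msprime.Demography()
        dem.add_population(name="Wild", initial_size=params["N_WILD"])
        dem.add_population(name="DomCN", initial_size=params["N_DOM"])
        dem.add_population(name="SEASA", initial_size=params["N_SEASA"])
        dem.add_population(name="Anc1", initial_size=params["N_ANC1"])
        dem.add_population(name="Anc0", initial_size=params["N_ANC0"])
        # bottleneck epoch: older half of each derived deme's existence
        for deme, ne_key, bf_key in (("DomCN", "N_DOM", "BF_DOM"),
                                     ("SEASA", "N_SEASA", "BF_SEASA")):
            frac = float(params.get(bf_key, 1.0))
            if frac < 1.0:
                dem.add_population_parameters_change(
                    time=t1 / 2.0, population=deme,
                    initial_size=frac * params[ne_key])
        sizes = {"Wild": params["N_WILD"], "DomCN": params["N_DOM"],
                 "SEASA": params["N_SEASA"]}
        for edge in self.migration_edges:
            m_scaled = float(params[edge.rate_param])
            for src, dst in ((edge.deme_a, edge.deme_b),
                             (edge.deme_b, edge.deme_a)):
                rate = m_scaled / (4.0 * sizes[src])
                if edge.recent_only:
                    if rate > 0:
                        dem.set_migration_rate(src, dst, rate)
                        dem.add_migration_rate_change(
                            time=t1 / 2.0, rate=0.0, source=src, dest=dst)
                elif rate > 0:
                    dem.set_migration_rate(src, dst, rate)
        dem.add_population_split(time=t1, derived=["DomCN", "SEASA"],
                                 ancestral="Anc1")
        dem.add_population_split(time=t0, derived=["Wild", "Anc1"],
                                 ancestral="Anc0")
        dem.sort_events()
        return dem


def default_registry() -> dict[str, DemographicModel]:
    """The eight gene-flow models: which migration edges are active.

    M1 none; M2 Wild<->DomCN; M3 DomCN<->SEASA; M4 Wild<->SEASA;
    M5 = M2+M3; M6 = M2+M4; M7 all three pairs (continuous);
    M8 all pairs, active only in the most recent T1/2 generations.
    """
    wd = MigrationEdge("Wild", "DomCN", "M_WILD_DOM")
    ds = MigrationEdge("DomCN", "SEASA", "M_DOM_SEASA")
    ws = MigrationEdge("Wild", "SEASA", "M_WILD_SEASA")
    recent = tuple(MigrationEdge(e.deme_a, e.deme_b, e.rate_param,
                                 recent_only=True) for e in (wd, ds, ws))
    return {
        "M1": DemographicModel("M1"),
        "M2": DemographicModel("M2", (wd,)),
        "M3": DemographicModel("M3", (ds,)),
        "M4": DemographicModel("M4", (ws,)),
        "M5": DemographicModel("M5", (wd, ds)),
        "M6": DemographicModel("M6", (wd, ws)),
        "M7": DemographicModel("M7", (wd, ds, ws)),
        "M8": DemographicModel("M8", recent),
    }


def draw_priors(model: DemographicModel, n_draws: int,
                seed: int | None = None) -> pd.DataFrame:
    """I.i.d. prior draws honoring bounds and the T1 < T0 ordering.

    The ordering constraint is satisfied by rejection; an acceptance rate
    below 0.1% raises rather than looping forever.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    priors = model.all_priors()
    out = np.empty((n_draws, len(priors)))
    names = [p.name for p in priors]
    filled = 0
    attempts = 0
    while filled < n_draws:
        batch = max(n_draws - filled, 64)
        attempts += batch
        draw = np.column_stack([p.sample(rng, batch) for p in priors])
        ok = draw[:, names.index("T1")] < draw[:, names.index("T0")]
        accepted = draw[ok][: n_draws - filled]
        out[filled:filled + len(accepted)] = accepted
        filled += len(accepted)
        if attempts > 1000 and filled / attempts < 0.001:
            raise RuntimeError("prior constraint rejection rate > 99.9%")
    return pd.DataFrame(out, columns=names)


@dataclass
class SimulatedDataset:
    """Haplotypes from independent loci.

    ``haplotypes[l]`` is a (segregating sites x haplotypes) 0/1 matrix
    (1 = derived); ``positions[l]`` holds continuous positions in
    [0, locus_bp). ``pop_of_hap`` labels every haplotype column.
    """

    haplotypes: list[np.ndarray]
    positions: list[np.ndarray]
    pop_of_hap: np.ndarray
    locus_bp: int
    sample_sizes: dict[str, int]  # diploid individuals per deme

    @property
    def n_loci(self) -> int:
        return len(self.haplotypes)


def simulate_dataset(model: DemographicModel, params: dict[str, float],
                     sample_sizes: dict[str, int], n_loci: int,
                     locus_bp: int, seed: int) -> SimulatedDataset:
    """Simulate independent loci under one parameter draw.

    Each locus is an independent coalescent genealogy (no intra-locus
    recombination) with infinite-sites mutations at rate mu per bp per
    generation. ``sample_sizes`` counts diploid individuals per sampled
    deme. Bit-reproducible under a fixed seed.
    """
    if n_loci < 1 or any(v < 1 for v in sample_sizes.values()):
        raise ValueError("need n_loci >= 1 and sample sizes >= 1")
    dem = model.to_msprime(params)
    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(1, 2**31 - 1, size=2)
    reps = msprime.sim_ancestry(
        samples=sample_sizes, demography=dem, sequence_length=locus_bp,
        ploidy=2, num_replicates=n_loci, random_seed=int(s1))
    mut_rng = np.random.default_rng(s2)
    haps, poss = [], []
    pop_of_hap = None
    for ts in reps:
        mts = msprime.sim_mutations(
            ts, rate=model.mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)))
        if pop_of_hap is None:
            pop_names = {p.id: p.metadata["name"] for p in mts.populations()}
            pop_of_hap = np.array(
                [pop_names[mts.node(u).population] for u in mts.samples()],
                dtype=object)
        if mts.num_sites:
            haps.append(mts.genotype_matrix().astype(np.int8))
            poss.append(np.array([s.position for s in mts.sites()]))
        else:
            haps.append(np.empty((0, len(pop_of_hap)), dtype=np.int8))
            poss.append(np.empty(0))
    return SimulatedDataset(haps, poss, pop_of_hap, locus_bp,
                            dict(sample_sizes))


# ---------------------------------------------------------------------------
# summary statistics

@dataclass
class SummaryInput:
    """Per-site derived/alt allele counts per population, tagged by locus.

    The common currency between simulated datasets and empirical variant
    tables: ``counts[s, i]`` derived copies in population i at site s,
    ``ns[s, i]`` non-missing haplotypes, ``locus_id[s]`` the locus index.
    """

    counts: np.ndarray
    ns: np.ndarray
    locus_id: np.ndarray
    pops: list[str]
    n_loci: int
    locus_bp: int


def summary_input_from_dataset(ds: SimulatedDataset,
                               pops=INGROUP_DEMES) -> SummaryInput:
    cols = [np.flatnonzero(ds.pop_of_hap == p) for p in pops]
    counts, ns, locus = [], [], []
    for l, hap in enumerate(ds.haplotypes):
        if hap.shape[0] == 0:
            continue
        counts.append(np.column_stack([hap[:, c].sum(axis=1) for c in cols]))
        ns.append(np.broadcast_to(
            np.array([len(c) for c in cols]), counts[-1].shape).copy())
        locus.append(np.full(hap.shape[0], l))
    if counts:
        counts = np.vstack(counts).astype(np.int64)
        ns = np.vstack(ns).astype(np.int64)
        locus = np.concatenate(locus)
    else:
        counts = np.empty((0, len(pops)), dtype=np.int64)
        ns = np.empty((0, len(pops)), dtype=np.int64)
        locus = np.empty(0, dtype=np.int64)
    return SummaryInput(counts, ns, locus, list(pops), ds.n_loci, ds.locus_bp)


def summary_input_from_variant_table(vt, pm, pops, locus_bp: int,
                                     ) -> SummaryInput:
    """Chunk an empirical table into pseudo-loci of ``locus_bp`` bp."""
    from .popio import _pop_counts

    per_pop = [_pop_counts(vt, pm, p) for p in pops]
    counts = np.column_stack([c for c, _ in per_pop]).astype(np.int64)
    ns = np.column_stack([n for _, n in per_pop]).astype(np.int64)
    locus = np.zeros(vt.n_sites, dtype=np.int64)
    offset = 0
    n_loci = 0
    for c in vt.chromosomes():
        m = vt.chrom == c
        ids = (vt.pos[m] - 1) // locus_bp
        locus[m] = ids + n_loci
        n_loci += int(ids.max()) + 1 if m.any() else 0
        offset += int(m.sum())
    return SummaryInput(counts, ns, locus, list(pops), n_loci, locus_bp)


def summary_stat_names(pops=INGROUP_DEMES) -> list[str]:
    """Names of the default 37-dimensional summary vector."""
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1:]]
    names = []
    names += [f"S_{p}" for p in pops]
    names += [f"pi_{p}" for p in pops]
    names += [f"tajd_{p}" for p in pops]
    names += [f"he_{p}" for p in pops]
    names += [f"privS_{p}" for p in pops]
    names += [f"fst_{a}_{b}" for a, b in pairs]
    names += [f"dxy_{a}_{b}" for a, b in pairs]
    names += [f"sharedS_{a}_{b}" for a, b in pairs]
    names += [f"sd_pi_{p}" for p in pops]
    names += [f"sd_fst_{a}_{b}" for a, b in pairs]
    names += [f"sd_dxy_{a}_{b}" for a, b in pairs]
    names += ["S_total", "pi_total", "tajd_total", "tajd_defined"]
    return names


def summarize(si: SummaryInput) -> np.ndarray:
    """The 37 summary statistics of a dataset (see summary_stat_names).

    Per population: segregating sites S, per-bp diversity pi, Tajima's D
    (from totals at the fixed sample size; 0 when undefined), expected
    heterozygosity over dataset variant sites, private S. Per pair: Hudson
    FST (ratio of sums), per-bp dxy, shared S. Across loci: SDs of
    per-locus pi, FST and dxy. Global: pooled S, pi, Tajima's D and the
    fraction of D statistics that were defined (the undefined ones are
    imputed as 0 so vectors stay finite for PLS).

    Every kernel (site_pi, site_dxy, Hudson components, Tajima's D) is the
    same code used by the windowed empirical scans.
    """
    npop = len(si.pops)
    pairs = [(i, j) for i in range(npop) for j in range(i + 1, npop)]
    total_bp = float(si.n_loci * si.locus_bp)
    c, n = si.counts.astype(float), si.ns.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, c / np.maximum(n, 1.0), 0.0)
    seg = (c > 0) & (c < n)
    pi_site = np.column_stack(
        [site_pi(p[:, i], n[:, i]) for i in range(npop)])

    ntot = n.sum(axis=1)
    ctot = c.sum(axis=1)
    ptot = np.where(ntot > 0, ctot / np.maximum(ntot, 1.0), 0.0)
    seg_tot = (ctot > 0) & (ctot < ntot)
    pi_tot_site = site_pi(ptot, ntot)

    stats: list[float] = []
    # S, pi, Tajima's D, H_E, private S per pop
    S_pop = seg.sum(axis=0).astype(float)
    stats += list(S_pop)
    stats += list(pi_site.sum(axis=0) / total_bp)
    tajd_defined = 0.0
    tajd_vals = []
    for i in range(npop):
        n_hap = int(n[:, i].max()) if len(n) else 0
        d = (tajimas_d_from_sums(float(pi_site[seg[:, i], i].sum()),
                                 int(S_pop[i]), n_hap)
             if n_hap >= 3 and S_pop[i] >= 1 else np.nan)
        if np.isfinite(d):
            tajd_defined += 1.0
            tajd_vals.append(float(d))
        else:
            tajd_vals.append(0.0)
    stats += tajd_vals
    any_var = seg_tot | seg.any(axis=1)
    n_var = max(int(any_var.sum()), 1)
    stats += [float(pi_site[any_var, i].sum() / n_var) for i in range(npop)]
    others_seg = [np.any(np.delete(seg, i, axis=1), axis=1)
                  for i in range(npop)]
    stats += [float((seg[:, i] & ~others_seg[i]).sum()) for i in range(npop)]

    # pairwise FST (Hudson, ratio of sums), dxy, shared S
    fst_terms = {}
    for i, j in pairs:
        num, den = hudson_fst_components(p[:, i], n[:, i], p[:, j], n[:, j])
        fst_terms[(i, j)] = (num, den)
        dsum = den.sum()
        stats.append(float(num.sum() / dsum) if dsum > 0 else 0.0)
    dxy_site = {}
    for i, j in pairs:
        dxy_site[(i, j)] = site_dxy(p[:, i], p[:, j])
        stats.append(float(dxy_site[(i, j)].sum() / total_bp))
    for i, j in pairs:
        stats.append(float((seg[:, i] & seg[:, j]).sum()))

    # across-locus dispersion
    per_locus = _per_locus_tables(si, pi_site, fst_terms, dxy_site, pairs)
    pl_pi, pl_fst, pl_dxy = per_locus
    stats += [float(pl_pi[:, i].std(ddof=0)) for i in range(npop)]
    stats += [float(pl_fst[:, k].std(ddof=0)) for k in range(len(pairs))]
    stats += [float(pl_dxy[:, k].std(ddof=0)) for k in range(len(pairs))]

    # global pooled
    S_total = float(seg_tot.sum())
    stats.append(S_total)
    stats.append(float(pi_tot_site.sum() / total_bp))
    n_hap_tot = int(ntot.max()) if len(ntot) else 0
    d_tot = (tajimas_d_from_sums(float(pi_tot_site[seg_tot].sum()),
                                 int(S_total), n_hap_tot)
             if n_hap_tot >= 3 and S_total >= 1 else np.nan)
    if np.isfinite(d_tot):
        tajd_defined += 1.0
        stats.append(float(d_tot))
    else:
        stats.append(0.0)
    stats.append(tajd_defined / (npop + 1.0))
    return np.array(stats)


def _per_locus_tables(si, pi_site, fst_terms, dxy_site, pairs):
    npop = len(si.pops)
    pl_pi = np.zeros((si.n_loci, npop))
    pl_fst = np.zeros((si.n_loci, len(pairs)))
    pl_dxy = np.zeros((si.n_loci, len(pairs)))
    if len(si.locus_id) == 0:
        return pl_pi, pl_fst, pl_dxy
    for l in range(si.n_loci):
        m = si.locus_id == l
        if not m.any():
            continue
        pl_pi[l] = pi_site[m].sum(axis=0) / si.locus_bp
        for k, (i, j) in enumerate(pairs):
            num, den = fst_terms[(i, j)]
            dsum = den[m].sum()
            pl_fst[l, k] = num[m].sum() / dsum if dsum > 0 else 0.0
            pl_dxy[l, k] = dxy_site[(i, j)][m].sum() / si.locus_bp
    return pl_pi, pl_fst, pl_dxy


# ---------------------------------------------------------------------------
# PLS-DA and ABC

@dataclass
class PLSReducer:
    """Standardize-then-PLS transformer fitted on labelled simulations."""

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # columns with non-zero variance
    pls: object

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X[:, self.keep] - self.mean) / self.sd
        return self.pls.transform(Z)


def pls_reduce(stats: np.ndarray, labels, n_components: int = 9,
               ) -> tuple[PLSReducer, np.ndarray]:
    """Fit a PLS-DA compression of summary statistics.

    Statistics are standardized (zero mean, unit SD; constant columns
    dropped with a warning), the response is the one-hot model label
    matrix, and the fitted transformer is applied identically to observed
    vectors. Returns (reducer, transformed_stats).
    """
    import warnings

    from sklearn.cross_decomposition import PLSRegression

    X = np.asarray(stats, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs >= 2 distinct labels")
    if n_components > min(X.shape[1], X.shape[0] - 1):
        raise ValueError("n_components too large")
    sd_all = X.std(axis=0, ddof=0)
    keep = sd_all > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant statistic(s)")
    Xk = X[:, keep]
    mean = Xk.mean(axis=0)
    sd = Xk.std(axis=0, ddof=0)
    Z = (Xk - mean) / sd
    Y = (labels[:, None] == classes[None, :]).astype(float)
    import sklearn.exceptions

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore",
                                  sklearn.exceptions.ConvergenceWarning)
            warnings.filterwarnings("ignore", message="y residual")
            pls = PLSRegression(n_components=n_components, scale=False)
            pls.fit(Z, Y)
            T = pls.transform(Z)
    except (ValueError, np.linalg.LinAlgError):
        T = np.array([np.nan])
    if not np.isfinite(T).all():
        # degenerate labels (e.g. identical class distributions) leave the
        # supervised fit undefined; fall back to unsupervised PCA
        from sklearn.decomposition import PCA

        warnings.warn("PLS-DA degenerate; falling back to PCA")
        pls = PCA(n_components=n_components)
        T = pls.fit_transform(Z)
    reducer = PLSReducer(mean=mean, sd=sd, keep=keep, pls=pls)
    return reducer, T


@dataclass
class ABCResult:
    """Posterior model probabilities with retention diagnostics."""

    table: pd.DataFrame  # model, n_sims, n_retained, density, posterior
    chosen: str
    method: str

    def posterior(self, model: str) -> float:
        row = self.table[self.table["model"] == model]
        return float(row["posterior"].iloc[0])


def abc_model_choice(observed: np.ndarray, sims: dict, retain_fraction: float
                     = 0.01, method: str = "glm", n_components: int = 9,
                     reducer: PLSReducer | None = None,
                     rng: np.random.Generator | None = None) -> ABCResult:
    """Posterior model probabilities for one observed summary vector.

    ``sims`` maps model name -> (stats 2D array, params 2D array or None).
    Simulation counts are equalized by subsampling before anything else.
    After PLS-DA reduction (fitted here unless a ``reducer`` is supplied):

    * ``rejection``: the globally nearest ``retain_fraction`` simulations
      (Euclidean distance in PLS space) vote; posterior = vote share.
    * ``glm``: per model, the nearest retain_fraction simulations within
      that model are kept and a linear-Gaussian regression of transformed
      stats on parameters is fitted (Leuenberger-Wegmann); the marginal
      density of the observed vector under that fitted model, averaged over
      the retained parameter draws, is multiplied by an equal model prior
      and normalized.
    """
    if method not in ("rejection", "glm"):
        raise ValueError(f"unknown method {method!r}")
    names = list(sims)
    if len(names) == 1:
        n = np.asarray(sims[names[0]][0]).shape[0]
        table = pd.DataFrame({"model": names, "n_sims": n, "n_retained": n,
                              "density": np.nan, "posterior": 1.0})
        return ABCResult(table, names[0], method)
    n_min = min(np.asarray(s).shape[0] for s, _ in sims.values())
    if n_min < 1:
        raise ValueError("empty simulation table")
    eq = {}
    for name in names:
        S, P = sims[name]
        S = np.asarray(S, dtype=float)
        if S.shape[0] > n_min:
            if rng is None:
                idx = np.arange(n_min)
            else:
                idx = rng.choice(S.shape[0], n_min, replace=False)
            S = S[idx]
            P = None if P is None else np.asarray(P, dtype=float)[idx]
        eq[name] = (S, None if P is None else np.asarray(P, dtype=float))

    pooled = np.vstack([eq[n][0] for n in names])
    labels = np.concatenate([np.repeat(n, n_min) for n in names])
    if reducer is None:
        reducer, Zs = pls_reduce(pooled, labels, n_components)
    else:
        Zs = reducer.transform(pooled)
    z_obs = reducer.transform(np.asarray(observed, dtype=float))[0]

    if method == "rejection":
        k = max(1, int(np.ceil(retain_fraction * len(Zs))))
        dist = np.linalg.norm(Zs - z_obs, axis=1)
        nearest = labels[np.argsort(dist, kind="stable")[:k]]
        counts = np.array([(nearest == n).sum() for n in names], dtype=float)
        post = counts / counts.sum()
        table = pd.DataFrame({"model": names, "n_sims": n_min,
                              "n_retained": counts.astype(int),
                              "density": np.nan, "posterior": post})
        return ABCResult(table, names[int(post.argmax())], method)

    log_densities, retained_counts = [], []
    for mi, name in enumerate(names):
        Zm = Zs[mi * n_min:(mi + 1) * n_min]
        Pm = eq[name][1]
        if Pm is None:
            raise ValueError(f"GLM method needs parameters for {name}")
        # retain at least enough draws to identify the regression
        floor = Zs.shape[1] + Pm.shape[1] + 5
        k = min(n_min, max(floor, int(np.ceil(retain_fraction * n_min))))
        dist = np.linalg.norm(Zm - z_obs, axis=1)
        idx = np.argsort(dist, kind="stable")[:k]
        log_densities.append(_glm_log_marginal_density(Zm[idx], Pm[idx],
                                                       z_obs))
        retained_counts.append(k)
    logd = np.array(log_densities)
    finite = np.isfinite(logd)
    if not finite.any():
        import warnings

        warnings.warn("no finite GLM density; returning uniform posterior")
        post = np.full(len(names), 1.0 / len(names))
        dens = np.zeros(len(names))
    else:
        shift = logd[finite].max()
        dens = np.where(finite, np.exp(np.clip(logd - shift, -700, 0)), 0.0)
        post = dens / dens.sum()
    table = pd.DataFrame({"model": names, "n_sims": n_min,
                          "n_retained": retained_counts, "density": dens,
                          "posterior": post})
    return ABCResult(table, names[int(post.argmax())], method)


def _glm_log_marginal_density(Z: np.ndarray, P: np.ndarray,
                              z_obs: np.ndarray,
                              ridge: float = 1e-8) -> float:
    """Log of the mean Gaussian density of z_obs under s = c + C*theta + eps.

    Parameters are standardized before the least-squares fit; the residual
    covariance gets a ridge term for numerical stability. The marginal
    density integrates over the retained parameter draws (their empirical
    distribution approximates the truncated prior); everything stays in
    log space so models are comparable even when all densities underflow.
    """
    P = np.asarray(P, dtype=float)
    p_sd = P.std(axis=0, ddof=0)
    p_keep = p_sd > 0
    Pz = (P[:, p_keep] - P[:, p_keep].mean(axis=0)) / p_sd[p_keep] \
        if p_keep.any() else np.empty((len(P), 0))
    X = np.column_stack([np.ones(len(P)), Pz])
    XtX = X.T @ X + ridge * np.eye(X.shape[1])
    beta = np.linalg.solve(XtX, X.T @ Z)
    pred = X @ beta
    resid = Z - pred
    cov = resid.T @ resid / max(len(Z) - X.shape[1], 1)
    cov += ridge * np.eye(cov.shape[0])
    # log-density of z_obs under N(pred_j, cov), averaged over j
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov += 1e-6 * max(np.trace(cov), 1.0) * np.eye(cov.shape[0])
        L = np.linalg.cholesky(cov)
    diff = z_obs[None, :] - pred
    sol = np.linalg.solve(L, diff.T)
    mahal = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    d = cov.shape[0]
    logphi = -0.5 * (mahal + logdet + d * np.log(2.0 * np.pi))
    mx = logphi.max()
    return float(mx + np.log(np.mean(np.exp(logphi - mx))))


def validate_model_choice(registry: dict[str, DemographicModel],
                          n_pods_per_model: int, n_sims_per_model: int,
                          seed: int, sample_sizes: dict[str, int] | None = None,
                          n_loci: int = 30, locus_bp: int = 2000,
                          retain_fraction: float = 0.05,
                          n_components: int = 9, method: str = "rejection",
                          ) -> dict:
    """Confusion-matrix validation of the model-choice machinery.

    For every registry model, pseudo-observed datasets simulated from prior
    draws are pushed through :func:`abc_model_choice`; the argmax model is
    tabulated. Returns ``{"confusion": DataFrame, "recovery": Series,
    "reference_tables": ...}``. Scale parameters default to a desk-scale
    budget (30 loci x 2 kb, 5 diploids per deme).
    """
    sample_sizes = sample_sizes or {d: 5 for d in INGROUP_DEMES}
    rng = np.random.default_rng(seed)
    names = list(registry)

    tables = {}
    for name in names:
        model = registry[name]
        params = draw_priors(model, n_sims_per_model,
                             int(rng.integers(1, 2**31 - 1)))
        stats = np.empty((n_sims_per_model, len(summary_stat_names())))
        for i in range(n_sims_per_model):
            ds = simulate_dataset(model, params.iloc[i].to_dict(),
                                  sample_sizes, n_loci, locus_bp,
                                  int(rng.integers(1, 2**31 - 1)))
            stats[i] = summarize(summary_input_from_dataset(ds))
        tables[name] = (stats, params.to_numpy())

    if len(names) > 1:
        pooled = np.vstack([tables[n][0] for n in names])
        labels = np.concatenate([np.repeat(n, n_sims_per_model)
                                 for n in names])
        reducer, _ = pls_reduce(pooled, labels, n_components)
    else:
        reducer = None

    confusion = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        model = registry[name]
        params = draw_priors(model, n_pods_per_model,
                             int(rng.integers(1, 2**31 - 1)))
        for i in range(n_pods_per_model):
            ds = simulate_dataset(model, params.iloc[i].to_dict(),
                                  sample_sizes, n_loci, locus_bp,
                                  int(rng.integers(1, 2**31 - 1)))
            obs = summarize(summary_input_from_dataset(ds))
            res = abc_model_choice(obs, tables, retain_fraction, method,
                                   n_components, reducer=reducer)
            confusion.loc[name, res.chosen] += 1
    recovery = pd.Series(np.diag(confusion) / n_pods_per_model, index=names,
                         name="recovery")
    return {"confusion": confusion, "recovery": recovery,
            "reference_tables": tables, "reducer": reducer}
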