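"""Windowed diversity and divergence statistics.

Per-window nucleotide diversity (theta_pi), Tajima's D, absolute divergence
(dxy), FST (Weir–Cockerham 1984 and Hudson), per-population heterozygosity
and LD decay. Per-bp quantities divide by the full window length in bp —
non-variant positions are assumed monomorphic and accessible, matching the
behaviour of VCFtools-style windowed scans.

Site-level kernels (``site_pi``, ``site_dxy``, FST components) are shared
with the coalescent summary-statistic code so the empirical and simulated
pipelines use a single definition of every statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popio import MISSING, PopulationMap, VariantTable, allele_freqs

__all__ = [
    "site_pi",
    "site_dxy",
    "tajima_constants",
    "tajimas_d_from_sums",
    "theta_pi_window",
    "tajimas_d_window",
    "dxy_window",
    "fst_window",
    "wc_fst_components",
    "hudson_fst_components",
    "heterozygosity",
    "ld_decay",
]


# ---------------------------------------------------------------------------
# site-level kernels

def site_pi(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2p(1-p) * n/(n-1) (unbiased pairwise diversity).

    Sites with fewer than 2 haplotypes contribute 0.
    """
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        val = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return np.where(n >= 2, np.nan_to_num(val), 0.0)


def site_dxy(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Per-site between-population mismatch probability pA(1-pB)+pB(1-pA)."""
    return pa * (1.0 - pb) + pb * (1.0 - pa)


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalizing constants for n sampled haplotypes."""
    if n < 3:
        raise ValueError("Tajima's D needs >= 3 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d_from_sums(k_hat: float, S: int, n: int) -> float:
    """Tajima's D from mean pairwise differences, segregating sites and n."""
    if S < 1:
        return np.nan
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    if var <= 0:
        return np.nan
    return (k_hat - S / c["a1"]) / np.sqrt(var)


# ---------------------------------------------------------------------------
# windowed accumulation helper

def _window_slices(vt: VariantTable, windows: pd.DataFrame):
    """Yield (row_index, site_slice) pairs mapping windows to site ranges."""
    for c in windows["chrom"].unique():
        cmask = vt.chrom == c
        offset = int(np.flatnonzero(cmask)[0]) if cmask.any() else 0
        pos = vt.pos[cmask]
        sub = windows[windows["chrom"] == c]
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        for row, a, b in zip(sub.index, lo, hi):
            yield row, slice(offset + a, offset + b)


def theta_pi_window(vt: VariantTable, pm: PopulationMap, population: str,
                    windows: pd.DataFrame) -> pd.DataFrame:
    """Window nucleotide diversity: sum of per-site pi over window length."""
    fv = allele_freqs(vt, pm, population)
    pi = site_pi(fv.p, fv.n)
    out = windows.copy()
    vals = np.zeros(len(windows))
    for row, sl in _window_slices(vt, windows):
        length = out.at[row, "end"] - out.at[row, "start"] + 1
        vals[out.index.get_loc(row)] = pi[sl].sum() / length
    out["theta_pi"] = vals
    return out


def tajimas_d_window(vt: VariantTable, pm: PopulationMap, population: str,
                     windows: pd.DataFrame) -> pd.DataFrame:
    """Window Tajima's D.

    Constants use the window's modal non-missing haplotype count; sites with
    other counts still contribute their own frequencies to S and pairwise
    differences. Windows with S=0 (or fewer than 3 modal haplotypes) carry
    NaN — undefined, not zero.
    """
    fv = allele_freqs(vt, pm, population)
    seg = (fv.n > 0) & (fv.p > 0) & (fv.p < 1)
    pi = site_pi(fv.p, fv.n)
    out = windows.copy()
    vals = np.full(len(windows), np.nan)
    for row, sl in _window_slices(vt, windows):
        i = out.index.get_loc(row)
        S = int(seg[sl].sum())
        if S < 1:
            continue
        n_seg = fv.n[sl][seg[sl]]
        counts = np.bincount(n_seg)
        n_modal = int(counts.argmax())
        if n_modal < 3:
            continue
        vals[i] = tajimas_d_from_sums(float(pi[sl].sum()), S, n_modal)
    out["tajimas_d"] = vals
    return out


def dxy_window(vt: VariantTable, pm: PopulationMap, pop_a: str, pop_b: str,
               windows: pd.DataFrame) -> pd.DataFrame:
    """Window mean pairwise divergence between two populations (per bp)."""
    fa = allele_freqs(vt, pm, pop_a)
    fb = allele_freqs(vt, pm, pop_b)
    ok = (fa.n > 0) & (fb.n > 0)
    d = np.where(ok, site_dxy(np.nan_to_num(fa.p), np.nan_to_num(fb.p)), 0.0)
    out = windows.copy()
    vals = np.zeros(len(windows))
    for row, sl in _window_slices(vt, windows):
        length = out.at[row, "end"] - out.at[row, "start"] + 1
        vals[out.index.get_loc(row)] = d[sl].sum() / length
    out["dxy"] = vals
    return out


# ---------------------------------------------------------------------------
# FST

def wc_fst_components(alt_a, n_a, het_a, alt_b, n_b, het_b):
    """Weir & Cockerham (1984) variance components a, b, c per site.

    Inputs are per-site alt-allele counts, non-missing haplotype counts and
    observed heterozygote fractions for the two populations. Returns the
    among-population (a), among-individual (b) and within-individual (c)
    components; FST = sum(a) / sum(a+b+c).
    """
    r = 2.0
    n1, n2 = n_a / 2.0, n_b / 2.0  # individuals
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt_a / n_a
        p2 = alt_b / n_b
        nbar = (n1 + n2) / r
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        ssq = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * het_a + n2 * het_b) / (r * nbar)
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        a = (nbar / nc) * (
            ssq
            - (pbar * (1.0 - pbar) - (r - 1.0) / r * ssq - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - (r - 1.0) / r * ssq
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    ok = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    z = np.zeros_like(np.asarray(a, dtype=float))
    return (np.where(ok, np.nan_to_num(a), z),
            np.where(ok, np.nan_to_num(b), z),
            np.where(ok, np.nan_to_num(c), z))


def hudson_fst_components(pa, n_a, pb, n_b):
    """Hudson FST numerator/denominator per site.

    The plain frequency contrast: num = (pA-pB)^2, den = pA(1-pB)+pB(1-pA),
    so identical frequency vectors give exactly 0 and fixed differences
    give exactly 1. (The Weir-Cockerham estimator carries the finite-sample
    correction; Hudson here is the definitional form.)
    """
    num = (pa - pb) ** 2
    den = site_dxy(pa, pb)
    ok = (n_a >= 1) & (n_b >= 1)
    return (np.where(ok, np.nan_to_num(num), 0.0),
            np.where(ok, np.nan_to_num(den), 0.0))


def fst_window(vt: VariantTable, pm: PopulationMap, pop_a: str, pop_b: str,
               windows: pd.DataFrame, estimator: str = "weir-cockerham",
               ) -> pd.DataFrame:
    """Window FST as a ratio of per-site component sums (weighted estimate).

    ``estimator`` is ``weir-cockerham`` (VCFtools' weighted convention) or
    ``hudson``. Windows whose denominator sums to zero carry NaN. Negative
    values are reported as computed, not clamped.
    """
    if estimator not in ("weir-cockerham", "hudson"):
        raise ValueError(f"unknown estimator {estimator!r}")
    ia = vt.sample_indices(pm.samples_for(pop_a))
    ib = vt.sample_indices(pm.samples_for(pop_b))
    num, den = _fst_site_terms(vt.genotypes, ia, ib, estimator)
    out = windows.copy()
    vals = np.full(len(windows), np.nan)
    for row, sl in _window_slices(vt, windows):
        i = out.index.get_loc(row)
        d = den[sl].sum()
        if d != 0:
            vals[i] = num[sl].sum() / d
    out["fst"] = vals
    return out


def _fst_site_terms(genotypes, idx_a, idx_b, estimator):
    ga, gb = genotypes[:, idx_a], genotypes[:, idx_b]
    ma, mb = ga == MISSING, gb == MISSING
    n_a = 2.0 * (~ma).sum(axis=1)
    n_b = 2.0 * (~mb).sum(axis=1)
    alt_a = np.where(ma, 0, ga).sum(axis=1).astype(float)
    alt_b = np.where(mb, 0, gb).sum(axis=1).astype(float)
    if estimator == "hudson":
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = np.where(n_a > 0, alt_a / np.maximum(n_a, 1), np.nan)
            pb = np.where(n_b > 0, alt_b / np.maximum(n_b, 1), np.nan)
        return hudson_fst_components(pa, n_a, pb, n_b)
    het_a = _het_fraction(ga, ma)
    het_b = _het_fraction(gb, mb)
    a, b, c = wc_fst_components(alt_a, n_a, het_a, alt_b, n_b, het_b)
    return a, a + b + c


def _het_fraction(g, missing):
    called = (~missing).sum(axis=1)
    het = ((g == 1) & ~missing).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / np.maximum(called, 1), 0.0)


# ---------------------------------------------------------------------------
# heterozygosity and LD

def heterozygosity(vt: VariantTable, pm: PopulationMap) -> pd.DataFrame:
    """Observed and expected heterozygosity per population.

    H_O: fraction of heterozygous genotypes among non-missing calls,
    averaged over sites. H_E: 2p(1-p) * 2n/(2n-1) (small-sample corrected,
    n = diploid individuals called), averaged over sites.
    """
    rows = []
    for pop in pm.populations():
        idx = vt.sample_indices(pm.samples_for(pop))
        g = vt.genotypes[:, idx]
        miss = g == MISSING
        called = (~miss).sum(axis=1)
        ok = called > 0
        het = ((g == 1) & ~miss).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = het[ok] / called[ok]
            nh = 2.0 * called[ok]  # haplotypes
            p = np.where(miss, 0, g)[ok].sum(axis=1) / nh
            he = 2.0 * p * (1.0 - p) * nh / (nh - 1.0)
            he = np.where(nh >= 2, he, 0.0)
        rows.append((pop, float(ho.mean()) if ok.any() else np.nan,
                     float(he.mean()) if ok.any() else np.nan))
    return pd.DataFrame(rows, columns=["population", "H_O", "H_E"])


def ld_decay(vt: VariantTable, pm: PopulationMap, population: str,
             max_dist_bp: int = 500_000, bin_width_bp: int = 10_000,
             haplotypes: np.ndarray | None = None) -> pd.DataFrame:
    """Mean r-squared between SNP pairs binned by physical distance.

    Unphased mode (default) uses the composite genotype correlation: r is
    the Pearson correlation of the two 0/1/2 genotype columns over samples
    called at both sites. When ``haplotypes`` (sites x haplotypes 0/1) is
    given, r^2 = D^2 / (p(1-p)q(1-q)) from haplotype frequencies.

    Returns a DataFrame with bin_lo, bin_hi (bp, half-open), mean_r2, n_pairs.
    """
    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)

    if haplotypes is None:
        idx = vt.sample_indices(pm.samples_for(population))
        mat = vt.genotypes[:, idx].astype(float)
        mat[vt.genotypes[:, idx] == MISSING] = np.nan
    else:
        mat = np.asarray(haplotypes, dtype=float)

    for c in vt.chromosomes():
        cmask = vt.chrom == c
        pos = vt.pos[cmask]
        sub = mat[cmask]
        for i in range(len(pos)):
            j_hi = np.searchsorted(pos, pos[i] + max_dist_bp, side="right")
            for j in range(i + 1, j_hi):
                r2 = _pair_r2(sub[i], sub[j], phased=haplotypes is not None)
                if np.isnan(r2):
                    continue
                b = min(int((pos[j] - pos[i]) // bin_width_bp), len(sums) - 1)
                sums[b] += r2
                counts[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:],
                         "mean_r2": mean, "n_pairs": counts})


def _pair_r2(x: np.ndarray, y: np.ndarray, phased: bool) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    x, y = x[ok], y[ok]
    if phased:
        pa, pb = x.mean(), y.mean()
        if pa in (0.0, 1.0) or pb in (0.0, 1.0):
            return np.nan
        d = (x * y).mean() - pa * pb
        return d * d / (pa * (1 - pa) * pb * (1 - pb))
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return np.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return cov * cov / (vx * vy)
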