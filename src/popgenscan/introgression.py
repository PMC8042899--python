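"""ABBA/BABA D-statistic, f3 three-population test, fd window scan and
introgressed-region calling with dxy/FST verification.

All statistics are frequency-based on a four-taxon tree (((P1,P2),P3),O):
after outgroup polarization, each usable site contributes

    abba = (1-p1) * p2 * p3        baba = p1 * (1-p2) * p3

(the outgroup derived frequency is 0 by construction). Genome-wide
significance comes from a weighted delete-one block jackknife over
contiguous coordinate blocks (2 Mb by default, the scale at which linkage
is safely broken).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diversity
from .popio import (PopulationMap, VariantTable, allele_freqs, derived_freqs,
                    polarize)

__all__ = [
    "SitePatterns",
    "JackknifeResult",
    "site_patterns",
    "patterson_d",
    "f3_test",
    "fd_scan",
    "call_introgressed_regions",
    "verify_region",
    "weighted_block_jackknife",
    "assign_blocks",
]


@dataclass
class SitePatterns:
    """Per-site ABBA/BABA terms for one population quartet."""

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    abba: np.ndarray
    baba: np.ndarray
    n_excluded: int  # sites dropped (outgroup unusable or a pop fully missing)


@dataclass
class JackknifeResult:
    """A genome-wide ratio estimate with block-jackknife uncertainty."""

    estimate: float
    se: float
    z: float
    n_blocks: int
    block_size_bp: int
    block_weights: np.ndarray
    delete_one: np.ndarray


def site_patterns(vt: VariantTable, pm: PopulationMap, p1: str, p2: str,
                  p3: str, outgroup: str, mode: str = "frequency",
                  ) -> SitePatterns:
    """ABBA/BABA terms at every polarizable site.

    ``mode='frequency'`` uses population derived-allele frequencies;
    ``mode='count'`` rounds each population to its majority allele
    (pseudo-haploid pattern counting, the oracle mode for haploid fixtures).
    Sites where the outgroup is polymorphic/missing or any P-population is
    entirely missing are excluded (and counted).
    """
    pops = [p1, p2, p3]
    sample_sets = [set(pm.samples_for(p)) for p in pops]
    for i in range(3):
        for j in range(i + 1, 3):
            if sample_sets[i] & sample_sets[j]:
                raise ValueError(f"populations {pops[i]} and {pops[j]} share samples")
    pol = polarize(vt, pm, outgroup)
    f1 = derived_freqs(vt, pm, p1, pol)
    f2 = derived_freqs(vt, pm, p2, pol)
    f3_ = derived_freqs(vt, pm, p3, pol)
    ok = pol.usable & (f1.n > 0) & (f2.n > 0) & (f3_.n > 0)
    q1, q2, q3 = f1.p[ok], f2.p[ok], f3_.p[ok]
    if mode == "count":
        q1, q2, q3 = (np.round(q) for q in (q1, q2, q3))
    elif mode != "frequency":
        raise ValueError(f"unknown mode {mode!r}")
    abba = (1.0 - q1) * q2 * q3
    baba = q1 * (1.0 - q2) * q3
    return SitePatterns(
        chrom=vt.chrom[ok], pos=vt.pos[ok], p1=q1, p2=q2, p3=q3,
        abba=abba, baba=baba, n_excluded=int((~ok).sum()),
    )


def assign_blocks(chrom: np.ndarray, pos: np.ndarray, block_size_bp: int,
                  ) -> np.ndarray:
    """Label sites by contiguous non-overlapping coordinate blocks.

    Blocks are ``[k*B+1, (k+1)*B]`` per chromosome (last one truncated);
    labels are consecutive integers over non-empty blocks, genome order.
    """
    labels = np.empty(len(pos), dtype=np.int64)
    nxt = 0
    for c in pd.unique(chrom):
        m = chrom == c
        raw = (pos[m] - 1) // block_size_bp
        uniq, inv = np.unique(raw, return_inverse=True)
        labels[m] = inv + nxt
        nxt += len(uniq)
    return labels


def weighted_block_jackknife(num: np.ndarray, den: np.ndarray,
                             blocks: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Weighted delete-one-block jackknife for a ratio estimator.

    The estimator is ``theta = sum(num)/sum(den)``; block j's weight is its
    share of the denominator mass, ``m_j = sum(den in j)``. The variance is
    the Busing et al. (1999) weighted delete-one estimate (the AdmixTools
    convention): with g blocks, n = sum(m_j), h_j = n/m_j and pseudovalues
    ``tau_j = h_j*theta - (h_j - 1)*theta_{-j}``,

        theta_J = g*theta - sum_j (1 - m_j/n) * theta_{-j}
        var     = (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1)

    which reduces to the classical delete-one jackknife for equal weights.
    Returns (estimate, se, delete_one_estimates, block_weights).
    """
    total_num = float(num.sum())
    total_den = float(den.sum())
    if total_den == 0:
        raise ZeroDivisionError("all sites uninformative (zero denominator)")
    theta = total_num / total_den
    uniq = np.unique(blocks)
    g = len(uniq)
    if g < 2:
        raise ValueError("need >= 2 non-empty blocks for the jackknife")
    bnum = np.array([num[blocks == b].sum() for b in uniq])
    bden = np.array([den[blocks == b].sum() for b in uniq])
    keep = bden > 0
    bnum, bden = bnum[keep], bden[keep]
    g = len(bnum)
    loo = (total_num - bnum) / (total_den - bden)
    m = bden
    n = total_den
    h = n / m
    theta_j = g * theta - float(np.sum((1.0 - m / n) * loo))
    tau = h * theta - (h - 1.0) * loo
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g)
    return theta, float(np.sqrt(var)), loo, m


def patterson_d(patterns: SitePatterns, block_size_bp: int = 2_000_000,
                ) -> JackknifeResult:
    """Genome-wide Patterson's D with weighted 2-Mb block-jackknife Z.

    D = sum(abba - baba) / sum(abba + baba). SE comes from the weighted
    delete-one-block jackknife with block weight = informative-site mass
    sum(abba+baba); Z = D/SE (infinite when the between-block variance
    vanishes, flagged by SE=0).
    """
    num = patterns.abba - patterns.baba
    den = patterns.abba + patterns.baba
    blocks = assign_blocks(patterns.chrom, patterns.pos, block_size_bp)
    d, se, loo, w = weighted_block_jackknife(num, den, blocks)
    z = np.inf * np.sign(d) if se == 0 else d / se
    return JackknifeResult(estimate=d, se=se, z=float(z), n_blocks=len(w),
                           block_size_bp=block_size_bp, block_weights=w,
                           delete_one=loo)


def f3_test(vt: VariantTable, pm: PopulationMap, target: str, source_b: str,
            source_c: str, block_size_bp: int = 2_000_000) -> JackknifeResult:
    """f3(target; B, C) with finite-sample correction and jackknife Z.

    Per usable site, t = (pA-pB)(pA-pC) - hA/nA with
    hA = pA(1-pA) * nA/(nA-1); f3 is the mean of t over sites. A
    significantly negative Z (<= -2 in the study design) indicates the
    target is admixed between sources related to B and C. Symmetric in
    (B, C); unscaled (no heterozygosity normalization).
    """
    fa = allele_freqs(vt, pm, target)
    fb = allele_freqs(vt, pm, source_b)
    fc = allele_freqs(vt, pm, source_c)
    ok = (fa.n >= 2) & (fb.n > 0) & (fc.n > 0)
    if not ok.any():
        raise ValueError("no site with >= 2 target haplotypes")
    pa, pb, pc = fa.p[ok], fb.p[ok], fc.p[ok]
    na = fa.n[ok]
    ha = pa * (1.0 - pa) * na / (na - 1.0)
    t = (pa - pb) * (pa - pc) - ha / na
    blocks = assign_blocks(vt.chrom[ok], vt.pos[ok], block_size_bp)
    est, se, loo, w = weighted_block_jackknife(t, np.ones_like(t), blocks)
    z = np.inf * np.sign(est) if se == 0 else est / se
    return JackknifeResult(estimate=est, se=se, z=float(z), n_blocks=len(w),
                           block_size_bp=block_size_bp, block_weights=w,
                           delete_one=loo)


def fd_scan(patterns: SitePatterns, windows: pd.DataFrame,
            min_snps: int = 100, negative_d: str = "zero") -> pd.DataFrame:
    """Windowed fd statistic (Martin et al. 2015 dynamic-donor estimator).

    Per window, numerator = sum(abba - baba); the denominator replaces both
    P2 and P3 by the per-site donor proxy pD = max(p2, p3). fd = num/den
    when num > 0; non-positive-D windows get fd = 0 (``negative_d='zero'``)
    or NaN (``'nan'``). Windows under ``min_snps`` pattern sites are flagged
    excluded. Returns windows plus columns n_pattern_snps, d_window, fd.
    """
    pD = np.maximum(patterns.p2, patterns.p3)
    abba_d = (1.0 - patterns.p1) * pD * pD
    baba_d = patterns.p1 * (1.0 - pD) * pD
    num_site = patterns.abba - patterns.baba
    den_d_site = abba_d - baba_d
    den_site = patterns.abba + patterns.baba

    out = windows.copy()
    n_snp = np.zeros(len(out), dtype=np.int64)
    dwin = np.full(len(out), np.nan)
    fd = np.full(len(out), np.nan)
    for c in out["chrom"].unique():
        m = patterns.chrom == c
        pos = patterns.pos[m]
        sub = out[out["chrom"] == c]
        lo = np.searchsorted(pos, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, sub["end"].to_numpy(), side="right")
        for row, a, b in zip(sub.index, lo, hi):
            i = out.index.get_loc(row)
            n_snp[i] = b - a
            sl = np.flatnonzero(m)[a:b] if b > a else slice(0, 0)
            num = num_site[sl].sum()
            den = den_site[sl].sum()
            dwin[i] = num / den if den > 0 else np.nan
            if num <= 0:
                fd[i] = 0.0 if negative_d == "zero" else np.nan
            else:
                dend = den_d_site[sl].sum()
                fd[i] = num / dend if dend > 0 else np.nan
    out["n_pattern_snps"] = n_snp
    out["d_window"] = dwin
    out["fd"] = fd
    out["excluded"] = out["excluded"] | (out["n_pattern_snps"] < min_snps)
    return out


def call_introgressed_regions(fd_windows: pd.DataFrame,
                              fd_threshold: float = 0.5,
                              min_region_bp: int = 200_000) -> pd.DataFrame:
    """Merge fd-passing windows into candidate introgressed regions.

    Windows with fd >= threshold (and not excluded) are merged when they
    overlap or are bookended; merged spans shorter than ``min_region_bp``
    are dropped. Returns chrom, start, end, n_windows, peak_fd, mean_fd.
    """
    passing = fd_windows[(~fd_windows["excluded"])
                         & (fd_windows["fd"] >= fd_threshold)]
    rows = []
    for c, sub in passing.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, w in sub.iterrows():
            if cur is None or w["start"] > cur["end"] + 1:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": c, "start": int(w["start"]),
                       "end": int(w["end"]), "n_windows": 1,
                       "peak_fd": float(w["fd"]), "fd_sum": float(w["fd"])}
            else:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["n_windows"] += 1
                cur["peak_fd"] = max(cur["peak_fd"], float(w["fd"]))
                cur["fd_sum"] += float(w["fd"])
        if cur is not None:
            rows.append(cur)
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                          "n_windows", "peak_fd", "fd_sum"])
    if len(regions):
        regions["mean_fd"] = regions["fd_sum"] / regions["n_windows"]
        regions = regions[(regions["end"] - regions["start"] + 1)
                          >= min_region_bp]
    else:
        regions["mean_fd"] = pd.Series(dtype=float)
    return regions.drop(columns="fd_sum").reset_index(drop=True)


def verify_region(region, vt: VariantTable, pm: PopulationMap,
                  recipient: str, donor_group: str, control_group: str,
                  window_size_bp: int | None = None) -> dict:
    """Contrast a candidate region's dxy/FST against the genome background.

    Recent gene flow lowers dxy(recipient, donor) inside the region relative
    to the genome-wide distribution of same-size windows, while shared
    ancestral polymorphism does not; FST shows the mirrored contrast. The
    background is every non-overlapping window of the region's size.

    Returns a dict with region values, background mean/sd and z-scores for
    dxy and FST against both the donor and the control group.
    """
    chrom, start, end = region["chrom"], int(region["start"]), int(region["end"])
    size = window_size_bp or (end - start + 1)
    from .popio import make_windows

    bg = make_windows(vt, size, size)
    reg = pd.DataFrame([{"chrom": chrom, "start": start, "end": end,
                         "n_snps": 0, "excluded": False}])
    out = {"chrom": chrom, "start": start, "end": end}
    for label, other in (("donor", donor_group), ("control", control_group)):
        for stat, fn in (("dxy", diversity.dxy_window),
                         ("fst", diversity.fst_window)):
            bg_vals = fn(vt, pm, recipient, other, bg)[stat].to_numpy()
            bg_vals = bg_vals[np.isfinite(bg_vals)]
            val = float(fn(vt, pm, recipient, other, reg)[stat].iloc[0])
            mu, sd = float(bg_vals.mean()), float(bg_vals.std(ddof=1))
            out[f"{stat}_{label}"] = val
            out[f"{stat}_{label}_bg_mean"] = mu
            out[f"{stat}_{label}_bg_sd"] = sd
            out[f"{stat}_{label}_z"] = (val - mu) / sd if sd > 0 else np.nan
    return out
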