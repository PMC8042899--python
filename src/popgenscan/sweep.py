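"""Joint theta_pi-ratio / Z(FST) selective-sweep scan.

Contrasts a wild against a domestic group in 40-kb/10-kb sliding windows:
windows in the upper tail of BOTH the log2(theta_pi_wild / theta_pi_dom)
distribution and the Z-transformed FST distribution (top 5% by default) are
called sweep candidates, then merged and annotated with overlapping genes.
Thresholds are empirical quantiles of the data at hand — the study's
printed cutoffs (log2 ratio 0.69, Z(FST) 1.86) are properties of its real
dataset, not constants of the method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import fst_window, tajimas_d_window, theta_pi_window
from .popio import PopulationMap, VariantTable

__all__ = ["sweep_scan", "merge_and_annotate"]


def sweep_scan(vt: VariantTable, pm: PopulationMap, wild_pop: str,
               domestic_pop: str, windows: pd.DataFrame,
               quantile: float = 0.95, min_snps: int = 10,
               fst_estimator: str = "weir-cockerham",
               with_tajimas_d: bool = True) -> pd.DataFrame:
    """Per-window sweep statistics and joint top-tail outlier calls.

    A window is ``included`` when it has >= min_snps SNPs and
    theta_pi_domestic > 0 (windows where the domestic group is invariant
    are flagged ``fixed_in_domestic`` instead of entering the ratio
    distribution). Over included windows, z_fst standardizes FST to mean 0
    / SD 1 and the outlier flag requires BOTH log2_pi_ratio and z_fst at or
    above their empirical ``quantile`` upper quantiles.

    Tajima's D (both groups) is reported alongside for plotting but plays
    no part in the outlier criterion.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0,1)")
    out = theta_pi_window(vt, pm, wild_pop, windows).rename(
        columns={"theta_pi": "theta_pi_wild"})
    out["theta_pi_dom"] = theta_pi_window(
        vt, pm, domestic_pop, windows)["theta_pi"].to_numpy()
    out["fst"] = fst_window(vt, pm, wild_pop, domestic_pop, windows,
                            estimator=fst_estimator)["fst"].to_numpy()
    if with_tajimas_d:
        out["tajimas_d_wild"] = tajimas_d_window(
            vt, pm, wild_pop, windows)["tajimas_d"].to_numpy()
        out["tajimas_d_dom"] = tajimas_d_window(
            vt, pm, domestic_pop, windows)["tajimas_d"].to_numpy()

    enough = (out["n_snps"] >= min_snps) & ~out["excluded"]
    out["fixed_in_domestic"] = enough & (out["theta_pi_dom"] == 0)
    included = (enough & (out["theta_pi_dom"] > 0)
                & (out["theta_pi_wild"] > 0) & np.isfinite(out["fst"]))
    out["included"] = included
    if included.sum() < 20:
        raise ValueError("fewer than 20 usable windows; quantiles meaningless")

    ratio = np.full(len(out), np.nan)
    inc = included.to_numpy()
    ratio[inc] = np.log2(out.loc[included, "theta_pi_wild"].to_numpy()
                         / out.loc[included, "theta_pi_dom"].to_numpy())
    out["log2_pi_ratio"] = ratio

    fst = out["fst"].to_numpy(dtype=float)
    mu = fst[inc].mean()
    sd = fst[inc].std(ddof=0)
    z = np.full(len(out), np.nan)
    z[inc] = (fst[inc] - mu) / sd if sd > 0 else 0.0
    out["z_fst"] = z

    ratio_cut = float(np.quantile(ratio[inc], quantile))
    z_cut = float(np.quantile(z[inc], quantile))
    out["outlier"] = inc & (ratio >= ratio_cut) & (z >= z_cut)
    out.attrs["log2_pi_ratio_cutoff"] = ratio_cut
    out.attrs["z_fst_cutoff"] = z_cut
    return out


def merge_and_annotate(scan: pd.DataFrame, genes: pd.DataFrame | None = None,
                       ) -> pd.DataFrame:
    """Merge outlier windows into sweep regions and attach overlapping genes.

    Overlapping or bookended outlier windows collapse into one region; a
    gene is listed when its span intersects the region by at least 1 bp.
    ``genes`` is a DataFrame as returned by :func:`popio.read_gff_genes`.

    Returns chrom, start, end, n_windows, max_z_fst, max_log2_pi_ratio,
    genes (comma-joined gene_ids, empty string when none or no annotation).
    """
    outliers = scan[scan["outlier"]]
    rows = []
    for c, sub in outliers.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur = None
        for _, w in sub.iterrows():
            if cur is None or w["start"] > cur["end"] + 1:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": c, "start": int(w["start"]),
                       "end": int(w["end"]), "n_windows": 1,
                       "max_z_fst": float(w["z_fst"]),
                       "max_log2_pi_ratio": float(w["log2_pi_ratio"])}
            else:
                cur["end"] = max(cur["end"], int(w["end"]))
                cur["n_windows"] += 1
                cur["max_z_fst"] = max(cur["max_z_fst"], float(w["z_fst"]))
                cur["max_log2_pi_ratio"] = max(cur["max_log2_pi_ratio"],
                                               float(w["log2_pi_ratio"]))
        if cur is not None:
            rows.append(cur)
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                          "n_windows", "max_z_fst",
                                          "max_log2_pi_ratio"])
    gene_lists = []
    for _, r in regions.iterrows():
        if genes is None or genes.empty:
            gene_lists.append("")
            continue
        hit = genes[(genes["chrom"] == r["chrom"])
                    & (genes["start"] <= r["end"])
                    & (genes["end"] >= r["start"])]
        gene_lists.append(",".join(hit["gene_id"].tolist()))
    regions["genes"] = gene_lists
    return regions
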