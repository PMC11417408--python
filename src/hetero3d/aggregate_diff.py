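"""Anchor-pair aggregate maps (APA-style) and Z-score differential interactions.

APA averages O/E windows centered on anchor-pair coordinates and reports a
center/corner enrichment. Differential interactions compare two genotypes'
O/E maps pair-by-pair via a distance-stratified Z-score of the log2 ratio:
within each log-spaced distance band the ratios are standardized, so a
pair's Z measures how unusual its genotype difference is for its separation.
Negative Z = stronger in the first (WT) map, positive = stronger in the
second (mutant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hicmatrix import ContactMatrix


@dataclass
class AnchorSet:
    """Anchor intervals mapped to center bins (chrom-local indices)."""

    intervals: pd.DataFrame    # chrom, start, end (bp)
    label: str
    genome: object = None

    def center_bins(self, genome) -> pd.DataFrame:
        mids = (self.intervals["start"] + self.intervals["end"]) // 2
        rows = []
        for chrom, mid in zip(self.intervals["chrom"], mids):
            b = genome.bin_index(chrom, int(mid))
            rows.append({"chrom": chrom, "bin": b - genome.chrom_offset(chrom)})
        out = pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
        return out


def aggregate_anchor_pairs(
    oe: ContactMatrix,
    set1: AnchorSet,
    set2: AnchorSet,
    window: int = 5,
    d_range: tuple[int, int] = (10, 100),
):
    """Mean O/E window over all cross-set anchor pairs; center enrichment.

    Pairs are formed across set1 x set2 on the same chromosome (self-pairs
    excluded, duplicates collapsed) with separation within ``d_range``. The
    aggregate is the nanmean of (2W+1)^2 windows centered at each pair;
    enrichment = center cell / mean of the four 3x3 corner blocks. Pairs
    whose window leaves the chromosome are skipped and counted.
    """
    oe.require_stage("oe")
    w = window
    c1 = set1.center_bins(oe.genome)
    c2 = set2.center_bins(oe.genome)
    lo, hi = d_range
    stacks = []
    n_skipped = 0
    seen = set()
    for chrom in oe.genome.names:
        b1 = c1[c1["chrom"] == chrom]["bin"].to_numpy()
        b2 = c2[c2["chrom"] == chrom]["bin"].to_numpy()
        if b1.size == 0 or b2.size == 0:
            continue
        m = oe.data[chrom]
        n = m.shape[0]
        a, b = np.meshgrid(b1, b2, indexing="ij")
        i = np.minimum(a, b).ravel()
        j = np.maximum(a, b).ravel()
        keep = (j - i >= lo) & (j - i <= hi)
        for pi, pj in zip(i[keep], j[keep]):
            key = (chrom, int(pi), int(pj))
            if key in seen:
                continue
            seen.add(key)
            if pi - w < 0 or pj + w + 1 > n or pi + w >= pj - w:
                n_skipped += 1
                continue
            stacks.append(m[pi - w: pi + w + 1, pj - w: pj + w + 1])
    if not stacks:
        raise ValueError("aggregate_anchor_pairs: zero eligible pairs")
    agg = np.nanmean(np.stack(stacks), axis=0)
    corners = [agg[:3, :3], agg[:3, -3:], agg[-3:, :3], agg[-3:, -3:]]
    corner_mean = float(np.nanmean([np.nanmean(c) for c in corners]))
    enrichment = float(agg[w, w] / corner_mean)
    result = {
        "aggregate": agg,
        "n_pairs": len(stacks),
        "n_skipped": n_skipped,
        "enrichment": enrichment,
    }
    return result


def differential_interactions(
    oe_wt: ContactMatrix,
    oe_mut: ContactMatrix,
    d_max: int = 100,
    n_bands: int = 8,
    eps: float = 0.01,
) -> pd.DataFrame:
    """Distance-stratified Z-scores of per-pair log2 O/E ratios.

    For each doubly-unmasked pair with 1 <= separation <= ``d_max``:
    r = log2((OE_mut + eps) / (OE_wt + eps)); r is standardized within
    log-spaced distance bands (mean 0, sd 1 by construction). Returns a
    BEDPE-ready table sorted by \|z\| descending with columns chrom, bin1,
    bin2, distance, log2_ratio, z, direction.
    """
    oe_wt.require_stage("oe")
    oe_mut.require_stage("oe")
    if oe_wt.genome != oe_mut.genome:
        raise ValueError("genotype matrices live on different genomes")
    edges = np.unique(np.geomspace(1, d_max + 1, n_bands + 1).round().astype(int))
    frames = []
    for chrom in oe_wt.genome.names:
        m1 = oe_wt.data[chrom]
        m2 = oe_mut.data[chrom]
        valid = oe_wt.mask[chrom] & oe_mut.mask[chrom]
        n = m1.shape[0]
        ii, jj = np.triu_indices(n, k=1)
        keep = (jj - ii <= d_max) & valid[ii] & valid[jj]
        ii, jj = ii[keep], jj[keep]
        v1, v2 = m1[ii, jj], m2[ii, jj]
        ok = np.isfinite(v1) & np.isfinite(v2)
        ii, jj, v1, v2 = ii[ok], jj[ok], v1[ok], v2[ok]
        frames.append(pd.DataFrame({
            "chrom": chrom, "bin1": ii, "bin2": jj, "distance": jj - ii,
            "log2_ratio": np.log2((v2 + eps) / (v1 + eps)),
        }))
    table = pd.concat(frames, ignore_index=True)
    band = np.searchsorted(edges, table["distance"].to_numpy(), side="right") - 1
    table["band"] = band
    zs = np.full(len(table), np.nan)
    for b, grp in table.groupby("band"):
        r = grp["log2_ratio"].to_numpy()
        sd = r.std(ddof=0)
        if sd == 0:
            warnings.warn(f"differential_interactions: zero variance in band {b}; dropped")
            continue
        zs[grp.index] = (r - r.mean()) / sd
    table["z"] = zs
    table = table[np.isfinite(table["z"])].copy()
    table["direction"] = np.where(table["z"] < 0, "wt_specific", "mut_specific")
    table = table.sort_values("z", key=np.abs, ascending=False, kind="stable")
    return table.reset_index(drop=True).drop(columns=["band"])
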