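"""Differential mark quantification and integrative classifications.

Implements the epigenome side of the pipeline: sample scaling, per-region
log2 differential signal with up/down/no-change status, the three-class
H3K27me3 redistribution rule (class I: H3K27me3 loss with constitutive marks
gained or unchanged; class II: H3K27me3 gain with H3K9me2 and H3K27me1 loss;
class III: H3K27me3 gain with H3K27me1 loss and stable-but-low H3K9me2),
TE gene-rich/gene-poor stratification, TE superfamily composition with a
two-proportion z-test, meta-region signal heatmaps, and the DE-gene x
chromatin-state cross-tabulation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .genome import BinnedGenome
from .tracks import SignalTrack


def scale_tracks(tracks: dict[str, SignalTrack]) -> dict[str, SignalTrack]:
    """Rescale every track to genome-wide mean 1 (depth normalization)."""
    return {name: t.scaled() for name, t in tracks.items()}


def _region_bins(genome: BinnedGenome, chrom: str, start: int, end: int) -> np.ndarray:
    """Global bin ids overlapped by a bp interval."""
    length = genome.chrom_length(chrom)
    if start < 0 or end > length or end <= start:
        raise ValueError(f"region {chrom}:{start}-{end} outside genome")
    off = genome.chrom_offset(chrom)
    b0 = start // genome.bin_size
    b1 = -(-(end) // genome.bin_size)
    return np.arange(off + b0, off + b1)


def bins_as_regions(genome: BinnedGenome) -> pd.DataFrame:
    """One region per bin (region_id = global bin id)."""
    bins = genome.bins.reset_index()
    return pd.DataFrame({
        "region_id": bins["bin_id"].astype(str),
        "chrom": bins["chrom"], "start": bins["start"], "end": bins["end"],
    })


def differential_signal(
    wt: SignalTrack,
    mut: SignalTrack,
    regions: pd.DataFrame,
    t_up: float = 0.5,
    t_down: float = -0.5,
    pseudo: float = 0.1,
    center: bool = False,
) -> pd.DataFrame:
    """Per-region log2 mutant/WT signal change with status and low flag.

    ``regions`` needs columns region_id, chrom, start, end (bp). For each
    region s = mean scaled signal; delta = log2((s_mut + pseudo) /
    (s_wt + pseudo)); status is up/down/nc against the thresholds; low_flag
    marks regions where both samples sit below the 25th percentile of the
    pooled per-bin signal distribution.

    ``center=True`` subtracts the median delta across regions before the
    status call — the log-space equivalent of median-of-ratios (DESeq-style)
    normalization. Genome-mean scaling assumes total signal is conserved
    between samples, which a genome-wide mark redistribution violates;
    centering re-anchors "no change" on the unchanged majority of regions.
    """
    if wt.normalization != "scaled" or mut.normalization != "scaled":
        raise ValueError("differential_signal expects scaled tracks")
    genome = wt.genome
    low_cut = float(np.percentile(np.concatenate([wt.values, mut.values]), 25))
    rows = []
    for _, r in regions.iterrows():
        bins = _region_bins(genome, r["chrom"], int(r["start"]), int(r["end"]))
        s_wt = float(wt.values[bins].mean())
        s_mut = float(mut.values[bins].mean())
        delta = float(np.log2((s_mut + pseudo) / (s_wt + pseudo)))
        rows.append({
            "region_id": r["region_id"], "s_wt": s_wt, "s_mut": s_mut,
            "delta": delta, "low_flag": max(s_wt, s_mut) < low_cut,
        })
    table = pd.DataFrame(rows).set_index("region_id")
    if center:
        table["delta"] -= float(table["delta"].median())
    table["status"] = np.where(
        table["delta"] > t_up, "up",
        np.where(table["delta"] < t_down, "down", "nc"),
    )
    return table


def classify_redistribution(
    d_k27me3: pd.DataFrame, d_k9me2: pd.DataFrame, d_k27me1: pd.DataFrame
) -> pd.Series:
    """Three-class H3K27me3 redistribution rule, evaluated per region.

    I   : H3K27me3 down, H3K9me2 in {up, nc}, H3K27me1 in {up, nc}
    II  : H3K27me3 up,   H3K9me2 down,        H3K27me1 down
    III : H3K27me3 up,   H3K9me2 nc and low,  H3K27me1 down
    else: none.  The rule is deterministic and the classes are disjoint.
    """
    idx = d_k27me3.index
    if not (idx.equals(d_k9me2.index) and idx.equals(d_k27me1.index)):
        raise ValueError("mark tables cover different regions")
    k27me3 = d_k27me3["status"]
    k9me2 = d_k9me2["status"]
    k9low = d_k9me2["low_flag"]
    k27me1 = d_k27me1["status"]
    out = pd.Series("none", index=idx, name="class")
    is_i = (k27me3 == "down") & k9me2.isin(["up", "nc"]) & k27me1.isin(["up", "nc"])
    is_ii = (k27me3 == "up") & (k9me2 == "down") & (k27me1 == "down")
    is_iii = (k27me3 == "up") & (k9me2 == "nc") & k9low & (k27me1 == "down")
    out[is_i] = "I"
    out[is_ii & (out == "none")] = "II"
    out[is_iii & (out == "none")] = "III"
    return out


def _merged_coverage(intervals: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chrom merged (start, end) arrays plus cumulative covered bp."""
    cov = {}
    for chrom, grp in intervals.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        merged = []
        for s, e in zip(g["start"], g["end"]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        arr = np.array(merged, dtype=float).reshape(-1, 2)
        cum = np.concatenate([[0.0], np.cumsum(arr[:, 1] - arr[:, 0])])
        cov[chrom] = (arr, cum)
    return cov


def _covered_bp(cov, chrom: str, lo: float, hi: float) -> float:
    if chrom not in cov:
        return 0.0
    arr, cum = cov[chrom]
    starts, ends = arr[:, 0], arr[:, 1]
    i0 = np.searchsorted(ends, lo, side="right")
    i1 = np.searchsorted(starts, hi, side="left")
    total = 0.0
    for k in range(i0, i1):
        total += max(0.0, min(ends[k], hi) - max(starts[k], lo))
    return total


def classify_te_location(
    tes: pd.DataFrame,
    genes: pd.DataFrame,
    genome: BinnedGenome,
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Label each TE gene_rich or gene_poor by local gene density.

    Gene density = gene-covered bp fraction in the window centered on the TE
    midpoint, clipped at chromosome ends; a TE is gene_rich iff its density
    is >= the median of all per-TE densities (ties go to gene_rich).
    """
    cov = _merged_coverage(genes)
    densities = []
    for _, te in tes.iterrows():
        chrom = te["chrom"]
        mid = (int(te["start"]) + int(te["end"])) // 2
        lo = max(0, mid - window_bp // 2)
        hi = min(genome.chrom_length(chrom), mid + window_bp // 2)
        densities.append(_covered_bp(cov, chrom, lo, hi) / (hi - lo))
    out = tes.copy()
    out["gene_density"] = densities
    median = float(np.median(densities))
    out["location_class"] = np.where(
        out["gene_density"] >= median, "gene_rich", "gene_poor"
    )
    return out


def superfamily_composition(
    te_subset: pd.DataFrame, te_genome: pd.DataFrame
) -> pd.DataFrame:
    """Per-superfamily proportions in a TE subset vs the whole genome,
    with a two-proportion z statistic and two-sided p per superfamily.

    Superfamilies absent from both sets are reported with z = 0, p = 1; a
    subset of size 1 triggers a small-sample warning.
    """
    if len(te_subset) == 0:
        raise ValueError("superfamily_composition: empty TE subset")
    if len(te_subset) < 2:
        warnings.warn("superfamily_composition: subset of size 1; test unreliable")
    n_sub, n_gen = len(te_subset), len(te_genome)
    fams = sorted(set(te_genome["superfamily"]) | set(te_subset["superfamily"]))
    rows = []
    for fam in fams:
        k_sub = int((te_subset["superfamily"] == fam).sum())
        k_gen = int((te_genome["superfamily"] == fam).sum())
        if k_sub == 0 and k_gen == 0:
            z, p = 0.0, 1.0
        else:
            try:
                z, p = proportions_ztest([k_sub, k_gen], [n_sub, n_gen])
            except Exception:
                z, p = np.nan, np.nan
            if not np.isfinite(z):
                z, p = 0.0, 1.0
        rows.append({
            "superfamily": fam,
            "p_subset": k_sub / n_sub,
            "p_genome": k_gen / n_gen,
            "z": float(z), "pvalue": float(p),
        })
    return pd.DataFrame(rows)


def _rescale_profile(values: np.ndarray, weights_span: tuple[float, float], k: int):
    """Area-weighted 1-D rescale of a bin-value profile segment to k columns."""
    lo, hi = weights_span
    out = np.zeros(k)
    step = (hi - lo) / k
    for a in range(k):
        c0, c1 = lo + a * step, lo + (a + 1) * step
        i0, i1 = int(np.floor(c0)), int(np.ceil(c1))
        total = 0.0
        wsum = 0.0
        for i in range(max(i0, 0), min(i1, values.size)):
            w = min(c1, i + 1) - max(c0, i)
            if w > 0:
                total += w * values[i]
                wsum += w
        out[a] = total / wsum if wsum > 0 else np.nan
    return out


def region_signal_matrix(
    track: SignalTrack,
    regions: pd.DataFrame,
    flank_bp: int = 0,
    k: int = 30,
    sort_values: np.ndarray | None = None,
    ascending: bool = False,
) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    """Per-region K-column signal matrix (meta-region heatmap) + mean profile.

    Each region (extended by ``flank_bp``, clipped at chromosome ends) is
    rescaled to ``k`` columns by area-weighted averaging of the per-bin
    signal. Rows are sorted by ``sort_values`` if given, else by descending
    row mean. Returns (matrix, column means, region order).
    """
    genome = track.genome
    rows = []
    ids = []
    for _, r in regions.iterrows():
        chrom = r["chrom"]
        length = genome.chrom_length(chrom)
        start = max(0, int(r["start"]) - flank_bp)
        end = min(length, int(r["end"]) + flank_bp)
        sl = genome.chrom_slice(chrom)
        vals = track.values[sl]
        lo = start / genome.bin_size
        hi = end / genome.bin_size
        rows.append(_rescale_profile(vals, (lo, hi), k))
        ids.append(r["region_id"])
    mat = np.stack(rows)
    key = np.nanmean(mat, axis=1) if sort_values is None else np.asarray(sort_values)
    order = np.argsort(key, kind="stable")
    if not ascending:
        order = order[::-1]
    mat = mat[order]
    idx = pd.Index([ids[i] for i in order], name="region_id")
    return mat, np.nanmean(mat, axis=0), idx


def integrate_expression(
    de_table: pd.DataFrame, deltas: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate DE status against per-mark change statuses.

    ``de_table`` needs columns gene_id, log2fc, padj, status (up/down/nc) and
    ``deltas`` maps mark/context name -> differential table indexed by
    region_id joinable on gene_id. Returns (cross-tab with counts and
    within-DE-status fractions, table of unjoined genes). Duplicated gene
    ids raise.
    """
    if de_table["gene_id"].duplicated().any():
        raise ValueError("integrate_expression: duplicated gene ids")
    joined = de_table.set_index("gene_id")
    tuple_cols = []
    for mark, d in deltas.items():
        col = d["status"].rename(f"{mark}_status")
        joined = joined.join(col, how="left")
        tuple_cols.append(f"{mark}_status")
    unjoined = joined[joined[tuple_cols].isna().any(axis=1)].reset_index()
    joined = joined.dropna(subset=tuple_cols)
    tab = (
        joined.groupby(["status"] + tuple_cols, sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = tab.groupby("status")["count"].transform("sum")
    tab["fraction"] = tab["count"] / totals
    return tab, unjoined
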