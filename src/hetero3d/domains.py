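"""Insulation profiles, TAD-boundary calling and aggregate domain analysis.

The insulation score follows the classic log2 diamond formulation: for each
bin the mean balanced contact in a ``w x w`` diamond straddling it, divided
by the chromosome's geometric mean and log2-transformed, so valid scores
average to zero per chromosome. Boundaries are prominence-filtered local
minima. Aggregate TAD analysis rescales flanked O/E submatrices to a common
K x K grid by exact area-weighted block averaging and averages them;
genotype differences are element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .hicmatrix import ContactMatrix


@dataclass
class InsulationProfile:
    genome: object
    scores: np.ndarray         # global per-bin log2 insulation, NaN if invalid
    window_bins: int

    def chrom_scores(self, chrom: str) -> np.ndarray:
        return self.scores[self.genome.chrom_slice(chrom)]


@dataclass
class DomainSet:
    intervals: pd.DataFrame    # chrom, start_bin, end_bin (half-open, chrom-local)
    provenance: str            # "planted" or "called"


@dataclass
class AggregateMap:
    matrix: np.ndarray         # K x K mean
    n_regions: int
    value_space: str           # "oe" or "diff"


def insulation_profile(matrix: ContactMatrix, window: int = 10) -> InsulationProfile:
    """Diamond insulation score on a balanced matrix.

    raw(i) = mean over unmasked cells of M[i-w:i, i+1:i+w+1];
    is(i) = log2(raw(i)) - mean(log2(raw)) over valid bins of the chromosome.
    Bins within ``window`` of a chromosome end, masked bins, and bins with an
    empty or non-positive diamond are invalid (NaN).
    """
    matrix.require_stage("balanced")
    genome = matrix.genome
    scores = np.full(genome.n_bins, np.nan)
    for chrom in genome.names:
        n = genome.chrom_nbins(chrom)
        if window >= n / 2:
            raise ValueError(
                f"insulation window {window} too large for {chrom!r} ({n} bins)"
            )
        m = matrix.data[chrom]
        valid = matrix.mask[chrom]
        raw = np.full(n, np.nan)
        for i in range(window, n - window):
            if not valid[i]:
                continue
            diamond = m[i - window:i, i + 1:i + window + 1]
            vals = diamond[np.isfinite(diamond)]
            if vals.size:
                raw[i] = vals.mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.where(raw > 0, np.log2(raw), np.nan)
        ok = np.isfinite(logr)
        if ok.any():
            logr = logr - logr[ok].mean()
        scores[genome.chrom_slice(chrom)] = logr
    return InsulationProfile(genome, scores, window)


def call_boundaries(profile: InsulationProfile, delta: float = 0.2) -> tuple[
    pd.DataFrame, DomainSet
]:
    """Prominence-filtered insulation minima, plus inter-boundary domains.

    A boundary is a local minimum of the insulation score whose prominence
    (within a +/-window neighborhood) is at least ``delta``. Returns the
    boundary table (chrom, bin) and the derived domains between consecutive
    boundaries. Calls are invariant to adding a constant to the score.
    """
    rows = []
    domains = []
    for chrom in profile.genome.names:
        s = profile.chrom_scores(chrom)
        valid = np.isfinite(s)
        # find minima per contiguous valid run so NaNs cannot bridge peaks
        edges = np.flatnonzero(np.diff(valid.astype(int)))
        starts = [0] if valid[0] else []
        starts += [e + 1 for e in edges if valid[e + 1]]
        ends = [e + 1 for e in edges if valid[e]]
        if valid[-1]:
            ends.append(valid.size)
        bounds = []
        for a, b in zip(starts, ends):
            peaks, _ = find_peaks(
                -s[a:b], prominence=delta, wlen=2 * profile.window_bins + 1
            )
            bounds.extend(int(p) + a for p in peaks)
        bounds.sort()
        rows.extend({"chrom": chrom, "bin": b} for b in bounds)
        for a, b in zip(bounds[:-1], bounds[1:]):
            domains.append({"chrom": chrom, "start_bin": a, "end_bin": b})
    boundaries = pd.DataFrame(rows, columns=["chrom", "bin"])
    dset = DomainSet(
        pd.DataFrame(domains, columns=["chrom", "start_bin", "end_bin"]), "called"
    )
    return boundaries, dset


def _rescale_block(m: np.ndarray, k: int) -> np.ndarray:
    """Area-weighted rescale of an n x n matrix to k x k, NaN-aware.

    Output cell (a, b) is the overlap-weighted mean of input cells under the
    uniform mapping of [0, n) onto [0, k); exact block means when k | n.
    """
    n = m.shape[0]
    w = np.zeros((k, n))
    step = n / k
    for a in range(k):
        lo, hi = a * step, (a + 1) * step
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n)):
            w[a, i] = min(hi, i + 1) - max(lo, i)
    finite = np.isfinite(m)
    filled = np.where(finite, m, 0.0)
    denom = w @ finite.astype(float) @ w.T
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, (w @ filled @ w.T) / denom, np.nan)


def aggregate_tads(
    oe: ContactMatrix, domains: DomainSet, k: int = 30
) -> AggregateMap:
    """Average of flanked, rescaled O/E submatrices over a domain list.

    Each domain is extended by flanks of half its length on both sides; the
    flanked submatrix is rescaled to ``k x k`` (area-weighted) and averaged
    element-wise over domains. Domains whose flanked window leaves the
    chromosome are skipped and counted.
    """
    oe.require_stage("oe")
    stacks = []
    n_skipped = 0
    for _, row in domains.intervals.iterrows():
        chrom = row["chrom"]
        s, e = int(row["start_bin"]), int(row["end_bin"])
        length = e - s
        flank = length // 2
        a, b = s - flank, e + flank
        n = oe.genome.chrom_nbins(chrom)
        if a < 0 or b > n or length == 0:
            n_skipped += 1
            continue
        stacks.append(_rescale_block(oe.data[chrom][a:b, a:b], k))
    if not stacks:
        raise ValueError("aggregate_tads: zero usable domains")
    agg = AggregateMap(np.nanmean(np.stack(stacks), axis=0), len(stacks), "oe")
    agg.n_skipped = n_skipped
    return agg


def diff_aggregate(agg_wt: AggregateMap, agg_mut: AggregateMap) -> AggregateMap:
    """Element-wise mutant minus wild-type aggregate."""
    if agg_wt.matrix.shape != agg_mut.matrix.shape:
        raise ValueError("aggregate shapes differ")
    return AggregateMap(
        agg_mut.matrix - agg_wt.matrix,
        min(agg_wt.n_regions, agg_mut.n_regions),
        "diff",
    )


def boundary_signal_matrix(
    profile: InsulationProfile, boundaries: pd.DataFrame, flank_bins: int = 10
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack of insulation windows around boundaries, plus mean profile.

    Rows (one per boundary, sorted ascending by center value) hold the
    insulation score in a +/-``flank_bins`` window; boundaries whose window
    leaves the chromosome are dropped and counted in the third return value.
    The second return is the column-wise nanmean profile.
    """
    rows = []
    n_dropped = 0
    for _, row in boundaries.iterrows():
        chrom, b = row["chrom"], int(row["bin"])
        s = profile.chrom_scores(chrom)
        if b - flank_bins < 0 or b + flank_bins + 1 > s.size:
            n_dropped += 1
            continue
        rows.append(s[b - flank_bins: b + flank_bins + 1])
    if not rows:
        raise ValueError("boundary_signal_matrix: no usable boundaries")
    mat = np.stack(rows)
    mat = mat[np.argsort(mat[:, flank_bins], kind="stable")]
    return mat, np.nanmean(mat, axis=0), n_dropped
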