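"""A/B compartment calling and compartmentalization statistics.

PC1 is taken from the Pearson correlation map of the distance-normalized
(O/E) matrix, per chromosome, with the sign fixed so the eigenvector
correlates positively with an orientation track (gene density or an active
mark such as H3K9ac): positive PC1 = compartment A. Compartment strength is
quantified two ways — a saddle statistic (mean O/E by PC1-quantile pair,
corner ratio) and interval-pair ("pentad") category averages — plus a
feature-sorted correlation-map segregation score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hicmatrix import ContactMatrix
from .tracks import SignalTrack

D_MIN_DEFAULT = 2  # bins excluded around the diagonal in compartment averages


@dataclass
class CompartmentCall:
    genome: object
    pc1: np.ndarray            # global per-bin PC1, NaN where masked
    labels: np.ndarray         # per-bin {A, B, masked}
    orientation_track: str
    eigen_gap: dict[str, float]

    def chrom_pc1(self, chrom: str) -> np.ndarray:
        return self.pc1[self.genome.chrom_slice(chrom)]

    def chrom_labels(self, chrom: str) -> np.ndarray:
        return self.labels[self.genome.chrom_slice(chrom)]


@dataclass
class SaddleResult:
    saddle: np.ndarray         # Q x Q mean OE by PC1-quantile pair
    counts: np.ndarray
    corner_frac: float
    strength: float


@dataclass
class PentadResult:
    means: dict[str, float]    # category -> mean OE over interval-pair blocks
    counts: dict[str, int]     # category -> number of contributing blocks
    d_min: int


def call_compartments(
    pearson: ContactMatrix, orientation: SignalTrack
) -> CompartmentCall:
    """Leading eigenvector of the column-mean-centered Pearson map, per chrom.

    The unit-length eigenvector is sign-flipped so that its correlation with
    the orientation track is positive; bins with PC1 > 0 are labeled A.
    Raises if the map is degenerate (no leading direction) or if the
    orientation correlation is exactly zero.
    """
    pearson.require_stage("pearson")
    genome = pearson.genome
    pc1 = np.full(genome.n_bins, np.nan)
    labels = np.full(genome.n_bins, "masked", dtype=object)
    gaps = {}
    for chrom in genome.names:
        valid = pearson.mask[chrom]
        sub = pearson.data[chrom][np.ix_(valid, valid)]
        centered = sub - sub.mean(axis=0, keepdims=True)
        if not np.isfinite(centered).all() or np.allclose(centered, 0):
            raise ValueError(
                f"call_compartments: degenerate Pearson map on {chrom!r} "
                "(constant columns); no compartment signal"
            )
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        if s[0] <= 0:
            raise ValueError(f"call_compartments: no leading direction on {chrom!r}")
        vec = u[:, 0]
        gaps[chrom] = float(s[0] / s[1]) if s.size > 1 and s[1] > 0 else np.inf
        orient = orientation.values[genome.chrom_slice(chrom)][valid]
        c = np.corrcoef(vec, orient)[0, 1]
        if not np.isfinite(c) or c == 0:
            raise ValueError(
                f"call_compartments: orientation track {orientation.name!r} "
                f"uncorrelated with PC1 on {chrom!r}; supply an explicit sign"
            )
        if c < 0:
            vec = -vec
        sl = genome.chrom_slice(chrom)
        idx = np.flatnonzero(valid) + sl.start
        pc1[idx] = vec
        labels[idx] = np.where(vec > 0, "A", "B")
    return CompartmentCall(genome, pc1, labels, orientation.name, gaps)


def _quantile_groups(values: np.ndarray, q: int) -> np.ndarray:
    """Group ids 0..q-1 by ascending value, groups as equal-sized as possible."""
    order = np.argsort(values, kind="stable")
    groups = np.empty(values.size, dtype=int)
    for g, chunk in enumerate(np.array_split(order, q)):
        groups[chunk] = g
    return groups


def saddle_strength(
    oe: ContactMatrix,
    call: CompartmentCall,
    q: int = 5,
    corner_frac: float = 0.2,
    d_min: int = D_MIN_DEFAULT,
) -> SaddleResult:
    """Saddle matrix and corner-ratio compartment strength.

    Bins are ranked by PC1 ascending within each chromosome and cut into
    ``q`` equal-size groups; cell (q1, q2) pools O/E over unmasked pairs with
    separation >= ``d_min`` across all chromosomes. Strength =
    (mean BB corner + mean AA corner) / (2 x mean AB corners), corners being
    the extreme ``corner_frac`` quantile blocks (pair-pooled means).
    """
    oe.require_stage("oe")
    if q < 2:
        raise ValueError("q must be >= 2")
    sums = np.zeros((q, q))
    counts = np.zeros((q, q))
    for chrom in oe.genome.names:
        valid = oe.mask[chrom] & np.isfinite(call.chrom_pc1(chrom))
        idx = np.flatnonzero(valid)
        if idx.size < q:
            raise ValueError(f"saddle_strength: too few unmasked bins on {chrom!r}")
        groups = _quantile_groups(call.chrom_pc1(chrom)[idx], q)
        m = oe.data[chrom]
        ii, jj = np.triu_indices(idx.size, k=d_min)
        vals = m[idx[ii], idx[jj]]
        ok = np.isfinite(vals)
        g1, g2, vals = groups[ii[ok]], groups[jj[ok]], vals[ok]
        np.add.at(sums, (g1, g2), vals)
        np.add.at(counts, (g1, g2), 1)
        np.add.at(sums, (g2, g1), vals)
        np.add.at(counts, (g2, g1), 1)
    with np.errstate(invalid="ignore"):
        saddle = sums / counts
    c = max(1, int(round(corner_frac * q)))

    def _pool(rows: slice, cols: slice) -> float:
        return float(sums[rows, cols].sum() / counts[rows, cols].sum())

    bb = _pool(slice(0, c), slice(0, c))
    aa = _pool(slice(q - c, q), slice(q - c, q))
    ab = float(
        (sums[0:c, q - c:q].sum() + sums[q - c:q, 0:c].sum())
        / (counts[0:c, q - c:q].sum() + counts[q - c:q, 0:c].sum())
    )
    strength = (aa + bb) / (2 * ab)
    return SaddleResult(saddle, counts, corner_frac, strength)


def _label_intervals(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal same-label runs over A/B labels; masked bins break runs."""
    out = []
    start = None
    for i, lab in enumerate(labels):
        if lab not in ("A", "B"):
            if start is not None:
                out.append((start, i, labels[start]))
                start = None
            continue
        if start is None:
            start = i
        elif lab != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    if start is not None:
        out.append((start, len(labels), labels[start]))
    return out


def compartment_pentad(
    oe: ContactMatrix, call: CompartmentCall, d_min: int = D_MIN_DEFAULT
) -> PentadResult:
    """Mean O/E over compartment-interval rectangles, by category AA/BB/AB.

    The compartment call is segmented into maximal same-label runs; for every
    (unordered) pair of intervals, including an interval with itself, the
    rectangular O/E block mean (cells with separation >= ``d_min``) is
    accumulated into AA, BB or AB. Categories with no eligible area are
    reported as absent.
    """
    oe.require_stage("oe")
    acc: dict[str, list[float]] = {"AA": [], "BB": [], "AB": []}
    for chrom in oe.genome.names:
        labels = call.chrom_labels(chrom)
        intervals = _label_intervals(labels)
        m = oe.data[chrom]
        n = m.shape[0]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        eligible = np.isfinite(m) & (d >= d_min)
        for k1, (s1, e1, l1) in enumerate(intervals):
            for s2, e2, l2 in intervals[k1:]:
                block = m[s1:e1, s2:e2]
                ok = eligible[s1:e1, s2:e2]
                if not ok.any():
                    continue
                cat = l1 + l2 if l1 <= l2 else l2 + l1
                if cat == "BA":
                    cat = "AB"
                acc[cat].append(float(block[ok].mean()))
    means = {k: float(np.mean(v)) for k, v in acc.items() if v}
    counts = {k: len(v) for k, v in acc.items() if v}
    return PentadResult(means, counts, d_min)


def feature_sorted_map(
    pearson: ContactMatrix, track: SignalTrack, n_groups: int = 10
) -> tuple[dict[str, np.ndarray], float]:
    """Reorder the correlation map by ascending track value; segregation score.

    Per chromosome the valid rows/columns are permuted by ascending track
    value (ties broken by bin id) and split into ``n_groups`` equal-size
    groups. The pooled segregation score is the mean correlation over
    same-group pairs minus the mean over pairs whose group indices differ by
    at least ``n_groups // 2``.
    """
    pearson.require_stage("pearson")
    maps = {}
    same_sum = same_n = far_sum = far_n = 0.0
    half = n_groups // 2
    for chrom in pearson.genome.names:
        valid = pearson.mask[chrom]
        idx = np.flatnonzero(valid)
        vals = track.values[pearson.genome.chrom_slice(chrom)][idx]
        if np.ptp(vals) == 0:
            warnings.warn(
                f"feature_sorted_map: constant track {track.name!r} on {chrom!r}; "
                "ties broken by bin id"
            )
        order = np.argsort(vals, kind="stable")
        sub = pearson.data[chrom][np.ix_(idx[order], idx[order])]
        maps[chrom] = sub
        groups = np.empty(idx.size, dtype=int)
        for g, chunk in enumerate(np.array_split(np.arange(idx.size), n_groups)):
            groups[chunk] = g
        ii, jj = np.triu_indices(idx.size, k=1)
        vv = sub[ii, jj]
        ok = np.isfinite(vv)
        dg = np.abs(groups[ii[ok]] - groups[jj[ok]])
        vv = vv[ok]
        same = dg == 0
        far = dg >= half
        same_sum += vv[same].sum()
        same_n += same.sum()
        far_sum += vv[far].sum()
        far_n += far.sum()
    if same_n == 0 or far_n == 0:
        raise ValueError("feature_sorted_map: not enough pairs for the score")
    score = float(same_sum / same_n - far_sum / far_n)
    return maps, score
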