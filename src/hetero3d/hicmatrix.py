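"""Contact-matrix core: ingestion, masking, ICE balancing, distance-expected,
observed/expected and Pearson correlation maps.

All matrices are dense, symmetric, per-chromosome (cis only) and share a
:class:`~hetero3d.genome.BinnedGenome`. Masked bins are tracked with a per-bin
validity flag and their rows/columns hold NaN once a mask has been applied.
Stages move forward only: raw -> balanced -> oe -> pearson.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome

STAGES = ("raw", "balanced", "oe", "pearson")


class StageError(ValueError):
    """Operation applied to a matrix in the wrong normalization stage."""


@dataclass
class ContactMatrix:
    genome: BinnedGenome
    data: dict[str, np.ndarray]
    stage: str = "raw"
    mask: dict[str, np.ndarray] = None  # per-chrom boolean "bin is valid"
    weights: dict[str, np.ndarray] = None  # ICE biases, present once balanced
    trans_total: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for chrom in self.genome.names:
            if chrom not in self.data:
                raise ValueError(f"missing matrix for chromosome {chrom!r}")
            n = self.genome.chrom_nbins(chrom)
            m = self.data[chrom]
            if m.shape != (n, n):
                raise ValueError(f"{chrom!r}: matrix shape {m.shape}, expected {(n, n)}")
        if self.mask is None:
            self.mask = {
                c: np.ones(self.genome.chrom_nbins(c), dtype=bool)
                for c in self.genome.names
            }

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            genome=self.genome,
            data={c: m.copy() for c, m in self.data.items()},
            stage=self.stage,
            mask={c: m.copy() for c, m in self.mask.items()},
            weights=None
            if self.weights is None
            else {c: w.copy() for c, w in self.weights.items()},
            trans_total=self.trans_total,
            converged=self.converged,
        )

    def total_mass(self) -> float:
        """Sum over all cells (cis) plus recorded trans total."""
        cis = sum(float(np.nansum(m)) for m in self.data.values())
        return cis + self.trans_total

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"matrix is at stage {self.stage!r}; expected one of {stages}"
            )


@dataclass
class ExpectedProfile:
    """Mean contact per genomic separation d (in bins), per chromosome.

    ``values[chrom][d]`` is the mean over doubly-unmasked pairs at separation
    d; ``counts[chrom][d]`` the number of contributing pairs. Separations with
    no contributing pairs hold NaN.
    """

    genome: BinnedGenome
    values: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]
    stage: str


# ---------------------------------------------------------------------------
# ingestion


def bin_pairs(pairs_file, genome: BinnedGenome) -> ContactMatrix:
    """Bin a 4DN-style ``.pairs`` text file into a raw contact matrix.

    Expected columns (whitespace-separated, ``#`` comments ignored):
    readID chrom1 pos1 chrom2 pos2 [strand1 strand2]. Cis pairs fill the
    per-chromosome matrices; trans pairs are kept only as a total count.
    Malformed lines are counted and reported via the returned matrix's
    ``n_malformed`` attribute.
    """
    data = {
        c: np.zeros((genome.chrom_nbins(c),) * 2) for c in genome.names
    }
    known = set(genome.names)
    n_pairs = 0
    n_malformed = 0
    trans = 0.0
    with open(pairs_file) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                n_malformed += 1
                continue
            _, c1, p1, c2, p2 = parts[:5]
            if c1 not in known or c2 not in known:
                raise ValueError(f"unknown chromosome in pairs file: {c1!r}/{c2!r}")
            try:
                p1, p2 = int(p1), int(p2)
            except ValueError:
                n_malformed += 1
                continue
            if not (0 <= p1 < genome.chrom_length(c1)) or not (
                0 <= p2 < genome.chrom_length(c2)
            ):
                n_malformed += 1
                continue
            n_pairs += 1
            if c1 == c2:
                i = p1 // genome.bin_size
                j = p2 // genome.bin_size
                data[c1][i, j] += 1
                if i != j:
                    data[c1][j, i] += 1
            else:
                trans += 1
    if n_pairs == 0:
        raise ValueError(f"no valid pairs found in {pairs_file}")
    cm = ContactMatrix(genome=genome, data=data, stage="raw", trans_total=trans)
    cm.n_malformed = n_malformed
    return cm


# ---------------------------------------------------------------------------
# masking and balancing


def mask_low_coverage(matrix: ContactMatrix, min_frac: float = 0.1) -> ContactMatrix:
    """Mask bins whose marginal sum falls below ``min_frac`` x median marginal.

    Masked rows/columns are set to NaN. Raises if every bin would be masked.
    """
    matrix.require_stage("raw")
    out = matrix.copy()
    for chrom in out.genome.names:
        m = out.data[chrom]
        marg = np.nansum(m, axis=1)
        median = np.median(marg)
        valid = marg >= min_frac * median
        if min_frac == 0:
            valid = np.ones_like(valid)
        out.mask[chrom] = out.mask[chrom] & valid
        m[~out.mask[chrom], :] = np.nan
        m[:, ~out.mask[chrom]] = np.nan
    if not any(mask.any() for mask in out.mask.values()):
        raise ValueError("mask_low_coverage: all bins masked")
    return out


def balance_ice(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative-correction (ICE) balancing of a raw matrix.

    Rows/columns are repeatedly divided by their marginals (rescaled to unit
    mean over unmasked bins) until the unmasked marginals deviate from their
    mean by less than ``tol``, or ``max_iter`` sweeps. Per-bin biases are
    stored in ``weights``; failure to converge sets ``converged=False`` with a
    warning rather than raising.
    """
    matrix.require_stage("raw")
    out = matrix.copy()
    out.weights = {}
    converged_all = True
    for chrom in out.genome.names:
        valid = out.mask[chrom]
        m = out.data[chrom]
        if not valid.any() or np.nansum(m) == 0:
            raise ValueError(f"balance_ice: {chrom!r} has zero total")
        work = np.nan_to_num(m[np.ix_(valid, valid)], nan=0.0)
        bias = np.ones(valid.sum())
        converged = False
        for _ in range(max_iter):
            marg = work.sum(axis=1)
            nz = marg > 0
            s = np.ones_like(marg)
            s[nz] = marg[nz] / marg[nz].mean()
            work /= np.outer(s, s)
            bias *= s
            if np.abs(s - 1).max() < tol:
                converged = True
                break
        if not converged:
            converged_all = False
            warnings.warn(f"balance_ice: {chrom!r} did not converge in {max_iter} sweeps")
        full = np.full_like(m, np.nan)
        full[np.ix_(valid, valid)] = work
        out.data[chrom] = full
        w = np.full(valid.size, np.nan)
        w[valid] = bias
        out.weights[chrom] = w
    out.stage = "balanced"
    out.converged = converged_all
    return out


# ---------------------------------------------------------------------------
# expected / OE / Pearson


def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    """Mean contact at each separation d, over doubly-unmasked pairs."""
    matrix.require_stage("raw", "balanced")
    values: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for chrom in matrix.genome.names:
        m = matrix.data[chrom]
        valid = matrix.mask[chrom]
        n = m.shape[0]
        e = np.full(n, np.nan)
        c = np.zeros(n, dtype=int)
        for d in range(n):
            diag = np.diagonal(m, offset=d)
            ok = valid[: n - d] & valid[d:] & np.isfinite(diag)
            c[d] = int(ok.sum())
            if c[d] > 0:
                e[d] = diag[ok].mean()
        values[chrom] = e
        counts[chrom] = c
    return ExpectedProfile(matrix.genome, values, counts, matrix.stage)


def observed_over_expected(
    matrix: ContactMatrix, expected: ExpectedProfile
) -> ContactMatrix:
    """OE(i, j) = M(i, j) / E(|i - j|); cells with E = 0 or undefined become NaN.

    By construction the mean of OE over unmasked pairs of each diagonal is
    exactly 1 (an arithmetic identity used as a pipeline self-check).
    """
    matrix.require_stage("raw", "balanced")
    if expected.genome != matrix.genome:
        raise ValueError("expected profile computed on a different genome")
    out = matrix.copy()
    for chrom in out.genome.names:
        m = out.data[chrom]
        n = m.shape[0]
        e = expected.values[chrom]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        ed = e[d]
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = np.where((ed > 0) & np.isfinite(ed), m / ed, np.nan)
        oe[~out.mask[chrom], :] = np.nan
        oe[:, ~out.mask[chrom]] = np.nan
        out.data[chrom] = oe
    out.stage = "oe"
    return out


def pearson_map(matrix: ContactMatrix) -> ContactMatrix:
    """Pearson correlation of OE columns, restricted to unmasked rows.

    The resulting map is symmetric with unit diagonal; NaN cells inside the
    valid block (e.g. the zero-separation diagonal of a zero-diagonal
    simulation) are handled with pairwise-complete observations.
    """
    matrix.require_stage("oe")
    out = matrix.copy()
    for chrom in out.genome.names:
        valid = out.mask[chrom]
        if valid.sum() < 3:
            raise ValueError(f"pearson_map: fewer than 3 unmasked bins on {chrom!r}")
        sub = out.data[chrom][np.ix_(valid, valid)]
        corr = pd.DataFrame(sub).corr(method="pearson").to_numpy()
        np.fill_diagonal(corr, 1.0)
        corr = (corr + corr.T) / 2  # enforce exact symmetry
        full = np.full_like(out.data[chrom], np.nan)
        full[np.ix_(valid, valid)] = corr
        out.data[chrom] = full
    out.stage = "pearson"
    return out
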