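"""Synthetic 3D-genome generator: matched wild-type and *ddm1*-like datasets.

The generator lays out small plant-like chromosomes — gene-rich arms flanking
a TE-rich pericentromeric core — assigns each bin one of three chromatin
states (active, facultative heterochromatin, constitutive heterochromatin),
and derives every downstream artifact from that truth: cis contact matrices
(Poisson counts with distance decay, homotypic state affinities, intra-TAD
boosts and planted anchor-pair boosts), noisy histone-mark and
DNA-methylation tracks, gene/TE annotations, a differential-expression table,
and the planted labels used as oracles by the test-suite.

"ddm1 mode" emulates loss of the DDM1 chromatin remodeler: a fraction of
core (constitutive) bins gain H3K27me3 and lose the constitutive marks
(redistribution classes II/III), a fraction of arm facultative bins lose
H3K27me3 and become active-like (class I), and the affinity structure mixes —
facultative/constitutive cross-affinity rises and so does the
active/repressed affinity, producing the mutant's novel genic-TE contacts and
its weakened compartmentalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .hicmatrix import ContactMatrix
from .tracks import SignalTrack

STATES = ("active", "fac_het", "const_het")
MARKS = ("H3K27me3", "H3K9me2", "H3K27me1", "H3K9ac", "mCG", "mCHG", "mCHH")

# Base signal level per (state, mark). Chosen so that every log2 contrast the
# redistribution classifier relies on is either exactly 0 or comfortably
# larger than the +/-0.5 call thresholds.
BASE_LEVELS: dict[str, dict[str, float]] = {
    "active": {
        "H3K27me3": 0.3, "H3K9me2": 0.8, "H3K27me1": 0.3,
        "H3K9ac": 2.0, "mCG": 0.2, "mCHG": 0.1, "mCHH": 0.1,
    },
    "fac_het": {
        "H3K27me3": 2.0, "H3K9me2": 0.3, "H3K27me1": 0.3,
        "H3K9ac": 0.2, "mCG": 0.3, "mCHG": 0.15, "mCHH": 0.1,
    },
    # TE-rich constitutive heterochromatin is essentially devoid of H3K27me3
    # in the wild type (below even the genic baseline), which is what makes
    # the K27me3-sorted correlation map segregate facultative from
    # constitutive domains.
    "const_het": {
        "H3K27me3": 0.1, "H3K9me2": 2.5, "H3K27me1": 2.5,
        "H3K9ac": 0.1, "mCG": 2.0, "mCHG": 1.5, "mCHH": 1.0,
    },
}
# Class III regions are constitutive bins that were lowly H3K9me2-marked to
# begin with and stay that way ("stable but low"): their H3K9me2 base is
# overridden in both genotypes to a level clearly below the facultative one.
CLASS3_K9ME2 = 0.15

DEFAULT_SUPERFAMILIES_CORE = {
    "LTR/Gypsy": 0.45, "LTR/Copia": 0.20, "DNA/MuDR": 0.08, "DNA/hAT": 0.06,
    "LINE/L1": 0.08, "SINE": 0.03, "RC/Helitron": 0.06, "DNA/Harbinger": 0.04,
}
DEFAULT_SUPERFAMILIES_ARM = {
    "LTR/Gypsy": 0.15, "LTR/Copia": 0.30, "DNA/MuDR": 0.12, "DNA/hAT": 0.12,
    "LINE/L1": 0.10, "SINE": 0.08, "RC/Helitron": 0.08, "DNA/Harbinger": 0.05,
}

_STREAM = {"layout": 0, "ddm1": 1, "contacts_wt": 2, "contacts_ddm1": 3,
           "tracks_wt": 4, "tracks_ddm1": 5, "de": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM[stream],))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired WT / ddm1-mode simulation.

    Defaults are the desk-scale study conditions: 2 chromosomes x 10 Mb at
    50 kb bins (200 bins each), the smallest scale at which compartments,
    TAD-like domains and saddle statistics are all resolvable.
    """

    n_chrom: int = 2
    chrom_len: int = 10_000_000
    bin_size: int = 50_000
    core_frac: float = 0.4          # fraction of bins in the TE-rich core
    p_fac: float = 0.3              # P(arm bin is facultative het in WT)
    alpha: float = 1.0              # distance-decay exponent
    depth: float = 1_000_000.0      # expected cis counts per chromosome
    a_aa: float = 1.6               # homotypic affinities
    a_ff: float = 1.6
    a_cc: float = 1.6
    a_cross_rep: float = 0.8        # facultative <-> constitutive, WT
    a_ab: float = 0.5               # active <-> repressed, WT
    a_cross_rep_mut: float = 1.4    # facultative <-> constitutive, ddm1 mode
    a_ab_mut: float = 0.8           # active <-> repressed, ddm1 mode
    tau: float = 2.0                # intra-TAD boost, WT
    tau_mut: float = 1.4            # intra-TAD boost, ddm1 mode
    n_tads_per_chrom: int = 10
    rho_relocate: float = 0.5       # core bins gaining H3K27me3 in ddm1
    rho_loss: float = 0.5           # WT facultative bins losing H3K27me3
    class3_frac: float = 0.5        # class III share among relocated bins
    n_anchor_pairs: int = 50        # boosted pairs present in both genotypes
    anchor_boost: float = 3.0
    n_anchor_pairs_mut: int = 0     # extra boosted pairs in ddm1 mode only
    anchor_d_range: tuple[int, int] = (10, 100)
    sigma_track: float = 0.3        # lognormal noise sd on mark tracks
    superfamilies_core: dict = field(
        default_factory=lambda: dict(DEFAULT_SUPERFAMILIES_CORE))
    superfamilies_arm: dict = field(
        default_factory=lambda: dict(DEFAULT_SUPERFAMILIES_ARM))
    seed: int = 1

    def validate(self) -> None:
        for name in ("a_aa", "a_ff", "a_cc", "a_cross_rep", "a_ab",
                     "a_cross_rep_mut", "a_ab_mut", "tau", "tau_mut",
                     "anchor_boost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("core_frac", "p_fac", "rho_relocate", "rho_loss",
                     "class3_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.chrom_len % self.bin_size != 0:
            raise ValueError("bin_size must divide chrom_len")
        if self.chrom_len // self.bin_size < 10:
            raise ValueError("chromosome shorter than 10 bins")

    @property
    def genome(self) -> BinnedGenome:
        return BinnedGenome(
            tuple((f"chr{i + 1}", self.chrom_len) for i in range(self.n_chrom)),
            self.bin_size,
        )


@dataclass
class TruthSet:
    """Planted states, domains, anchor pairs and class labels (the oracle)."""

    genome: BinnedGenome
    state_wt: np.ndarray                 # per-bin, values in STATES
    state_mut: np.ndarray
    domains: pd.DataFrame                # chrom, start_bin, end_bin (chrom-local)
    anchor_pairs: pd.DataFrame           # chrom, bin1, bin2 (chrom-local), genotype
    class_label: np.ndarray              # per-bin, {I, II, III, none}
    compartment_label: np.ndarray        # per-bin, {A, B}; A iff WT state active

    def validate(self) -> None:
        n = self.genome.n_bins
        for arr, allowed in (
            (self.state_wt, STATES),
            (self.state_mut, STATES),
            (self.class_label, ("I", "II", "III", "none")),
            (self.compartment_label, ("A", "B")),
        ):
            if arr.shape != (n,):
                raise ValueError("truth array length does not match genome")
            if not set(np.unique(arr)) <= set(allowed):
                raise ValueError("unexpected truth label")
        for chrom, grp in self.domains.groupby("chrom", sort=False):
            g = grp.sort_values("start_bin")
            if (g["end_bin"] <= g["start_bin"]).any():
                raise ValueError("empty domain interval")
            if (g["start_bin"].to_numpy()[1:] < g["end_bin"].to_numpy()[:-1]).any():
                raise ValueError("overlapping domains")


def build_genome_layout(
    cfg: SimulationConfig,
) -> tuple[BinnedGenome, TruthSet, pd.DataFrame, pd.DataFrame]:
    """Lay out chromosomes, WT chromatin states, TADs, anchors, genes and TEs.

    Returns ``(genome, truth, genes, tes)``. Genes/TEs are interval tables in
    bp (0-based half-open); TEs carry a ``superfamily`` column. The central
    ``core_frac`` of each chromosome is constitutive heterochromatin densely
    covered by TEs; arms carry one gene per bin and are active or facultative
    with probability ``p_fac``.
    """
    cfg.validate()
    genome = cfg.genome
    rng = _rng(cfg.seed, "layout")
    n_total = genome.n_bins
    state = np.full(n_total, "active", dtype=object)
    domains = []
    anchors = []
    genes = []
    tes = []
    arm_sfs = sorted(cfg.superfamilies_arm)
    arm_p = np.array([cfg.superfamilies_arm[s] for s in arm_sfs], dtype=float)
    arm_p /= arm_p.sum()
    core_sfs = sorted(cfg.superfamilies_core)
    core_p = np.array([cfg.superfamilies_core[s] for s in core_sfs], dtype=float)
    core_p /= core_p.sum()

    for chrom in genome.names:
        n = genome.chrom_nbins(chrom)
        off = genome.chrom_offset(chrom)
        n_core = int(round(cfg.core_frac * n))
        core_start = (n - n_core) // 2
        core_end = core_start + n_core
        core = np.arange(core_start, core_end)
        arms = np.concatenate([np.arange(0, core_start), np.arange(core_end, n)])

        state[off + core] = "const_het"
        fac = arms[rng.random(arms.size) < cfg.p_fac]
        state[off + fac] = "fac_het"

        # TADs tile the repressed core into equal-size intervals.
        if n_core > 0 and cfg.n_tads_per_chrom > 0:
            edges = np.linspace(core_start, core_end,
                                cfg.n_tads_per_chrom + 1).round().astype(int)
            for s, e in zip(edges[:-1], edges[1:]):
                if e > s:
                    domains.append({"chrom": chrom, "start_bin": int(s),
                                    "end_bin": int(e)})

        # Annotations: one gene (60% of a bin) per arm bin; 1 TE per arm bin
        # and 1-2 TEs per core bin (superfamily distribution heavier in
        # LTR/Gypsy inside the core).
        gene_len = max(1, (6 * cfg.bin_size) // 10)
        te_len = max(1, cfg.bin_size // 10)
        for k, b in enumerate(arms):
            start = b * cfg.bin_size + int(rng.integers(0, cfg.bin_size - gene_len + 1))
            genes.append({"chrom": chrom, "start": start, "end": start + gene_len,
                          "name": f"gene_{chrom}_{k:04d}", "strand": "+"})
            ts = b * cfg.bin_size + int(rng.integers(0, cfg.bin_size - te_len + 1))
            tes.append({"chrom": chrom, "start": ts, "end": ts + te_len,
                        "superfamily": str(rng.choice(arm_sfs, p=arm_p)),
                        "location": "arm"})
        for k, b in enumerate(core):
            for rep in range(2 if k % 2 == 0 else 1):
                ts = b * cfg.bin_size + int(rng.integers(0, cfg.bin_size - te_len + 1))
                tes.append({"chrom": chrom, "start": ts, "end": ts + te_len,
                            "superfamily": str(rng.choice(core_sfs, p=core_p)),
                            "location": "core"})

        # Anchor pairs present in both genotypes: facultative-facultative
        # arm pairs within the APA distance range.
        n_anch = cfg.n_anchor_pairs // cfg.n_chrom
        anchors.extend(
            _sample_pairs(rng, fac, fac, n_anch, cfg.anchor_d_range, chrom, "both")
        )

    genes = pd.DataFrame(genes, columns=["chrom", "start", "end", "name", "strand"])
    tes = pd.DataFrame(tes).sort_values(["chrom", "start"]).reset_index(drop=True)
    tes["name"] = [f"te_{i:05d}" for i in range(len(tes))]

    truth = TruthSet(
        genome=genome,
        state_wt=state,
        state_mut=state.copy(),
        domains=pd.DataFrame(domains, columns=["chrom", "start_bin", "end_bin"]),
        anchor_pairs=pd.DataFrame(
            anchors, columns=["chrom", "bin1", "bin2", "genotype"]
        ),
        class_label=np.full(n_total, "none", dtype=object),
        compartment_label=np.where(state == "active", "A", "B").astype(object),
    )
    truth.validate()
    return genome, truth, genes, tes


def _sample_pairs(rng, bins1, bins2, n, d_range, chrom, genotype):
    """Sample up to ``n`` distinct (i < j) pairs with separation in d_range."""
    lo, hi = d_range
    a, b = np.meshgrid(np.asarray(bins1), np.asarray(bins2), indexing="ij")
    a, b = a.ravel(), b.ravel()
    i, j = np.minimum(a, b), np.maximum(a, b)
    keep = (j - i >= lo) & (j - i <= hi)
    i, j = i[keep], j[keep]
    if i.size == 0:
        return []
    order = rng.permutation(i.size)
    seen = set()
    out = []
    for k in order:
        key = (int(i[k]), int(j[k]))
        if key in seen:
            continue
        seen.add(key)
        out.append({"chrom": chrom, "bin1": key[0], "bin2": key[1],
                    "genotype": genotype})
        if len(out) >= n:
            break
    return out


def apply_ddm1_redistribution(truth: TruthSet, cfg: SimulationConfig) -> TruthSet:
    """Derive the mutant truth: relocate H3K27me3 core-ward, erode it in arms.

    Exactly ``round(rho_relocate * n_core)`` constitutive bins become
    facultative (classes II and III, split by ``class3_frac``), and
    ``round(rho_loss * n_fac)`` WT facultative bins become active-like
    (class I). Sampling is genome-wide and deterministic given the seed.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "ddm1")
    out = TruthSet(
        genome=truth.genome,
        state_wt=truth.state_wt.copy(),
        state_mut=truth.state_wt.copy(),
        domains=truth.domains.copy(),
        anchor_pairs=truth.anchor_pairs.copy(),
        class_label=np.full(truth.genome.n_bins, "none", dtype=object),
        compartment_label=truth.compartment_label.copy(),
    )
    core_bins = np.flatnonzero(truth.state_wt == "const_het")
    fac_bins = np.flatnonzero(truth.state_wt == "fac_het")

    n_reloc = int(round(cfg.rho_relocate * core_bins.size))
    reloc = rng.choice(core_bins, size=n_reloc, replace=False)
    reloc.sort()
    n_class3 = int(round(cfg.class3_frac * n_reloc))
    class3 = rng.choice(reloc, size=n_class3, replace=False)
    out.state_mut[reloc] = "fac_het"
    out.class_label[reloc] = "II"
    out.class_label[class3] = "III"

    n_loss = int(round(cfg.rho_loss * fac_bins.size))
    loss = rng.choice(fac_bins, size=n_loss, replace=False)
    out.state_mut[loss] = "active"
    out.class_label[loss] = "I"

    # Mutant-specific boosted anchor pairs: preferentially between newly
    # facultative core bins and arm bins that carried H3K27me3 in the WT;
    # when nothing relocates, among WT facultative bins. Pairs already
    # boosted in both genotypes are excluded.
    if cfg.n_anchor_pairs_mut > 0:
        existing = set(
            zip(out.anchor_pairs["chrom"], out.anchor_pairs["bin1"],
                out.anchor_pairs["bin2"])
        )
        extra = []
        for chrom in truth.genome.names:
            sl = truth.genome.chrom_slice(chrom)
            local_reloc = reloc[(reloc >= sl.start) & (reloc < sl.stop)] - sl.start
            local_fac = fac_bins[(fac_bins >= sl.start) & (fac_bins < sl.stop)] - sl.start
            n_here = cfg.n_anchor_pairs_mut // cfg.n_chrom
            ends2 = local_reloc if local_reloc.size else local_fac
            cands = _sample_pairs(rng, local_fac, ends2, n_here + len(existing),
                                  cfg.anchor_d_range, chrom, "mut")
            cands = [c for c in cands
                     if (c["chrom"], c["bin1"], c["bin2"]) not in existing]
            extra.extend(cands[:n_here])
        out.anchor_pairs = pd.concat(
            [out.anchor_pairs, pd.DataFrame(extra)], ignore_index=True
        )
    out.validate()
    return out


def _affinity_matrix(cfg: SimulationConfig, genotype: str) -> dict[tuple[str, str], float]:
    cross_rep = cfg.a_cross_rep if genotype == "wt" else cfg.a_cross_rep_mut
    a_ab = cfg.a_ab if genotype == "wt" else cfg.a_ab_mut
    aff = {
        ("active", "active"): cfg.a_aa,
        ("fac_het", "fac_het"): cfg.a_ff,
        ("const_het", "const_het"): cfg.a_cc,
        ("fac_het", "const_het"): cross_rep,
        ("active", "fac_het"): a_ab,
        ("active", "const_het"): a_ab,
    }
    for (s1, s2), v in list(aff.items()):
        aff[(s2, s1)] = v
    return aff


def simulate_contacts(
    truth: TruthSet, cfg: SimulationConfig, genotype: str = "wt"
) -> ContactMatrix:
    """Draw a raw cis contact matrix: Poisson counts with rate
    ``L * d^-alpha * A(s_i, s_j) * T_ij`` (T = TAD and anchor boosts), with L
    calibrated per chromosome so the expected total equals ``depth``.
    Diagonal is zero; the matrix is symmetric.
    """
    cfg.validate()
    if genotype not in ("wt", "ddm1"):
        raise ValueError(f"genotype must be 'wt' or 'ddm1', got {genotype!r}")
    rng = _rng(cfg.seed, f"contacts_{genotype}")
    states = truth.state_wt if genotype == "wt" else truth.state_mut
    aff = _affinity_matrix(cfg, genotype)
    tau = cfg.tau if genotype == "wt" else cfg.tau_mut
    genome = truth.genome
    data = {}
    for chrom in genome.names:
        sl = genome.chrom_slice(chrom)
        s = states[sl]
        n = s.size
        # state-pair affinity lookup
        codes = np.array([STATES.index(x) for x in s])
        lut = np.zeros((3, 3))
        for i1, s1 in enumerate(STATES):
            for i2, s2 in enumerate(STATES):
                lut[i1, i2] = aff[(s1, s2)]
        amat = lut[np.ix_(codes, codes)]
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        with np.errstate(divide="ignore"):
            decay = np.where(d > 0, d ** (-cfg.alpha), 0.0)
        boost = np.ones((n, n))
        for _, dom in truth.domains[truth.domains["chrom"] == chrom].iterrows():
            a, b = int(dom["start_bin"]), int(dom["end_bin"])
            boost[a:b, a:b] = tau
        pairs = truth.anchor_pairs[truth.anchor_pairs["chrom"] == chrom]
        for _, p in pairs.iterrows():
            if p["genotype"] == "both" or genotype == "ddm1":
                boost[int(p["bin1"]), int(p["bin2"])] *= cfg.anchor_boost
                boost[int(p["bin2"]), int(p["bin1"])] *= cfg.anchor_boost
        rate = decay * amat * boost
        np.fill_diagonal(rate, 0.0)
        upper = np.triu(rate, k=1)
        scale = cfg.depth / upper.sum()
        counts = rng.poisson(scale * upper)
        data[chrom] = (counts + counts.T).astype(float)
    return ContactMatrix(genome=genome, data=data, stage="raw")


def simulate_tracks(
    truth: TruthSet, cfg: SimulationConfig, genotype: str = "wt"
) -> dict[str, SignalTrack]:
    """Per-bin mark/methylation tracks: state base level x LogNormal(0, sigma).

    Class III bins carry a low WT H3K9me2 base (their defining feature:
    constitutive bins that gain H3K27me3 while H3K9me2 stays low).
    """
    cfg.validate()
    if genotype not in ("wt", "ddm1"):
        raise ValueError(f"genotype must be 'wt' or 'ddm1', got {genotype!r}")
    rng = _rng(cfg.seed, f"tracks_{genotype}")
    states = truth.state_wt if genotype == "wt" else truth.state_mut
    n = truth.genome.n_bins
    tracks = {}
    for mark in MARKS:
        base = np.array([BASE_LEVELS[s][mark] for s in states], dtype=float)
        if mark == "H3K9me2":
            base[truth.class_label == "III"] = CLASS3_K9ME2
        noise = (
            np.exp(rng.normal(0.0, cfg.sigma_track, size=n))
            if cfg.sigma_track > 0
            else np.ones(n)
        )
        tracks[mark] = SignalTrack(mark, truth.genome, base * noise)
    return tracks


def simulate_de_table(
    truth: TruthSet, genes: pd.DataFrame, cfg: SimulationConfig
) -> pd.DataFrame:
    """Per-gene log2 fold change and adjusted p, class-conditional.

    Genes in class I bins (H3K27me3 loss, de-repressed) are up-shifted
    (log2FC ~ N(2.5, 0.5), tiny padj); all other genes draw from a null
    (log2FC ~ N(0, 0.3), padj ~ U(0, 1)). A ``status`` column applies the
    conventional |log2FC| > 1 and padj < 0.05 cut.
    """
    rng = _rng(cfg.seed, "de")
    mids = ((genes["start"] + genes["end"]) // 2).to_numpy()
    bin_ids = np.array(
        [truth.genome.bin_index(c, int(m)) for c, m in zip(genes["chrom"], mids)]
    )
    cls = truth.class_label[bin_ids]
    n = len(genes)
    log2fc = rng.normal(0.0, 0.3, size=n)
    padj = rng.uniform(0.0, 1.0, size=n)
    up = cls == "I"
    log2fc[up] = rng.normal(2.5, 0.5, size=int(up.sum()))
    padj[up] = 10.0 ** rng.uniform(-8.0, -3.0, size=int(up.sum()))
    status = np.where(
        (padj < 0.05) & (log2fc > 1), "up",
        np.where((padj < 0.05) & (log2fc < -1), "down", "nc"),
    )
    return pd.DataFrame(
        {"gene_id": genes["name"].to_numpy(), "log2fc": log2fc,
         "padj": padj, "status": status}
    )


@dataclass
class SimulatedDataset:
    """Everything one paired simulation produces."""

    config: SimulationConfig
    genome: BinnedGenome
    truth: TruthSet
    matrices: dict[str, ContactMatrix]          # keys: wt, ddm1
    tracks: dict[str, dict[str, SignalTrack]]   # [genotype][mark]
    genes: pd.DataFrame
    tes: pd.DataFrame
    de_table: pd.DataFrame


def simulate_dataset(cfg: SimulationConfig, mode: str = "paired") -> SimulatedDataset:
    """Run the full generator. ``mode`` is 'paired', 'wt' or 'ddm1'."""
    if mode not in ("paired", "wt", "ddm1"):
        raise ValueError(f"mode must be 'paired', 'wt' or 'ddm1', got {mode!r}")
    genome, truth_wt, genes, tes = build_genome_layout(cfg)
    truth = apply_ddm1_redistribution(truth_wt, cfg)
    genotypes = {"paired": ("wt", "ddm1"), "wt": ("wt",), "ddm1": ("ddm1",)}[mode]
    matrices = {g: simulate_contacts(truth, cfg, g) for g in genotypes}
    tracks = {g: simulate_tracks(truth, cfg, g) for g in genotypes}
    de = simulate_de_table(truth, genes, cfg)
    return SimulatedDataset(cfg, genome, truth, matrices, tracks, genes, tes, de)
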