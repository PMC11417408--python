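"""Self-contained evaluation experiments on the synthetic study conditions.

Each function regenerates its inputs from a seed, runs the relevant slice of
the analysis pipeline, and returns the measured quantity — compartment-label
recovery, saddle strength and its affinity response, pentad category means,
feature-sorted segregation scores, insulation-dip and aggregate-TAD
differences, APA enrichment, differential-interaction calibration and
planted-pair recovery, and redistribution-classifier accuracy. The test
suite and the reproduction script both drive these.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import compartments as cp
from . import domains as dm
from . import epimarks as em
from . import hicmatrix as hm
from .aggregate_diff import AnchorSet, aggregate_anchor_pairs, differential_interactions
from .simgenome import SimulationConfig, simulate_dataset

# The differential-interaction experiments run at a higher sequencing depth:
# ranking a 3x contact boost among ~30k pairs needs the Poisson sd of the
# per-pair log2 ratio to sit well below log2(3), which at 50-kb bins requires
# on the order of 4e6 cis contacts per 10-Mb chromosome.
DIFF_DEPTH = 4_000_000.0


def normalize(matrix, min_frac=0.1):
    """Standard chain: mask -> ICE -> expected -> O/E."""
    masked = hm.mask_low_coverage(matrix, min_frac)
    bal = hm.balance_ice(masked)
    oe = hm.observed_over_expected(bal, hm.expected_by_distance(bal))
    return bal, oe


def paired_metrics(seed: int, insulation_window: int = 4, delta: float = 0.2) -> dict:
    """All WT-vs-ddm1 comparative metrics for one paired simulation."""
    ds = simulate_dataset(SimulationConfig(seed=seed))
    out: dict = {}
    oes, profs = {}, {}
    for g in ("wt", "ddm1"):
        bal, oe = normalize(ds.matrices[g])
        pm = hm.pearson_map(oe)
        call = cp.call_compartments(pm, ds.tracks[g]["H3K9ac"])
        ok = call.labels != "masked"
        out[f"recovery_{g}"] = float(
            (call.labels[ok] == ds.truth.compartment_label[ok]).mean()
        )
        out[f"strength_{g}"] = cp.saddle_strength(oe, call).strength
        out[f"pentad_ab_{g}"] = cp.compartment_pentad(oe, call).means["AB"]
        out[f"sortscore_{g}"] = cp.feature_sorted_map(
            pm, ds.tracks[g]["H3K27me3"]
        )[1]
        oes[g] = oe
        profs[g] = dm.insulation_profile(bal, window=insulation_window)
    bounds_wt, _ = dm.call_boundaries(profs["wt"], delta=delta)
    for g in ("wt", "ddm1"):
        _, mean_prof, _ = dm.boundary_signal_matrix(
            profs[g], bounds_wt, flank_bins=insulation_window
        )
        out[f"dip_{g}"] = float(mean_prof[insulation_window])
    out["n_boundaries_wt"] = int(len(bounds_wt))
    planted = dm.DomainSet(ds.truth.domains, "planted")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        aggs = {g: dm.aggregate_tads(oes[g], planted, k=30) for g in ("wt", "ddm1")}
    diff = dm.diff_aggregate(aggs["wt"], aggs["ddm1"])
    k = diff.matrix.shape[0]
    mid = slice(k // 4, k - k // 4)
    out["ata_central_wt"] = float(np.nanmean(aggs["wt"].matrix[mid, mid]))
    out["ata_central_ddm1"] = float(np.nanmean(aggs["ddm1"].matrix[mid, mid]))
    out["ata_central_diff"] = float(np.nanmean(diff.matrix[mid, mid]))
    return out


def strength_vs_affinity(seed: int, affinities=(1.2, 1.6, 2.0)) -> list[float]:
    """Saddle strength of WT simulations with uniform homotypic affinity a."""
    strengths = []
    for a in affinities:
        cfg = SimulationConfig(seed=seed, a_aa=a, a_ff=a, a_cc=a)
        ds = simulate_dataset(cfg, mode="wt")
        _, oe = normalize(ds.matrices["wt"])
        pm = hm.pearson_map(oe)
        call = cp.call_compartments(pm, ds.tracks["wt"]["H3K9ac"])
        strengths.append(cp.saddle_strength(oe, call).strength)
    return strengths


def boundary_f1(seed: int, window: int = 4, delta: float = 0.2,
                tol: int = 1) -> float:
    """Boundary recovery on a TAD-only simulation (uniform affinities,
    tau = 2), F1 against the planted domain edges at +/-``tol`` bins."""
    cfg = SimulationConfig(seed=seed, a_aa=1, a_ff=1, a_cc=1, a_cross_rep=1,
                           a_ab=1, tau=2.0)
    ds = simulate_dataset(cfg, mode="wt")
    bal, _ = normalize(ds.matrices["wt"])
    prof = dm.insulation_profile(bal, window=window)
    bounds, _ = dm.call_boundaries(prof, delta=delta)
    truth = {}
    for chrom, grp in ds.truth.domains.groupby("chrom"):
        edges = sorted(set(grp["start_bin"]) | set(grp["end_bin"]))
        n = ds.genome.chrom_nbins(chrom)
        truth[chrom] = [e for e in edges if 0 < e < n]
    tp, used = 0, set()
    for chrom, b in zip(bounds["chrom"], bounds["bin"]):
        for t in truth.get(chrom, []):
            if abs(b - t) <= tol and (chrom, t) not in used:
                used.add((chrom, t))
                tp += 1
                break
    n_called = len(bounds)
    n_truth = sum(len(v) for v in truth.values())
    if n_called == 0 or tp == 0:
        return 0.0
    prec, rec = tp / n_called, tp / n_truth
    return 2 * prec * rec / (prec + rec)


def apa_enrichment(seed: int) -> float:
    """Center/corner enrichment of the planted 3x-boosted anchor pairs."""
    ds = simulate_dataset(SimulationConfig(seed=seed), mode="wt")
    _, oe = normalize(ds.matrices["wt"])
    anch = ds.truth.anchor_pairs
    bs = ds.genome.bin_size
    s1 = AnchorSet(pd.DataFrame({
        "chrom": anch["chrom"], "start": anch["bin1"] * bs,
        "end": (anch["bin1"] + 1) * bs}), "anchors_left")
    s2 = AnchorSet(pd.DataFrame({
        "chrom": anch["chrom"], "start": anch["bin2"] * bs,
        "end": (anch["bin2"] + 1) * bs}), "anchors_right")
    return aggregate_anchor_pairs(oe, s1, s2)["enrichment"]


def null_z_fraction(seed: int) -> float:
    """Fraction of |z| > 1.96 between two independent identical simulations."""
    oes = []
    for k in (1, 2):
        ds = simulate_dataset(
            SimulationConfig(seed=seed * 10 + k, depth=DIFF_DEPTH), mode="wt"
        )
        oes.append(normalize(ds.matrices["wt"])[1])
    table = differential_interactions(*oes)
    return float((table["z"].abs() > 1.96).mean())


def planted_pair_recovery(seed: int, n_planted: int = 30, top: int = 100) -> float:
    """Fraction of planted mutant-specific boosted pairs ranking in the top
    ``top`` by |z|. Genotypes differ only by the planted pairs."""
    cfg = SimulationConfig(
        seed=seed, depth=DIFF_DEPTH, n_anchor_pairs_mut=n_planted,
        rho_relocate=0.0, rho_loss=0.0,
        a_ab_mut=0.5, a_cross_rep_mut=0.8, tau_mut=2.0,
    )
    ds = simulate_dataset(cfg)
    oe_wt = normalize(ds.matrices["wt"])[1]
    oe_mut = normalize(ds.matrices["ddm1"])[1]
    table = differential_interactions(oe_wt, oe_mut)
    mut_pairs = ds.truth.anchor_pairs[ds.truth.anchor_pairs["genotype"] == "mut"]
    planted = set(zip(mut_pairs["chrom"], mut_pairs["bin1"], mut_pairs["bin2"]))
    head = table.head(top)
    found = set(zip(head["chrom"], head["bin1"], head["bin2"])) & planted
    return len(found) / len(planted)


def classifier_accuracy(seed: int, sigma: float) -> float:
    """Redistribution-class agreement with planted labels over changed bins."""
    ds = simulate_dataset(SimulationConfig(seed=seed, sigma_track=sigma))
    regions = em.bins_as_regions(ds.genome)
    deltas = {}
    for mark in ("H3K27me3", "H3K9me2", "H3K27me1"):
        deltas[mark] = em.differential_signal(
            ds.tracks["wt"][mark].scaled(), ds.tracks["ddm1"][mark].scaled(),
            regions, center=True,
        )
    classes = em.classify_redistribution(
        deltas["H3K27me3"], deltas["H3K9me2"], deltas["H3K27me1"]
    )
    truth = ds.truth.class_label
    changed = truth != "none"
    return float((classes.to_numpy()[changed] == truth[changed]).mean())
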