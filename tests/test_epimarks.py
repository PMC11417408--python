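import numpy as np
import pandas as pd
import pytest

from hetero3d import epimarks as em
from hetero3d.genome import BinnedGenome
from hetero3d.tracks import SignalTrack


@pytest.fixture
def genome():
    return BinnedGenome.from_dict({"c1": 500_000}, 50_000)  # 10 bins


def _track(genome, values, name="mark", norm="raw"):
    return SignalTrack(name, genome, np.asarray(values, float), norm)


def test_scale_tracks_examples(genome):
    t = _track(genome, np.full(10, 1.0))
    scaled = em.scale_tracks({"m": t})["m"]
    assert np.allclose(scaled.values, t.values)
    t7 = _track(genome, np.full(10, 7.0))
    assert np.allclose(em.scale_tracks({"m": t7})["m"].values, 1.0)
    a = _track(genome, np.full(10, 2.0))
    b = _track(genome, np.full(10, 5.0))
    out = em.scale_tracks({"a": a, "b": b})
    assert out["a"].values.mean() == pytest.approx(1.0)
    assert out["b"].values.mean() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        em.scale_tracks({"z": _track(genome, np.zeros(10))})


def _regions(genome, bins):
    bs = genome.bin_size
    return pd.DataFrame({
        "region_id": [str(b) for b in bins], "chrom": "c1",
        "start": [b * bs for b in bins], "end": [(b + 1) * bs for b in bins],
    })


def test_differential_signal_arithmetic(genome):
    wt = _track(genome, [0.9] + [1.0] * 9, norm="scaled")
    mut = _track(genome, [1.9] + [1.0] * 9, norm="scaled")
    out = em.differential_signal(wt, mut, _regions(genome, range(10)))
    assert out.loc["0", "delta"] == pytest.approx(1.0)
    assert out.loc["0", "status"] == "up"
    assert out.loc["5", "delta"] == pytest.approx(0.0)
    assert out.loc["5", "status"] == "nc"


def test_differential_signal_antisymmetric(genome):
    rng = np.random.default_rng(40)
    a = _track(genome, rng.random(10) + 0.1, norm="scaled")
    b = _track(genome, rng.random(10) + 0.1, norm="scaled")
    fwd = em.differential_signal(a, b, _regions(genome, range(10)))
    rev = em.differential_signal(b, a, _regions(genome, range(10)))
    assert np.allclose(fwd["delta"], -rev["delta"], atol=1e-12)


def test_differential_signal_requires_scaled(genome):
    t = _track(genome, np.ones(10))
    with pytest.raises(ValueError):
        em.differential_signal(t, t, _regions(genome, [0]))


def test_differential_signal_region_outside_genome(genome):
    t = _track(genome, np.ones(10), norm="scaled")
    bad = pd.DataFrame({"region_id": ["x"], "chrom": ["c1"],
                        "start": [0], "end": [600_000]})
    with pytest.raises(ValueError):
        em.differential_signal(t, t, bad)


def _delta_frame(statuses, lows=None):
    lows = lows or [False] * len(statuses)
    return pd.DataFrame({
        "status": statuses, "low_flag": lows,
        "delta": [0.0] * len(statuses),
    }, index=pd.Index([str(i) for i in range(len(statuses))], name="region_id"))


@pytest.mark.parametrize("k27me3,k9me2,k27me1,k9low,expected", [
    ("down", "nc", "up", False, "I"),
    ("down", "up", "nc", False, "I"),
    ("up", "down", "down", False, "II"),
    ("up", "nc", "down", True, "III"),
    ("up", "nc", "down", False, "none"),   # III requires the low flag
    ("up", "up", "down", False, "none"),
    ("nc", "down", "down", False, "none"),
    ("down", "down", "nc", False, "none"),
])
def test_classifier_rule_cases(k27me3, k9me2, k27me1, k9low, expected):
    cls = em.classify_redistribution(
        _delta_frame([k27me3]), _delta_frame([k9me2], [k9low]),
        _delta_frame([k27me1]),
    )
    assert cls.iloc[0] == expected


def test_classifier_is_pure_and_classes_disjoint():
    statuses = ["up", "down", "nc"]
    rows = [(a, b, c, l) for a in statuses for b in statuses
            for c in statuses for l in (True, False)]
    k27me3 = _delta_frame([r[0] for r in rows])
    k9me2 = _delta_frame([r[1] for r in rows], [r[3] for r in rows])
    k27me1 = _delta_frame([r[2] for r in rows])
    c1 = em.classify_redistribution(k27me3, k9me2, k27me1)
    c2 = em.classify_redistribution(k27me3, k9me2, k27me1)
    assert (c1 == c2).all()
    # each combination lands in exactly one class
    assert set(c1.unique()) <= {"I", "II", "III", "none"}


def test_classifier_noise_free_recovery():
    """Noise-free tracks: classes match the planted labels exactly."""
    from hetero3d.simgenome import SimulationConfig, simulate_dataset

    ds = simulate_dataset(SimulationConfig(seed=3, sigma_track=0.0))
    regions = em.bins_as_regions(ds.genome)
    deltas = {}
    for mark in ("H3K27me3", "H3K9me2", "H3K27me1"):
        deltas[mark] = em.differential_signal(
            ds.tracks["wt"][mark].scaled(), ds.tracks["ddm1"][mark].scaled(),
            regions, center=True,
        )
    cls = em.classify_redistribution(
        deltas["H3K27me3"], deltas["H3K9me2"], deltas["H3K27me1"])
    assert (cls.to_numpy() == ds.truth.class_label).all()


# ---------------------------------------------------------------------------
# TE location and superfamilies


def test_te_location_zero_gene_window_is_poor(genome):
    tes = pd.DataFrame({"chrom": ["c1", "c1"], "start": [0, 400_000],
                        "end": [5_000, 405_000]})
    genes = pd.DataFrame({"chrom": ["c1"] * 4,
                          "start": [400_000, 420_000, 440_000, 460_000],
                          "end": [410_000, 430_000, 450_000, 470_000]})
    out = em.classify_te_location(tes, genes, genome, window_bp=100_000)
    assert out.loc[0, "location_class"] == "gene_poor"
    assert out.loc[1, "location_class"] == "gene_rich"


def test_te_location_ties_go_gene_rich(genome):
    tes = pd.DataFrame({"chrom": ["c1"] * 3, "start": [100_000, 200_000, 300_000],
                        "end": [105_000, 205_000, 305_000]})
    genes = pd.DataFrame({"chrom": [], "start": [], "end": []})
    out = em.classify_te_location(tes, genes, genome)
    assert (out["location_class"] == "gene_rich").all()


def test_te_location_recovers_simulated_layout():
    from hetero3d.simgenome import SimulationConfig, build_genome_layout

    cfg = SimulationConfig(seed=4)
    genome, truth, genes, tes = build_genome_layout(cfg)
    out = em.classify_te_location(tes, genes, genome)
    agree = (np.where(out["location"] == "arm", "gene_rich", "gene_poor")
             == out["location_class"]).mean()
    assert agree >= 0.95


def test_superfamily_subset_equals_genome_null():
    te = pd.DataFrame({"superfamily": ["Gypsy"] * 10 + ["Copia"] * 10})
    out = em.superfamily_composition(te, te).set_index("superfamily")
    assert np.allclose(out["z"], 0.0)
    assert np.allclose(out["pvalue"], 1.0)


def test_superfamily_two_proportion_hand_oracle():
    subset = pd.DataFrame({"superfamily": ["Gypsy"] * 30 + ["Copia"] * 20})
    genome_tes = pd.DataFrame({"superfamily": ["Gypsy"] * 100 + ["Copia"] * 300})
    out = em.superfamily_composition(subset, genome_tes).set_index("superfamily")
    assert out.loc["Gypsy", "p_subset"] == pytest.approx(0.6)
    assert out.loc["Gypsy", "p_genome"] == pytest.approx(0.25)
    p1, p2, n1, n2 = 0.6, 0.25, 50, 400
    p = (30 + 100) / (n1 + n2)
    z_hand = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    assert out.loc["Gypsy", "z"] == pytest.approx(z_hand, abs=1e-12)


def test_superfamily_singleton_subset_warns():
    subset = pd.DataFrame({"superfamily": ["Gypsy"]})
    genome_tes = pd.DataFrame({"superfamily": ["Gypsy"] * 5 + ["Copia"] * 5})
    with pytest.warns(UserWarning):
        out = em.superfamily_composition(subset, genome_tes)
    assert set(out["p_subset"]) <= {0.0, 1.0}
    with pytest.raises(ValueError):
        em.superfamily_composition(subset.iloc[:0], genome_tes)


# ---------------------------------------------------------------------------
# region signal matrix


def test_region_matrix_constant_track(genome):
    t = _track(genome, np.full(10, 4.2))
    regions = _regions(genome, [1, 5])
    mat, mean, order = em.region_signal_matrix(t, regions, k=5)
    assert np.allclose(mat, 4.2)
    assert np.allclose(mean, 4.2)


def test_region_matrix_exact_block_means():
    genome = BinnedGenome.from_dict({"c1": 300_000}, 50_000)  # 6 bins
    t = _track(genome, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    regions = pd.DataFrame({"region_id": ["r"], "chrom": ["c1"],
                            "start": [0], "end": [300_000]})
    mat, _, _ = em.region_signal_matrix(t, regions, k=3)
    assert np.allclose(mat[0], [1.5, 3.5, 5.5], atol=1e-12)


def test_region_matrix_sort_key_permutes_rows_only(genome):
    rng = np.random.default_rng(41)
    t = _track(genome, rng.random(10))
    regions = _regions(genome, [0, 3, 7])
    m1, mean1, ord1 = em.region_signal_matrix(t, regions, k=4)
    m2, mean2, ord2 = em.region_signal_matrix(
        t, regions, k=4, sort_values=np.array([3.0, 1.0, 2.0]))
    assert np.allclose(mean1, mean2, atol=1e-12)
    assert sorted(map(tuple, m1)) == sorted(map(tuple, m2))
    assert ord2.tolist() == ["0", "7", "3"]


# ---------------------------------------------------------------------------
# expression integration


def test_integrate_all_nc_single_cell():
    de = pd.DataFrame({"gene_id": ["g1", "g2"], "log2fc": [0, 0],
                       "padj": [0.9, 0.8], "status": ["nc", "nc"]})
    deltas = {"H3K27me3": pd.DataFrame(
        {"status": ["nc", "nc"]}, index=pd.Index(["g1", "g2"]))}
    tab, unjoined = em.integrate_expression(de, deltas)
    assert len(tab) == 1
    assert tab["fraction"].iloc[0] == pytest.approx(1.0)
    assert len(unjoined) == 0


def test_integrate_fraction_arithmetic():
    genes = [f"g{i}" for i in range(10)]
    de = pd.DataFrame({"gene_id": genes, "log2fc": [2.0] * 10,
                       "padj": [0.001] * 10, "status": ["up"] * 10})
    k27 = pd.DataFrame({"status": ["down"] * 4 + ["nc"] * 6},
                       index=pd.Index(genes))
    tab, _ = em.integrate_expression(de, {"H3K27me3": k27})
    fr = tab.set_index("H3K27me3_status")["fraction"]
    assert fr["down"] == pytest.approx(0.4)
    assert fr["nc"] == pytest.approx(0.6)
    assert tab.groupby("status")["fraction"].sum().iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_integrate_duplicated_ids_rejected():
    de = pd.DataFrame({"gene_id": ["g1", "g1"], "log2fc": [0, 0],
                       "padj": [1, 1], "status": ["nc", "nc"]})
    with pytest.raises(ValueError):
        em.integrate_expression(de, {})


def test_integrate_modal_cell_is_class_i_for_up_genes():
    """DE table tied to planted classes: the K27me3-loss cell dominates
    up-regulated genes."""
    from hetero3d.simgenome import SimulationConfig, simulate_dataset

    ds = simulate_dataset(SimulationConfig(seed=6, sigma_track=0.0))
    regions = em.bins_as_regions(ds.genome)
    d27 = em.differential_signal(
        ds.tracks["wt"]["H3K27me3"].scaled(), ds.tracks["ddm1"]["H3K27me3"].scaled(),
        regions, center=True,
    )
    mids = ((ds.genes["start"] + ds.genes["end"]) // 2).to_numpy()
    bin_ids = [str(ds.genome.bin_index(c, int(m)))
               for c, m in zip(ds.genes["chrom"], mids)]
    per_gene = d27.loc[bin_ids].set_index(pd.Index(ds.genes["name"], name="gene_id"))
    tab, _ = em.integrate_expression(ds.de_table, {"H3K27me3": per_gene})
    up = tab[tab["status"] == "up"]
    modal = up.sort_values("count", ascending=False).iloc[0]
    assert modal["H3K27me3_status"] == "down"
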