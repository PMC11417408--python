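import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetero3d import hicmatrix as hm
from hetero3d.genome import BinnedGenome

from conftest import as_contact_matrix, symmetric_matrix


# ---------------------------------------------------------------------------
# bin_pairs


def _write_pairs(path, rows):
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        for k, (c1, p1, c2, p2) in enumerate(rows):
            fh.write(f"r{k}\t{c1}\t{p1}\t{c2}\t{p2}\t+\t-\n")


def test_bin_pairs_counts_and_boundaries(tmp_path, small_genome):
    path = tmp_path / "test.pairs"
    _write_pairs(path, [
        ("chrA", 10, "chrA", 20),
        ("chrA", 30, "chrA", 40),
        ("chrA", 5, "chrA", 45),          # three pairs inside bin 0
        ("chrA", 49_999, "chrA", 50_000),  # half-open boundary: bins 0 and 1
    ])
    cm = hm.bin_pairs(path, small_genome)
    assert cm.data["chrA"][0, 0] == 3
    assert cm.data["chrA"][0, 1] == 1 and cm.data["chrA"][1, 0] == 1


def test_bin_pairs_conserves_mass(tmp_path, small_genome):
    rng = np.random.default_rng(0)
    rows = [("chrA", int(p1), "chrA", int(p2))
            for p1, p2 in rng.integers(0, 500_000, size=(1000, 2))]
    path = tmp_path / "uniform.pairs"
    _write_pairs(path, rows)
    cm = hm.bin_pairs(path, small_genome)
    # diagonal counted once, off-diagonal mirrored: sum of upper triangle = 1000
    m = cm.data["chrA"]
    assert np.triu(m).sum() == 1000


def test_bin_pairs_rejects_unknown_chromosome_and_empty(tmp_path, small_genome):
    path = tmp_path / "bad.pairs"
    _write_pairs(path, [("chrZ", 1, "chrA", 2)])
    with pytest.raises(ValueError, match="chrZ"):
        hm.bin_pairs(path, small_genome)
    empty = tmp_path / "empty.pairs"
    empty.write_text("# nothing\n")
    with pytest.raises(ValueError):
        hm.bin_pairs(empty, small_genome)


# ---------------------------------------------------------------------------
# masking


def test_mask_zero_min_frac_masks_nothing():
    rng = np.random.default_rng(1)
    cm = as_contact_matrix(symmetric_matrix(rng, 10))
    out = hm.mask_low_coverage(cm, min_frac=0.0)
    assert out.mask["chrA"].all()


def test_mask_dead_bins():
    rng = np.random.default_rng(2)
    m = symmetric_matrix(rng, 30)
    dead = [3, 7, 11, 19, 28]
    m[dead, :] = 0.0
    m[:, dead] = 0.0
    out = hm.mask_low_coverage(as_contact_matrix(m), min_frac=0.1)
    assert sorted(np.flatnonzero(~out.mask["chrA"])) == dead
    assert np.isnan(out.data["chrA"][dead[0]]).all()


def test_mask_all_masked_rejected():
    # a threshold above every marginal (min_frac > 1 on a uniform matrix)
    # masks everything and must raise
    cm = as_contact_matrix(np.ones((5, 5)) - np.eye(5))
    with pytest.raises(ValueError):
        hm.mask_low_coverage(cm, min_frac=2.0)


# ---------------------------------------------------------------------------
# balancing


def test_balance_marginal_cv_small():
    rng = np.random.default_rng(3)
    cm = as_contact_matrix(symmetric_matrix(rng, 50))
    bal = hm.balance_ice(cm)
    marg = np.nansum(np.nan_to_num(bal.data["chrA"]), axis=1)
    cv = marg.std() / marg.mean()
    assert cv < 1e-4
    assert bal.converged
    assert np.isfinite(bal.weights["chrA"]).all()


def test_balance_doubly_stochastic_fixed_point():
    # circulant symmetric matrix with constant marginals
    n = 8
    m = np.ones((n, n)) - np.eye(n)
    cm = as_contact_matrix(m)
    bal = hm.balance_ice(cm)
    assert np.allclose(bal.weights["chrA"], 1.0, atol=1e-4)
    assert np.allclose(np.nan_to_num(bal.data["chrA"]), m, rtol=1e-4)


def test_balance_idempotent():
    rng = np.random.default_rng(4)
    cm = as_contact_matrix(symmetric_matrix(rng, 40))
    bal = hm.balance_ice(cm, tol=1e-8)
    again = hm.ContactMatrix(
        genome=bal.genome,
        data={c: np.nan_to_num(m) for c, m in bal.data.items()},
        stage="raw", mask={c: v.copy() for c, v in bal.mask.items()},
    )
    rebal = hm.balance_ice(again, tol=1e-8)
    assert np.allclose(rebal.weights["chrA"], 1.0, atol=1e-6)


def test_balance_diag_only_matrix():
    m = np.zeros((6, 6))
    np.fill_diagonal(m, 2.0)
    bal = hm.balance_ice(as_contact_matrix(m))
    off = np.nan_to_num(bal.data["chrA"]) - np.diag(np.diag(np.nan_to_num(bal.data["chrA"])))
    assert (off == 0).all()


def test_balance_zero_total_rejected():
    cm = as_contact_matrix(np.zeros((5, 5)))
    cm.mask["chrA"][:] = True
    with pytest.raises(ValueError):
        hm.balance_ice(cm)


# ---------------------------------------------------------------------------
# expected / OE / pearson


def test_expected_hand_example():
    m = np.array([
        [0, 2, 4, 8],
        [2, 0, 2, 4],
        [4, 2, 0, 2],
        [8, 4, 2, 0],
    ], dtype=float)
    exp = hm.expected_by_distance(as_contact_matrix(m))
    e = exp.values["chrA"]
    assert e[1] == 2 and e[2] == 4 and e[3] == 8


def test_expected_constant_matrix():
    m = np.full((5, 5), 3.0)
    np.fill_diagonal(m, 3.0)
    exp = hm.expected_by_distance(as_contact_matrix(m))
    assert np.allclose(exp.values["chrA"], 3.0)


def test_expected_excludes_masked_bins():
    m = np.array([
        [0, 1, 10],
        [1, 0, 1],
        [10, 1, 0],
    ], dtype=float)
    cm = as_contact_matrix(m)
    cm.mask["chrA"][1] = False
    exp = hm.expected_by_distance(cm)
    # only pair (0, 2) remains at d=2; d=1 has no unmasked pairs
    assert exp.values["chrA"][2] == 10
    assert exp.counts["chrA"][1] == 0 and np.isnan(exp.values["chrA"][1])


def test_expected_matches_enumeration_small():
    rng = np.random.default_rng(5)
    for _ in range(5):
        n = int(rng.integers(3, 7))
        m = symmetric_matrix(rng, n)
        cm = as_contact_matrix(m)
        exp = hm.expected_by_distance(cm)
        for d in range(1, n):
            vals = [m[i, i + d] for i in range(n - d)]
            assert exp.values["chrA"][d] == pytest.approx(np.mean(vals), abs=1e-12)


def test_oe_identity_and_hand_example():
    m = np.array([
        [0, 2, 4, 8],
        [2, 0, 2, 4],
        [4, 2, 0, 2],
        [8, 4, 2, 0],
    ], dtype=float)
    cm = as_contact_matrix(m)
    oe = hm.observed_over_expected(cm, hm.expected_by_distance(cm))
    assert oe.data["chrA"][0, 3] == pytest.approx(1.0)
    assert oe.stage == "oe"


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_oe_per_diagonal_unit_mean(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 25))
    m = symmetric_matrix(rng, n, jitter=2.0)
    cm = as_contact_matrix(m)
    oe = hm.observed_over_expected(cm, hm.expected_by_distance(cm))
    for d in range(1, n):
        diag = np.diagonal(oe.data["chrA"], offset=d)
        diag = diag[np.isfinite(diag)]
        if diag.size:
            assert abs(diag.mean() - 1.0) < 1e-9


def test_oe_genome_mismatch_rejected():
    rng = np.random.default_rng(6)
    cm1 = as_contact_matrix(symmetric_matrix(rng, 5))
    cm2 = as_contact_matrix(symmetric_matrix(rng, 6))
    with pytest.raises(ValueError):
        hm.observed_over_expected(cm1, hm.expected_by_distance(cm2))


def test_pearson_two_block_closed_form():
    # two blocks with OE within=2, between=0.5: columns within a block are
    # identical -> correlation 1; across blocks perfectly anticorrelated
    n = 10
    oe = np.full((n, n), 0.5)
    oe[:5, :5] = 2.0
    oe[5:, 5:] = 2.0
    cm = as_contact_matrix(oe, stage="raw")
    cm.stage = "oe"
    p = hm.pearson_map(cm)
    c = p.data["chrA"]
    assert np.allclose(c[:5, :5], 1.0)
    assert np.allclose(c[5:, :5], -1.0)
    assert np.allclose(c, c.T)
    assert np.allclose(np.diag(c), 1.0)


def test_pearson_requires_oe_stage_and_enough_bins():
    rng = np.random.default_rng(7)
    cm = as_contact_matrix(symmetric_matrix(rng, 5))
    with pytest.raises(hm.StageError):
        hm.pearson_map(cm)
    small = as_contact_matrix(symmetric_matrix(rng, 5), stage="raw")
    small.stage = "oe"
    small.mask["chrA"][2:] = False
    with pytest.raises(ValueError):
        hm.pearson_map(small)


def test_stage_transitions_forward_only():
    rng = np.random.default_rng(8)
    cm = as_contact_matrix(symmetric_matrix(rng, 12))
    bal = hm.balance_ice(cm)
    with pytest.raises(hm.StageError):
        hm.balance_ice(bal)
    oe = hm.observed_over_expected(bal, hm.expected_by_distance(bal))
    with pytest.raises(hm.StageError):
        hm.expected_by_distance(oe)
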