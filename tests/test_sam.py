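import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from imprintscan import BetaMatrix, SamConfig, SimConfig, sam_multiclass, sam_two_class, simulate_dataset, simulate_null_dataset
from imprintscan.errors import ValidationError

from conftest import TRIPLOID_ONLY, random_bm, two_group_sheet

FIXED_S0 = SamConfig(n_permutations=300, seed=0, s0_method="fixed_percentile", s0_percentile=5)


def manual_two_class_d(X, na, s0):
    """Independent oracle: the moderated statistic computed longhand."""
    A, B = X[:, :na], X[:, na:]
    nb = B.shape[1]
    r = A.mean(1) - B.mean(1)
    ss = ((A - A.mean(1, keepdims=True)) ** 2).sum(1) + (
        (B - B.mean(1, keepdims=True)) ** 2
    ).sum(1)
    s = np.sqrt((1 / na + 1 / nb) * ss / (na + nb - 2))
    return r / (s + s0), s


def test_statistic_matches_longhand_computation():
    rng = np.random.default_rng(10)
    sheet = two_group_sheet(4, 5)
    bm = random_bm(60, sheet, rng)
    res = sam_two_class(bm, sheet, "diandric", "digynic", FIXED_S0)
    X = bm.beta.to_numpy()
    _, s = manual_two_class_d(X, 4, 0.0)
    s0 = np.percentile(s, 5)
    d_expected, _ = manual_two_class_d(X, 4, s0)
    assert res.s0 == pytest.approx(s0)
    np.testing.assert_allclose(res.d.to_numpy(), d_expected, rtol=1e-12)


def test_identical_groups_yield_zero_d_and_no_calls():
    sheet = two_group_sheet(3, 3)
    block = np.tile(np.array([[0.1], [0.5], [0.9]]), (1, 3))
    beta = pd.DataFrame(
        np.hstack([block, block]), index=["c1", "c2", "c3"], columns=sheet.index
    )
    res = sam_two_class(BetaMatrix(beta), sheet, "diandric", "digynic", FIXED_S0)
    assert np.allclose(res.d, 0.0, atol=1e-6)
    assert res.called == []


def test_sign_flip_symmetry():
    """Swapping the group roles flips d and leaves |d|, q, called unchanged."""
    rng = np.random.default_rng(2)
    sheet = two_group_sheet(4, 6)
    bm = random_bm(80, sheet, rng)
    cfg = SamConfig(n_permutations=300, seed=1)  # C(10,4)=210 -> exhaustive
    fwd = sam_two_class(bm, sheet, "diandric", "digynic", cfg)
    rev = sam_two_class(bm, sheet, "digynic", "diandric", cfg)
    assert fwd.exhaustive and rev.exhaustive
    np.testing.assert_allclose(fwd.d, -rev.d, rtol=1e-12)
    np.testing.assert_allclose(fwd.q, rev.q, rtol=1e-12)
    assert fwd.called == rev.called


def test_seed_determinism():
    cfg = SimConfig(
        n_background=300, n_maternal_dmr=5, n_paternal_dmr=5,
        n_tissue_specific=0, n_gestation_drift=0,
        samples_per_group=dict(TRIPLOID_ONLY), seed=4,
    )
    bm, sheet, _, _ = simulate_dataset(cfg)
    sam_cfg = SamConfig(n_permutations=200, seed=99)
    r1 = sam_two_class(bm, sheet, "diandric", "digynic", sam_cfg)
    r2 = sam_two_class(bm, sheet, "diandric", "digynic", sam_cfg)
    pd.testing.assert_frame_equal(r1.delta_table, r2.delta_table)
    assert r1.called == r2.called


def test_probe_shift_invariance():
    """Adding a constant to every sample at a probe leaves its d unchanged."""
    rng = np.random.default_rng(6)
    sheet = two_group_sheet(5, 5)
    bm = random_bm(40, sheet, rng)
    base = bm.beta.copy()
    base.iloc[0] = base.iloc[0].clip(0.0, 0.7)  # headroom for the shift
    shifted = base.copy()
    shifted.iloc[0] = shifted.iloc[0] + 0.2
    ra = sam_two_class(BetaMatrix(base), sheet, "diandric", "digynic", FIXED_S0)
    rb = sam_two_class(BetaMatrix(shifted), sheet, "diandric", "digynic", FIXED_S0)
    assert ra.d.iloc[0] == pytest.approx(rb.d.iloc[0], rel=1e-9)


def test_exhaustive_enumeration_small_design():
    rng = np.random.default_rng(7)
    sheet = two_group_sheet(2, 2)
    bm = random_bm(30, sheet, rng)
    res = sam_two_class(bm, sheet, "diandric", "digynic", SamConfig(n_permutations=100, seed=0))
    assert res.exhaustive and res.n_permutations_used == 6  # C(4,2)


def test_group_below_two_samples_rejected(tiny_bm):
    sheet = pd.DataFrame(
        {"sample_id": ["s1", "s2", "s3", "s4"],
         "group": ["diandric", "digynic", "digynic", "digynic"]}
    ).set_index("sample_id")
    with pytest.raises(ValidationError):
        sam_two_class(tiny_bm, sheet, "diandric", "digynic")


def test_missing_values_drop_probe_with_warning():
    sheet = two_group_sheet(3, 3)
    rng = np.random.default_rng(8)
    bm = random_bm(10, sheet, rng)
    beta = bm.beta.copy()
    beta.iloc[0, 0] = np.nan
    with pytest.warns(UserWarning, match="missing"):
        res = sam_two_class(BetaMatrix(beta), sheet, "diandric", "digynic", FIXED_S0)
    assert len(res.d) == 9


def test_null_simulation_rarely_calls_anything():
    zero_call_runs = 0
    for seed in range(3):
        cfg = SimConfig(
            n_background=2000, samples_per_group=dict(TRIPLOID_ONLY), seed=seed
        )
        bm, sheet, _, _ = simulate_null_dataset(cfg)
        res = sam_two_class(
            bm, sheet, "diandric", "digynic", SamConfig(n_permutations=200, seed=seed)
        )
        zero_call_runs += res.called == []
    assert zero_call_runs == 3


def test_spiked_probes_recovered():
    cfg = SimConfig(
        n_background=1000, n_maternal_dmr=25, n_paternal_dmr=25,
        n_tissue_specific=0, n_gestation_drift=0,
        samples_per_group=dict(TRIPLOID_ONLY), seed=12,
    )
    bm, sheet, _, truth = simulate_dataset(cfg)
    res = sam_two_class(bm, sheet, "diandric", "digynic", SamConfig(n_permutations=200, seed=12))
    imprinted = set(truth.probes_of("maternal_dmr")) | set(truth.probes_of("paternal_dmr"))
    called = set(res.called)
    assert len(called & imprinted) >= 48  # >= 95% of 50
    assert len(called - imprinted) == 0


# ---------------------------------------------------------------- multiclass
def test_multiclass_k2_equals_absolute_two_class_d():
    rng = np.random.default_rng(13)
    sheet = two_group_sheet(5, 5)
    bm = random_bm(50, sheet, rng)
    two = sam_two_class(bm, sheet, "diandric", "digynic", FIXED_S0)
    multi = sam_multiclass(bm, sheet, ["diandric", "digynic"], FIXED_S0)
    np.testing.assert_allclose(multi.d, np.abs(two.d), rtol=1e-10)
    rho = spearmanr(multi.d, two.d**2).statistic
    assert rho == pytest.approx(1.0)


def test_multiclass_identical_groups_zero_calls():
    ids = [f"s{i}" for i in range(9)]
    sheet = pd.DataFrame(
        {"sample_id": ids, "group": ["brain"] * 3 + ["kidney"] * 3 + ["muscle"] * 3}
    ).set_index("sample_id")
    rng = np.random.default_rng(1)
    col = rng.uniform(0.1, 0.9, 40)
    beta = pd.DataFrame(
        np.tile(col[:, None], (1, 9)), index=[f"cg{i}" for i in range(40)], columns=ids
    )
    res = sam_multiclass(BetaMatrix(beta), sheet, ["brain", "kidney", "muscle"], FIXED_S0)
    assert np.allclose(res.d, 0.0, atol=1e-6) and res.called == []


def test_multiclass_shifted_group_detected():
    rng = np.random.default_rng(14)
    ids = [f"s{i}" for i in range(24)]
    sheet = pd.DataFrame(
        {"sample_id": ids, "group": ["brain"] * 8 + ["kidney"] * 8 + ["placenta_mid"] * 8}
    ).set_index("sample_id")
    base = rng.uniform(0.2, 0.5, (100, 24))
    base[:5, 16:] += 0.3  # placenta shifted at 5 designated probes
    beta = pd.DataFrame(
        base + rng.normal(0, 0.02, base.shape),
        index=[f"cg{i}" for i in range(100)], columns=ids,
    ).clip(0, 1)
    res = sam_multiclass(
        BetaMatrix(beta), sheet, ["brain", "kidney", "placenta_mid"],
        SamConfig(n_permutations=200, seed=14),
    )
    called = set(res.called)
    assert {f"cg{i}" for i in range(5)} <= called
    assert len(called - {f"cg{i}" for i in range(5)}) == 0
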