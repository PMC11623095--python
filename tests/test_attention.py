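"""MSR-SA operator: grouping, geometry, sampling, fusion and attention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msrunet import (
    ConfigurationError,
    GroupSpec,
    MSRAttention,
    Tensor,
    auto_group_specs,
    dilated_sample,
    dilation_rate,
    fuse_cross_window,
    group_attention,
    partition_windows,
    split_groups,
)
from msrunet.attention import sample_valid_mask, unpartition_windows

from conftest import dense_attention


# ---------------------------------------------------------------- grouping
def test_split_groups_slices_channels():
    x = np.arange(4 * 4 * 8, dtype=float).reshape(4, 4, 8)
    parts = split_groups(x, 2)
    assert len(parts) == 2
    assert np.array_equal(parts[0].data, x[..., :4])
    assert np.array_equal(parts[1].data, x[..., 4:])


def test_split_groups_identity_for_single_group():
    x = np.ones((4, 4, 8))
    (only,) = split_groups(x, 1)
    assert np.array_equal(only.data, x)


def test_split_groups_round_trip(rng):
    x = rng.normal(size=(2, 5, 6, 12))
    parts = split_groups(x, 3)
    back = np.concatenate([p.data for p in parts], axis=-1)
    assert np.array_equal(back, x)


def test_split_groups_indivisible_raises():
    with pytest.raises(ConfigurationError, match="8.*3|3.*8"):
        split_groups(np.ones((4, 4, 8)), 3)


# ------------------------------------------------------------ dilation law
@pytest.mark.parametrize("S,M,expected", [(7, 7, 1), (13, 7, 2), (25, 7, 4)])
def test_dilation_rate_values(S, M, expected):
    assert dilation_rate(S, M) == expected


def test_dilation_rate_invalid_pairing():
    with pytest.raises(ConfigurationError, match="pairing"):
        dilation_rate(10, 7)


def test_group_spec_enforces_window_dilation_consistency():
    with pytest.raises(ConfigurationError, match="window"):
        GroupSpec(index=1, channels=4, window=12, dilation=2, grid=7).validate(32, 32)
    # valid: S = D*(M-1)+1
    GroupSpec(index=1, channels=4, window=13, dilation=2, grid=7).validate(32, 32)


def test_group_spec_rejects_window_larger_than_map():
    spec = GroupSpec(index=1, channels=4, window=13, dilation=2, grid=7)
    with pytest.raises(ConfigurationError, match="exceeds"):
        spec.validate(8, 8)


# ------------------------------------------------------- window partitioning
def test_partition_14x14_into_four_windows(rng):
    x = rng.normal(size=(14, 14, 3))
    win, pad, valid = partition_windows(x, 7)
    assert win.shape == (4, 7, 7, 3)
    assert pad == (0, 0)
    assert valid.all()
    assert np.array_equal(win.data[0], x[:7, :7])
    assert np.array_equal(win.data[3], x[7:, 7:])


def test_partition_single_window_when_side_equals_map(rng):
    x = rng.normal(size=(7, 7, 2))
    win, pad, valid = partition_windows(x, 7)
    assert win.shape == (1, 7, 7, 2)
    assert np.array_equal(win.data[0], x)


def test_partition_pads_and_restores_10x10(rng):
    x = rng.normal(size=(10, 10, 2))
    win, pad, valid = partition_windows(x, 7)
    assert win.shape == (4, 7, 7, 2)
    assert pad == (4, 4)
    assert valid.sum() == 100  # only original pixels flagged valid
    back = unpartition_windows(win, 10, 10)
    assert np.array_equal(back.data, x)


# ----------------------------------------------------------- dilated sampling
def test_dilated_sample_identity_when_dense(rng):
    w = rng.normal(size=(3, 7, 7, 2))
    s = dilated_sample(w, 7, 1)
    assert np.array_equal(s.data, w)


def test_dilated_sample_grid_indices(rng):
    w = rng.normal(size=(1, 13, 13, 1))
    s = dilated_sample(w, 7, 2)
    assert s.shape == (1, 7, 7, 1)
    assert np.array_equal(s.data, w[:, ::2, ::2, :])


def test_dilated_sample_always_49_points_for_default_grid(rng):
    for S, D in [(7, 1), (13, 2), (19, 3), (25, 4)]:
        w = rng.normal(size=(2, S, S, 3))
        s = dilated_sample(w, 7, D)
        assert s.shape[1] * s.shape[2] == 49


def test_dilated_sample_inconsistent_triple_raises():
    with pytest.raises(ConfigurationError, match="inconsistent"):
        dilated_sample(np.ones((1, 13, 13, 1)), 7, 3)


# ------------------------------------------------------------- fusion
def test_fusion_single_window_is_identity(rng):
    x = rng.normal(size=(1, 49, 4))
    for mode in ("max", "mean"):
        out = fuse_cross_window(x, mode)
        assert np.allclose(out.data, x[0])


def test_fusion_max_mean_values():
    x = np.stack([np.full((4, 2), 1.0), np.full((4, 2), 3.0)])
    assert np.allclose(fuse_cross_window(x, "max").data, 3.0)
    assert np.allclose(fuse_cross_window(x, "mean").data, 2.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_fusion_window_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(5, 9, 3))
    perm = rng.permutation(5)
    for mode in ("max", "mean"):
        a = fuse_cross_window(x, mode).data
        b = fuse_cross_window(x[perm], mode).data
        assert np.array_equal(a, b)  # bitwise


def test_fusion_excludes_padded_positions():
    x = np.stack([np.zeros((4, 1)), np.full((4, 1), -5.0)])
    valid = np.array([[True] * 4, [False] * 4])
    # max over only the valid window = 0, not -5 ... but also not +penalty
    assert np.allclose(fuse_cross_window(x, "max", valid).data, 0.0)
    x2 = np.stack([np.full((4, 1), 2.0), np.full((4, 1), 10.0)])
    assert np.allclose(fuse_cross_window(x2, "mean", valid).data, 2.0)


def test_fusion_linear_weighted_sum():
    x = np.stack([np.full((2, 1), 1.0), np.full((2, 1), 3.0)])
    out = fuse_cross_window(x, "linear", weights=np.array([0.25, 0.75]))
    assert np.allclose(out.data, 0.25 * 1 + 0.75 * 3)
    with pytest.raises(ConfigurationError, match="weight"):
        fuse_cross_window(x, "linear")


def test_fusion_unknown_mode_lists_valid_modes():
    with pytest.raises(ConfigurationError, match="max.*mean.*linear"):
        fuse_cross_window(np.ones((1, 2, 2)), "median")


# ------------------------------------------------------------- attention
def test_single_key_attention_returns_value_row(rng):
    Q = rng.normal(size=(5, 3))
    K = rng.normal(size=(1, 3))
    V = rng.normal(size=(1, 3))
    out = group_attention(Q, K, V, h=3.0)
    assert np.allclose(out.data, np.broadcast_to(V, (5, 3)))


def test_identical_keys_give_value_mean(rng):
    Q = rng.normal(size=(4, 2))
    K = np.tile(rng.normal(size=(1, 2)), (6, 1))
    V = rng.normal(size=(6, 2))
    out = group_attention(Q, K, V, h=2.0)
    assert np.allclose(out.data, np.broadcast_to(V.mean(axis=0), (4, 2)))


def test_attention_matches_dense_oracle_small():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(2, 2))
    out = group_attention(x, x, x, h=2.0)
    ref = dense_attention(x.reshape(1, 2, 2), h=2.0).reshape(2, 2)
    assert np.allclose(out.data, ref, atol=1e-6)


def test_attention_rows_sum_to_one(rng):
    from msrunet.autograd import softmax

    Q = Tensor(rng.normal(size=(10, 4)))
    K = Tensor(rng.normal(size=(49, 4)))
    scores = Q @ K.transpose((1, 0))
    rows = softmax(scores, axis=-1).data.sum(axis=-1)
    assert np.allclose(rows, 1.0, atol=1e-6)


def test_attention_dimension_mismatch_raises(rng):
    with pytest.raises(ConfigurationError, match="mismatch"):
        group_attention(np.ones((4, 3)), np.ones((5, 2)), np.ones((5, 2)), h=1.0)


# ------------------------------------------------------------- full operator
def test_msr_sa_equals_dense_attention_in_degenerate_config(rng):
    """G=1, S=M=7, D=1 on a 7x7 map with identity projections reduces the
    operator to plain dense self-attention over the 49 tokens."""
    x = rng.normal(size=(1, 7, 7, 8))
    spec = GroupSpec(index=1, channels=8, window=7, dilation=1, grid=7)
    attn = MSRAttention(8, [spec], init="identity")
    out = attn(Tensor(x)).data
    ref = dense_attention(x[0], h=8.0)
    assert np.abs(out[0] - ref).max() <= 1e-5


def test_msr_sa_preserves_shape_any_valid_config(rng):
    x = rng.normal(size=(2, 16, 16, 12))
    specs = auto_group_specs(16, 16, 12, 3)
    attn = MSRAttention(12, specs, rng=rng)
    assert attn(Tensor(x)).shape == x.shape


def test_presets_differ_on_random_input(rng):
    x = Tensor(rng.normal(size=(1, 16, 16, 8)))
    out = {}
    for preset in ("default", "low"):
        specs = auto_group_specs(16, 16, 8, 4, preset=preset)
        attn = MSRAttention(8, specs, rng=np.random.default_rng(0))
        out[preset] = attn(x).data
    assert not np.allclose(out["default"], out["low"])


def test_key_count_constant_across_presets_and_window_sweep():
    for preset in ("default", "low", "high"):
        for side in (56, 28, 14, 7):
            for spec in auto_group_specs(side, side, 16, 4, preset=preset):
                spec.validate(side, side)
                assert spec.num_keys == 49
                assert dilation_rate(spec.window, spec.grid) == spec.dilation


def test_auto_specs_clamp_grid_on_tiny_maps():
    for side in (4, 2):
        for spec in auto_group_specs(side, side, 8, 2):
            spec.validate(side, side)
            assert spec.window == side  # dense attention on tiny maps
            assert spec.num_keys == side * side


def test_msr_sa_invalid_spec_fails_before_compute(rng):
    specs = [GroupSpec(index=1, channels=8, window=13, dilation=2, grid=7)]
    attn = MSRAttention(8, specs, rng=rng)
    with pytest.raises(ConfigurationError):
        attn(Tensor(rng.normal(size=(1, 8, 8, 8))))


def test_msr_sa_gradients_reach_all_projections(rng):
    specs = auto_group_specs(8, 8, 8, 2)
    attn = MSRAttention(8, specs, rng=rng)
    out = attn(Tensor(rng.normal(size=(1, 8, 8, 8))))
    (out * out).sum().backward()
    for name, p in attn.named_parameters():
        assert p.grad is not None and np.abs(p.grad).sum() > 0, name
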