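"""Layer parameter counting, kernel inversion, canonical builds, audits."""

import numpy as np
import pytest

import nodulecam as nc
from nodulecam.architectures import (
    ExpectedCount,
    InvalidSpecError,
    ShapeError,
    packaged_description_path,
)
from nodulecam.training import softmax


def spec(kind, cin=1, cout=1, **kw):
    return nc.LayerSpec(kind=kind, in_channels=cin, out_channels=cout, **kw)


@pytest.mark.parametrize(
    "layer, expected",
    [
        (spec("conv3d", 1, 16, kernel=6), 3472),
        (spec("batchnorm", 16, 16), 64),
        (spec("dense", 64, 256), 16640),
        (spec("conv3d", 1, 1, kernel=1), 2),
        (spec("conv2d", 1, 16, kernel=4), 272),
        (spec("conv3d", 16, 16, kernel=2, bias=False), 2048),
        (spec("maxpool3d", kernel=2), 0),
        (spec("flatten"), 0),
        (spec("dropout"), 0),
    ],
)
def test_count_parameters_closed_form(layer, expected):
    assert nc.count_parameters(layer) == expected


def test_count_is_independent_of_spatial_extent_and_padding():
    same = spec("conv3d", 4, 8, kernel=3, padding="same")
    valid = spec("conv3d", 4, 8, kernel=3, padding="valid")
    assert nc.count_parameters(same) == nc.count_parameters(valid)


def test_invalid_specs_rejected():
    with pytest.raises(InvalidSpecError):
        nc.LayerSpec(kind="conv4d")
    with pytest.raises(InvalidSpecError):
        spec("conv3d", 1, 16)  # kernel missing
    with pytest.raises(InvalidSpecError):
        spec("dense", 1, 16, kernel=3)  # kernel not applicable
    with pytest.raises(InvalidSpecError):
        spec("conv3d", 0, 16, kernel=3)


def brute_force_kernel(cin, cout, printed, ndim):
    hits = [k for k in range(1, 12) if k**ndim * cin * cout + cout == printed]
    return hits[0] if len(hits) == 1 else None


@pytest.mark.parametrize(
    "cin, cout, printed, ndim, expected",
    [
        (1, 16, 8208, 3, 8),
        (16, 32, 13856, 3, 3),
        (1, 16, 3472, 3, 6),
        (16, 16, 2064, 3, 2),
        (64, 32, 53328, 3, None),  # printed cell admits no integer kernel
        (64, 32, 18454, 2, None),
        (64, 32, 55328, 3, 3),  # the corrected value does
        (64, 32, 18464, 2, 3),
    ],
)
def test_derive_kernel_size_matches_brute_force(cin, cout, printed, ndim, expected):
    assert nc.derive_kernel_size(cin, cout, printed, ndim) == expected
    assert brute_force_kernel(cin, cout, printed, ndim) == expected


@pytest.mark.parametrize("name", ["alexnet2d", "alexnet3d", "proposed3d"])
def test_canonical_description_reproduces_printed_counts(name):
    desc = nc.canonical_description(name)
    for layer_spec, exp in zip(desc.layers, desc.expected_counts):
        assert nc.count_parameters(layer_spec) == exp.effective
        if not exp.known_typo:
            assert nc.count_parameters(layer_spec) == exp.printed


def test_proposed3d_structure():
    desc = nc.canonical_description("proposed3d")
    assert desc.input_shape == (1, 27, 27, 27)
    first = desc.layers[0]
    assert (first.kind, first.in_channels, first.out_channels, first.kernel,
            first.padding) == ("conv3d", 1, 16, 6, "same")
    # the flatten width is forced to 64 by the printed dense count 16640
    shapes = desc.trace_shapes()
    flat_idx = next(i for i, l in enumerate(desc.layers) if l.kind == "flatten")
    assert shapes[flat_idx] == (64,)
    assert shapes[flat_idx - 1] == (64, 1, 1, 1)


def test_alexnet3d_structure():
    desc = nc.canonical_description("alexnet3d")
    kernels = [l.kernel for l in desc.layers if l.kind == "conv3d"]
    assert kernels == [8, 3, 3, 3, 3]
    last = desc.layers[-1]
    assert (last.in_channels, last.out_channels) == (75, 2)
    assert nc.count_parameters(last) == 152


@pytest.mark.parametrize(
    "name, n_typos, typo_pairs",
    [
        ("proposed3d", 0, []),
        ("alexnet3d", 1, [(53328, 55328)]),
        ("alexnet2d", 1, [(18454, 18464)]),
    ],
)
def test_audit_passes_with_expected_typos(name, n_typos, typo_pairs):
    model = nc.build_model(nc.canonical_description(name), seed=0)
    report = nc.audit(model)
    assert report.passed
    typos = report.known_typos()
    assert len(typos) == n_typos
    assert [(t.printed, t.corrected) for t in typos] == typo_pairs
    for row in report.rows:
        assert row.status in ("match", "known-typo")


def test_audit_detects_mismatch():
    desc = nc.canonical_description("proposed3d")
    desc.expected_counts[0] = ExpectedCount(9999)
    report = nc.audit(nc.build_model(desc, seed=0))
    assert not report.passed
    assert report.rows[0].status == "mismatch"
    assert "FAIL" in report.to_table()


def test_build_is_deterministic_under_seed():
    desc = nc.canonical_description("proposed3d")
    a = nc.build_model(desc, seed=42).net.state()
    b = nc.build_model(desc, seed=42).net.state()
    c = nc.build_model(desc, seed=43).net.state()
    for key in a:
        np.testing.assert_array_equal(a[key], b[key])
    assert any(not np.array_equal(a[k], c[k]) for k in a)


def test_forward_pass_and_softmax_normalization():
    model = nc.build_model(nc.canonical_description("proposed3d"), seed=0)
    vol = np.random.default_rng(0).normal(size=(3, 1, 27, 27, 27))
    scores = model.forward(vol)
    assert scores.shape == (3, 2)
    probs = softmax(scores)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_uniform_init_respects_unit_bound():
    model = nc.build_model(nc.canonical_description("proposed3d"), seed=7)
    for layer in model.net.layers:
        if "w" in layer.params:
            assert np.abs(layer.params["w"]).max() <= 1.0


def test_shape_error_names_offending_layer():
    desc = nc.NetworkDescription(
        name="proposed3d",
        input_shape=(1, 4, 4, 4),
        layers=[
            nc.LayerSpec(kind="conv3d", in_channels=1, out_channels=2,
                         kernel=3, padding="valid"),
            nc.LayerSpec(kind="maxpool3d", kernel=4),
        ],
    )
    with pytest.raises(ShapeError, match="layer 1"):
        nc.build_model(desc, seed=0)


def test_channel_chain_invariant_enforced():
    with pytest.raises(InvalidSpecError):
        nc.NetworkDescription(
            name="proposed3d",
            input_shape=(1, 8, 8, 8),
            layers=[
                nc.LayerSpec(kind="conv3d", in_channels=1, out_channels=4,
                             kernel=3, padding="same"),
                nc.LayerSpec(kind="conv3d", in_channels=8, out_channels=4,
                             kernel=3, padding="same"),
            ],
        )


@pytest.mark.parametrize("name", ["alexnet2d", "alexnet3d", "proposed3d"])
def test_packaged_yaml_round_trip(name, tmp_path):
    desc = nc.canonical_description(name)
    shipped = nc.load_description(packaged_description_path(name))
    assert shipped.layers == desc.layers
    assert shipped.expected_counts == desc.expected_counts
    out = tmp_path / "desc.yaml"
    nc.save_description(desc, out)
    again = nc.load_description(out)
    assert again.layers == desc.layers
    assert nc.audit(nc.build_model(again, seed=0)).passed
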