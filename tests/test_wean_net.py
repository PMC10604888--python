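"""Architecture contracts: census, structural constants, variable-length
forward, component behaviours, checkpointing."""

import numpy as np
import pytest

from weanwave import nn
from weanwave.preprocess import PreprocessConfig
from weanwave.wean_net import (
    TABLE1_BNECKS,
    AssembledModel,
    BneckSpec,
    ConstructionError,
    ExtractorSpec,
    MLPSpec,
    ModelSpec,
    assemble_model,
    build_extractor,
    build_mlp,
    build_subblock,
    count_parameters,
    fuse_features,
    load_checkpoint,
    predict,
    save_checkpoint,
)

PUBLISHED_PARAMETER_COUNT = 17_124_721


@pytest.fixture(scope="module")
def default_model():
    return assemble_model(seed=0)


def test_default_census_matches_published_total(default_model):
    assert default_model.n_parameters == PUBLISHED_PARAMETER_COUNT
    assert count_parameters(default_model) == PUBLISHED_PARAMETER_COUNT


def test_census_breakdown_sums_to_total(default_model):
    assert sum(c for _, _, c in default_model.parameter_census) \
        == default_model.n_parameters
    for _, shape, count in default_model.parameter_census:
        assert count == int(np.prod(shape)) if shape else count == 1


def test_extractors_have_15_bottlenecks(default_model):
    assert default_model.model.wave_extractor.n_bnecks == 15
    assert default_model.model.num_extractor.n_bnecks == 15


def test_bneck_channel_sequences_match_backbone_table():
    outs = [b.out_channels for b in TABLE1_BNECKS]
    assert outs == [16, 24, 24, 32, 32, 32, 64, 64, 64, 64, 88, 88, 120, 120, 120]
    expands = [b.expand_size for b in TABLE1_BNECKS]
    assert expands == [16, 64, 72, 72, 96, 96, 192, 160, 144, 144, 384, 528,
                       528, 720, 720]
    acts = [b.activation for b in TABLE1_BNECKS]
    assert acts[:6] == ["relu"] * 6
    assert acts[6:] == ["hard_swish"] * 9
    assert [b.kernel for b in TABLE1_BNECKS] == [3, 3, 3, 5, 5, 5, 3, 3, 3, 3,
                                                 3, 3, 5, 5, 5]


def test_classifier_dimensions(default_model):
    m = default_model.model
    assert m.cls1.weight.shape[0] == 1280
    assert m.cls2.weight.shape == (1, 1280)


def test_extractor_pools_to_720_for_any_input_size():
    ex = build_extractor(ExtractorSpec(stem_in_channels=3),
                         rng=np.random.default_rng(0))
    for hw in [(100, 130), (90, 130), (32, 48)]:
        out = ex.forward(np.random.default_rng(1).random((1, 3) + hw))
        assert out.shape[1] == 720
        assert out.mean(axis=(2, 3)).shape == (1, 720)


def test_extractor_requires_15_bnecks():
    with pytest.raises(ConstructionError, match="15"):
        ExtractorSpec(stem_in_channels=3, bnecks=TABLE1_BNECKS[:14])


def test_extractor_head_must_be_720():
    with pytest.raises(ConstructionError, match="720"):
        ExtractorSpec(stem_in_channels=3, head_conv_out=512)


def test_bneck_expand_below_out_rejected():
    with pytest.raises(ConstructionError):
        BneckSpec(kernel=3, expand_size=8, out_channels=16,
                  activation="relu", use_se=False, stride=1)


def test_toy_census_conv_plus_norm():
    """One 3x3 conv 3->16 without bias plus its normalization:
    432 weights + 32 scale/shift entries = 464."""

    class Toy(nn.Module):
        def __init__(self):
            self.conv = nn.Conv2d(3, 16, 3)
            self.bn = nn.BatchNorm2d(16)

    assert count_parameters(Toy()) == 464


def test_empty_module_has_zero_parameters():
    class Empty(nn.Module):
        pass

    assert count_parameters(Empty()) == 0


@pytest.mark.parametrize("dim", [1, 8, 720])
def test_subblock_preserves_shape(dim):
    sb = build_subblock(dim, rng=np.random.default_rng(0))
    x = np.random.default_rng(1).standard_normal((3, dim))
    assert sb.forward(x).shape == (3, dim)


def test_subblock_zero_linears_reduce_to_skip_path():
    """With both linear layers zeroed the residual branch vanishes and the
    output is exactly the final activation of the input."""
    sb = build_subblock(6, hidden=11, rng=np.random.default_rng(0))
    for lin in (sb.lin1, sb.lin2):
        lin.weight.data[...] = 0.0
        lin.bias.data[...] = 0.0
    x = np.random.default_rng(2).standard_normal((4, 6))
    act = nn.SiLU()
    assert np.allclose(sb.forward(x), act.forward(x))


def test_subblock_gradient_flows_through_skip():
    sb = build_subblock(5, rng=np.random.default_rng(3))
    x = np.random.default_rng(4).standard_normal((2, 5))
    y = sb.forward(x)
    gx = sb.backward(np.ones_like(y))
    assert np.any(gx != 0)
    eps = 1e-6
    idx = (0, 2)
    x[idx] += eps
    fp = sb.forward(x).sum()
    x[idx] -= 2 * eps
    fm = sb.forward(x).sum()
    fd = (fp - fm) / (2 * eps)
    assert fd == pytest.approx(gx[idx], rel=1e-4, abs=1e-4)


def test_mlp_must_encode_to_lower_dimension():
    with pytest.raises(ConstructionError, match="lower"):
        build_mlp(MLPSpec(conv1x1_out=720, subblock_dim=720 * 20))


def test_mlp_output_dimension_is_subblock_dim():
    spec = MLPSpec(conv1x1_out=4, subblock_dim=80, subblock_hidden=16)
    mlp = build_mlp(spec, positions=20, rng=np.random.default_rng(0))
    fused = np.random.default_rng(1).random((2, 720, 1, 20))
    assert mlp.forward(fused).shape == (2, 80)


def test_fusion_produces_720_by_positions():
    rng = np.random.default_rng(0)
    wave = rng.random((2, 720, 4, 5))
    num = rng.random((2, 720, 2, 3))
    fused = fuse_features(wave, num, positions=20)
    assert fused.shape == (2, 720, 1, 20)


def test_fusion_identical_maps_give_identical_halves():
    m = np.random.default_rng(1).random((1, 720, 3, 10))
    fused = fuse_features(m, m, positions=20)
    assert np.allclose(fused[..., :10], fused[..., 10:])


def test_fusion_mean_preservation():
    """Average pooling preserves the mean, so the fused map's mean is the
    mean of the two branch means (hand-checkable on a 2-slot toy)."""
    a = np.arange(8, dtype=float).reshape(1, 1, 2, 4)
    a = np.tile(a, (1, 720, 1, 1))
    b = a + 10
    fused = fuse_features(a, b, positions=2)
    assert fused.mean() == pytest.approx((a.mean() + b.mean()) / 2)


def test_fusion_odd_positions_rejected():
    m = np.zeros((1, 720, 2, 2))
    with pytest.raises(Exception, match="even"):
        fuse_features(m, m, positions=3)


def test_forward_variable_lengths_constant_output_shape(default_model):
    rng = np.random.default_rng(2)
    m = default_model.model
    shapes = set()
    for (hw, hn) in [((7, 130), (7, 70)), ((12, 130), (9, 70))]:
        logit = m.forward(rng.random((2, 3) + hw), rng.random((2, 25) + hn))
        shapes.add(logit.shape)
    assert shapes == {(2,)}


def test_batch_permutation_equivariance(default_model):
    rng = np.random.default_rng(3)
    xw = rng.random((3, 3, 10, 130))
    xn = rng.random((3, 25, 4, 70))
    m = default_model.model
    out = m.forward(xw, xn)
    perm = [2, 0, 1]
    out_p = m.forward(xw[perm], xn[perm])
    assert np.allclose(out_p, out[perm])


def test_predict_probability_and_determinism(default_model, tiny_record, pp_tiny):
    p1 = predict(default_model, tiny_record, pp_tiny)
    p2 = predict(default_model, tiny_record, pp_tiny)
    assert 0.0 < p1 < 1.0
    assert p1 == p2


def test_predict_handles_prefix_cropped_record(default_model, tiny_record, pp_tiny):
    """Full records and shorter prefixes both produce a probability."""
    from dataclasses import replace
    from weanwave.vent_data import SBTRecord, WaveformRecording

    wf = tiny_record.waveform
    short = WaveformRecording(patient_id=wf.patient_id,
                              sample_period_ms=wf.sample_period_ms,
                              paw=wf.paw[:2000], flow=wf.flow[:2000],
                              volume=wf.volume[:2000])
    rec = SBTRecord(waveform=short, numeric=tiny_record.numeric)
    p = predict(default_model, rec, pp_tiny)
    assert 0.0 < p < 1.0


def test_checkpoint_roundtrip(tmp_path, default_model, tiny_record, pp_tiny):
    before = predict(default_model, tiny_record, pp_tiny)
    path = save_checkpoint(default_model, tmp_path / "model.npz")
    loaded = load_checkpoint(path)
    assert loaded.n_parameters == PUBLISHED_PARAMETER_COUNT
    after = predict(loaded, tiny_record, pp_tiny)
    assert after == pytest.approx(before, abs=1e-12)
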