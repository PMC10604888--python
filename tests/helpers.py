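"""Shared test utilities: rank statistics and the toy Grad-CAM /
occlusion-oracle trial used by both the explanation tests and the
acceptance suite."""

import numpy as np


def spearman(a, b):
    ra = np.argsort(np.argsort(a)).astype(float)
    rb = np.argsort(np.argsort(b)).astype(float)
    ra -= ra.mean()
    rb -= rb.mean()
    return float(np.sum(ra * rb) /
                 np.sqrt(np.sum(ra ** 2) * np.sum(rb ** 2)))


def toy_cam_and_occlusion(seed, n_blocks=8):
    """One trial on a toy model (conv -> ReLU -> GAP -> linear readout):
    returns (block-averaged cam, occlusion logit drops, raw cam,
    bright-region corner)."""
    from weanwave import nn
    from weanwave.explain import cam_from_activations

    rng = np.random.default_rng(seed)
    conv = nn.Conv2d(1, 4, 3, bias=True, rng=rng)
    relu = nn.ReLU()
    w = np.abs(rng.standard_normal(4)) + 0.1  # positive readout weights

    def logit_of(x):
        A = relu(conv(x[None]))
        return float(A.mean(axis=(2, 3))[0] @ w), A[0]

    x = rng.random((1, 12, 12)) * 0.3
    r0, c0 = rng.integers(0, 9, 2)
    x[0, r0:r0 + 3, c0:c0 + 3] += 2.0  # one bright region
    base, A = logit_of(x)
    H, W = A.shape[1:]
    gA = np.broadcast_to((w / (H * W))[:, None, None], A.shape) * (A > 0)
    _, cam = cam_from_activations(A, np.ascontiguousarray(gA))

    cols = np.array_split(np.arange(12), n_blocks // 2)
    rows = np.array_split(np.arange(12), 2)
    weights, drops = [], []
    for rr in rows:
        for cc in cols:
            xp = x.copy()
            xp[0][np.ix_(rr, cc)] = 0.0
            occluded, _ = logit_of(xp)
            drops.append(base - occluded)
            weights.append(cam[np.ix_(rr, cc)].mean())
    return np.array(weights), np.array(drops), cam, (r0, c0)
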