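"""Shared helpers: seeded random streams and small numeric utilities."""

from __future__ import annotations

import numpy as np

#: luminance weights for RGB -> gray (ITU-R BT.601)
LUMA = np.array([0.299, 0.587, 0.114])


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one seed into ``n`` independent substreams.

    Every stochastic stage of the pipeline draws from its own substream so
    stages can be re-run (or skipped) without perturbing the others.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n)]


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Per-pixel luminance of an (H, W, 3) raster, in the input's value range."""
    return rgb[..., :3].astype(float) @ LUMA


def blue_ratio(rgb: np.ndarray) -> np.ndarray:
    """Blue-ratio channel, emphasising basophilic (hematoxylin-dark) nuclei."""
    rgb = rgb.astype(float)
    return rgb[..., 2] / (1.0 + rgb[..., 0] + rgb[..., 1])
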