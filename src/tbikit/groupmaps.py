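"""Voxelwise group-difference FA maps.

The group comparison averages the diffusion tensor volumes within each
group (component-wise Euclidean mean), computes FA on each group's mean
tensor, and subtracts sham from injured — FA-of-mean, not mean-of-FA.
The two orderings agree only when the group is homogeneous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .dti import eigensystem, fa_from_eigenvalues
from .phantom import TensorField

__all__ = ["GroupTensorAverage", "average_tensors", "fa_map",
           "fa_difference_map", "render_overlay"]


@dataclass
class GroupTensorAverage:
    """Voxelwise mean tensor components for one group."""

    components: np.ndarray  # grid + (6,)
    n_samples: int

    @property
    def shape(self):
        return self.components.shape[:-1]


def _components(sample) -> np.ndarray:
    return sample.components if isinstance(sample, TensorField) else np.asarray(sample, float)


def average_tensors(samples: Sequence, method: str = "euclidean"
                    ) -> GroupTensorAverage:
    """Voxelwise mean of tensor fields on a shared grid.

    method="euclidean" (default) averages tensor components directly,
    matching the literal group-averaging procedure; "log-euclidean"
    averages matrix logarithms and exponentiates back (requires SPD
    voxels; non-positive eigenvalues are clamped first).
    """
    if len(samples) == 0:
        raise ValueError("need at least one sample")
    comps = [_components(s) for s in samples]
    shape = comps[0].shape
    for c in comps[1:]:
        if c.shape != shape:
            raise ValueError(f"grid mismatch: {c.shape} vs {shape}")
    if method == "euclidean":
        mean = np.mean(comps, axis=0)
    elif method == "log-euclidean":
        from .dti import components_to_tensor, tensor_to_components
        logs = []
        for c in comps:
            w, v = np.linalg.eigh(components_to_tensor(c))
            w = np.log(np.maximum(w, 1e-12))
            logs.append(np.einsum("...ij,...j,...kj->...ik", v, w, v))
        w, v = np.linalg.eigh(np.mean(logs, axis=0))
        mean = tensor_to_components(
            np.einsum("...ij,...j,...kj->...ik", v, np.exp(w), v))
    else:
        raise ValueError(f"unknown averaging method: {method!r}")
    return GroupTensorAverage(mean, len(samples))


def fa_map(avg: GroupTensorAverage) -> np.ndarray:
    evals, _, _ = eigensystem(avg.components, clamp=True)
    return fa_from_eigenvalues(evals)


def fa_difference_map(
    injured: GroupTensorAverage, sham: GroupTensorAverage
) -> np.ndarray:
    """FA(mean injured tensor) − FA(mean sham tensor), per voxel."""
    if injured.shape != sham.shape:
        raise ValueError(f"grid mismatch: {injured.shape} vs {sham.shape}")
    return fa_map(injured) - fa_map(sham)


def render_overlay(
    diff: np.ndarray,
    background: np.ndarray,
    out_dir: str | Path,
    window: tuple[float, float] = (-0.2, 0.2),
    prefix: str = "fa_diff",
) -> list[Path]:
    """Signed colour overlay per axial slice: warm = positive, cool =
    negative, zero transparent, on a grayscale background.  Returns the
    written PNG paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = window
    if lo >= hi:
        raise ValueError(f"window must satisfy lo < hi, got {window}")
    diff = np.asarray(diff, float)
    background = np.asarray(background, float)
    if diff.shape != background.shape:
        raise ValueError("diff and background grids differ")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    masked = np.ma.masked_where(diff == 0, diff)
    for z in range(diff.shape[2]):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(background[:, :, z].T, cmap="gray", origin="lower")
        im = ax.imshow(masked[:, :, z].T, cmap="coolwarm", vmin=lo, vmax=hi,
                       origin="lower")
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_axis_off()
        path = out_dir / f"{prefix}_z{z:03d}.png"
        fig.savefig(path, dpi=100, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
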