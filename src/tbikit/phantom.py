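"""Synthetic labeled tensor phantoms and noisy DWI volumes.

The phantom stands in for a registered cohort of ex vivo mouse brains: a
3D grid carrying 19 labeled regions (bilateral white-matter tracts, grey
matter regions, and midline callosal/commissural structures), each with a
tissue-class baseline diffusion tensor.  Injury is modelled as
multiplicative perturbation of the baseline eigenvalues inside designated
regions (e.g. lower l1 and higher l2, l3 to reduce FA, as seen in
traumatic axonal injury).  The geometry is deliberately simple — each
region is a rectangular block spanning five slices — because only the
labels and tensor values, not anatomy, enter the downstream statistics.

Noisy signals follow the magnitude-MRI (Rician) model:

    S~ = sqrt((S + e1)^2 + e2^2),   e1, e2 ~ N(0, sigma^2),  sigma = S0/snr.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ROI_NAMES
from .dti import components_to_tensor, tensor_to_components
from .scheme import AcquisitionScheme

__all__ = [
    "TensorField",
    "PhantomSpec",
    "build_tensor_phantom",
    "synthesize_dwi",
    "make_histo_image",
    "WHITE_MATTER_ROIS",
    "GRAY_MATTER_ROIS",
    "default_injury_effects",
]

#: Coherent, strongly anisotropic fibre regions.
WHITE_MATTER_ROIS: tuple[str, ...] = tuple(
    r for r in ROI_NAMES
    if any(k in r for k in ("Brachium", "Cingulum", "Corpus Callosum",
                            "Capsule", "Optic Tract", "Commissure"))
)
#: Nearly isotropic regions.
GRAY_MATTER_ROIS: tuple[str, ...] = tuple(
    r for r in ROI_NAMES if r not in WHITE_MATTER_ROIS
)

# Fixed-tissue baselines (mm^2/s): ex vivo diffusivities are well below
# in vivo values; both classes have trace ~1.0e-3.
_WM_EVALS = (0.70e-3, 0.15e-3, 0.15e-3)   # prolate, FA ~ 0.75
_GM_EVALS = (0.36e-3, 0.33e-3, 0.31e-3)   # near-isotropic, FA ~ 0.06

_ROI_BLOCK = (4, 4)   # in-plane voxels per region
_ROI_SLICES = 5       # through-plane extent, matching a 500 um ROI at 100 um
_GAP = 1


class PhantomConfigError(ValueError):
    """Raised for unknown ROI names or invalid phantom parameters."""


@dataclass
class TensorField:
    """Per-voxel symmetric tensors with a named label volume.

    ``components`` has shape grid + (6,) ordered (Dxx, Dyy, Dzz, Dxy,
    Dxz, Dyz); ``labels`` is an integer volume, 0 = background;
    ``roi_labels`` maps region name -> label value.
    """

    components: np.ndarray
    labels: np.ndarray
    roi_labels: dict[str, int]
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.components.shape[:-1] != self.labels.shape:
            raise PhantomConfigError("components grid does not match labels grid")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def tensors(self) -> np.ndarray:
        return components_to_tensor(self.components)

    def roi_mask(self, roi: str) -> np.ndarray:
        if roi not in self.roi_labels:
            raise PhantomConfigError(f"unknown ROI name: {roi!r}")
        return self.labels == self.roi_labels[roi]


@dataclass
class PhantomSpec:
    """Everything needed to build a labeled tensor phantom.

    ``injury_effects`` maps (roi_name, eigenvalue_index) -> multiplicative
    factor applied to that eigenvalue in the injured group;
    eigenvalue_index 0 is the largest.  ``snr`` is the b=0
    signal-to-noise ratio used when synthesising DWIs from the phantom
    (np.inf = noise-free).
    """

    grid_shape: tuple[int, int, int] = (26, 22, 9)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    roi_labels: dict[str, int] = field(
        default_factory=lambda: {r: i + 1 for i, r in enumerate(ROI_NAMES)}
    )
    wm_eigenvalues: tuple[float, float, float] = _WM_EVALS
    gm_eigenvalues: tuple[float, float, float] = _GM_EVALS
    injury_effects: dict[tuple[str, int], float] = field(default_factory=dict)
    snr: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(ROI_NAMES) - set(self.roi_labels)
        if missing:
            raise PhantomConfigError(f"roi_labels missing regions: {sorted(missing)}")
        for ev in (*self.wm_eigenvalues, *self.gm_eigenvalues):
            if ev <= 0:
                raise PhantomConfigError("baseline eigenvalues must be positive")
        for (roi, idx), factor in self.injury_effects.items():
            if roi not in self.roi_labels:
                raise PhantomConfigError(f"injury effect on unknown ROI: {roi!r}")
            if not 0 <= idx <= 2:
                raise PhantomConfigError(f"eigenvalue index out of range: {idx}")
            if factor <= 0:
                raise PhantomConfigError("injury factors must be positive")
        if self.snr <= 0:
            raise PhantomConfigError("snr must be positive (np.inf = noise-free)")


def default_injury_effects() -> dict[tuple[str, int], float]:
    """FA-reducing eigenvalue perturbations in the tracts that carry the
    injury in this model: lower axial, higher radial diffusivity."""
    effects: dict[tuple[str, int], float] = {}
    for roi in ("Optic Tract_Left", "Optic Tract_Right",
                "Brachium_Left", "Brachium_Right"):
        effects[(roi, 0)] = 0.80
        effects[(roi, 1)] = 1.25
        effects[(roi, 2)] = 1.25
    return effects


def _block_origin(k: int) -> tuple[int, int]:
    """In-plane origin of the k-th region block (5 columns x 4 rows)."""
    col, row = k % 5, k // 5
    return (_GAP + col * (_ROI_BLOCK[0] + _GAP), _GAP + row * (_ROI_BLOCK[1] + _GAP))


def _tensor_from_eigenvalues(evals: np.ndarray, principal: np.ndarray) -> np.ndarray:
    """Symmetric tensor with the given eigenvalues; e1 = ``principal``,
    remaining axes completed orthonormally."""
    e1 = principal / np.linalg.norm(principal)
    helper = np.array([0.0, 1.0, 0.0]) if abs(e1[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return R @ np.diag(evals) @ R.T


def build_tensor_phantom(spec: PhantomSpec, group: str = "sham") -> TensorField:
    """Build the labeled tensor field for one group.

    Sham voxels take the tissue-class baseline tensor (white-matter
    regions: prolate with principal axis along x; grey matter: near
    isotropic).  For ``group="injured"`` the eigenvalues inside each ROI
    named in ``spec.injury_effects`` are multiplied by the configured
    factors before the tensor is reassembled.
    """
    if group not in ("sham", "injured"):
        raise PhantomConfigError(f"group must be 'sham' or 'injured', got {group!r}")
    nx, ny, nz = spec.grid_shape
    z0 = max(0, (nz - _ROI_SLICES) // 2)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    comps = np.zeros(spec.grid_shape + (6,), dtype=float)

    x_axis = np.array([1.0, 0.0, 0.0])
    for k, roi in enumerate(ROI_NAMES):
        ox, oy = _block_origin(k)
        if ox + _ROI_BLOCK[0] > nx or oy + _ROI_BLOCK[1] > ny:
            raise PhantomConfigError(
                f"grid {spec.grid_shape} too small for the 19-region layout"
            )
        evals = np.array(
            spec.wm_eigenvalues if roi in WHITE_MATTER_ROIS else spec.gm_eigenvalues
        )
        if group == "injured":
            for idx in range(3):
                factor = spec.injury_effects.get((roi, idx))
                if factor is not None:
                    evals[idx] *= factor
        # keep the descending order contract even under extreme factors
        order = np.argsort(evals)[::-1]
        D = _tensor_from_eigenvalues(evals[order], x_axis)
        sl = (slice(ox, ox + _ROI_BLOCK[0]), slice(oy, oy + _ROI_BLOCK[1]),
              slice(z0, z0 + _ROI_SLICES))
        labels[sl] = spec.roi_labels[roi]
        comps[sl] = tensor_to_components(D)

    return TensorField(comps, labels, dict(spec.roi_labels), spec.voxel_size)


def synthesize_dwi(
    tensors: TensorField | np.ndarray,
    scheme: AcquisitionScheme,
    s0: float = 1000.0,
    snr: float = np.inf,
    seed: int | None = 0,
) -> np.ndarray:
    """Forward-simulate DWI amplitudes from a tensor field.

    Noise-free signal per volume i: S_i = s0 * exp(-b_i g_i^T D g_i);
    background voxels (zero tensor, zero label) give S = 0 in every
    volume.  Finite ``snr`` adds Rician corruption with channel sigma =
    s0 / snr, reproducible under ``seed``.

    Returns grid + (n_volumes,) amplitudes (all >= 0).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if snr <= 0:
        raise ValueError("snr must be positive (np.inf = noise-free)")
    if isinstance(tensors, TensorField):
        comps = tensors.components
        foreground = tensors.labels > 0
    else:
        comps = np.asarray(tensors, dtype=float)
        foreground = np.any(comps != 0, axis=-1)
    lead = comps.shape[:-1]
    b = scheme.b_values
    g = scheme.directions
    # g^T D g expanded over the 6 unique components
    gq = np.column_stack([g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                          2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
                          2 * g[:, 1] * g[:, 2]])
    adc = comps.reshape(-1, 6) @ gq.T                       # (V, n)
    S = s0 * np.exp(-b[None, :] * adc)
    S[~foreground.reshape(-1)] = 0.0
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        e1 = rng.normal(0.0, sigma, S.shape)
        e2 = rng.normal(0.0, sigma, S.shape)
        S = np.sqrt((S + e1) ** 2 + e2 ** 2)
    return S.reshape(lead + (b.size,))


def make_histo_image(
    true_fraction: float,
    shape: tuple[int, int] = (256, 256),
    seed: int | None = 0,
    threshold_midpoint: int = 128,
) -> np.ndarray:
    """Synthetic 8-bit photomicrograph with an exact stained-area fraction.

    Exactly ``round(true_fraction * N)`` pixels receive intensities below
    ``threshold_midpoint`` (stained-is-dark, as for a brown DAB
    chromogen on a bright-field background); the rest lie at or above it.
    Stained pixels form spatially clustered blobs: pixels are ranked by a
    smoothed random field and the darkest ranks are assigned to the stain.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError(f"true_fraction must be in [0, 1], got {true_fraction}")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    k = int(round(true_fraction * n))
    field = gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 32 + 1)
    order = np.argsort(field, axis=None, kind="stable")
    img = np.empty(n, dtype=np.uint8)
    lo = threshold_midpoint
    # stained intensities in [lo//4, lo-1], background in [lo+32, 255]
    img[order[:k]] = rng.integers(lo // 4, lo, size=k)
    img[order[k:]] = rng.integers(min(lo + 32, 255), 256, size=n - k)
    return img.reshape(shape)
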