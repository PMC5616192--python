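"""Diffusion tensor estimation and scalar metric maps.

The signal model is the single-tensor Stejskal–Tanner equation

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with D a symmetric positive 3x3 tensor (mm^2/s).  Estimation proceeds in
two stages, mirroring common practice: a weighted log-linear least-squares
initialiser followed by unweighted nonlinear least squares on the signal
amplitudes (Gauss–Newton with step halving).

The scalar metrics derived from the sorted eigenvalues l1 >= l2 >= l3:

    T  = l1 + l2 + l3                    (trace)
    AD = l1                              (axial diffusivity)
    RD = (l2 + l3) / 2                   (radial diffusivity)
    FA = sqrt(1/2) * sqrt((l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2)
                   / sqrt(l1^2 + l2^2 + l3^2)

plus the Westin shape measures separating prolate from oblate diffusion.
Two normalisations of the Westin measures circulate; both are offered:

    trace convention:    WL = (l1 - l2) / T,   WP = 2 (l2 - l3) / T
                         (then WL + WP + WS = 1 with WS = 3 l3 / T)
    lambda1 convention:  WL = (l1 - l2) / l1,  WP = (l2 - l3) / l1

The trace-normalised form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheme import AcquisitionScheme

__all__ = [
    "tensor_to_components",
    "components_to_tensor",
    "fit_tensor_loglinear",
    "fit_tensor_nonlinear",
    "eigensystem",
    "compute_metrics",
    "fa_from_eigenvalues",
    "westin_from_eigenvalues",
    "TensorModel",
    "TensorFitResult",
    "metric_maps",
    "METRIC_NAMES",
]

METRIC_NAMES = ("FA", "T", "AD", "RD", "WL", "WP")

#: (voxel, 6) component order used throughout: Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
_IJ = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]

_SIGNAL_FLOOR_FRACTION = 1e-6  # log-linear stage floors S at this * S0 proxy
_EIG_CLAMP = 1e-12


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the acquisition cannot determine all tensor components."""


def tensor_to_components(D: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensors -> (..., 6) unique components."""
    D = np.asarray(D, dtype=float)
    return np.stack([D[..., i, j] for i, j in _IJ], axis=-1)


def components_to_tensor(c: np.ndarray) -> np.ndarray:
    """(..., 6) components -> (..., 3, 3) symmetric tensors."""
    c = np.asarray(c, dtype=float)
    D = np.empty(c.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(_IJ):
        D[..., i, j] = c[..., k]
        D[..., j, i] = c[..., k]
    return D


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_design(X: np.ndarray) -> None:
    if X.shape[0] < 7 or np.linalg.matrix_rank(X) < 7:
        raise SingularFitError(
            "acquisition scheme cannot determine a tensor: need >= 7 volumes "
            "spanning >= 6 non-collinear directions plus b=0"
        )


def fit_tensor_loglinear(
    signals: np.ndarray, scheme: AcquisitionScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares on log(S).

    Solves log S = X beta with beta = (log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    and weights proportional to S^2 (the delta-method variance of log S
    under additive noise), vectorised over voxels.

    Parameters
    ----------
    signals : (..., n_volumes) array
    scheme : AcquisitionScheme

    Returns
    -------
    components : (..., 6) tensor components (mm^2/s)
    s0 : (...) estimated non-diffusion-weighted signal
    """
    X = scheme.design_matrix()
    _check_design(X)
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    lead = S.shape[:-1]
    S = S.reshape(-1, S.shape[-1])
    floor = _SIGNAL_FLOOR_FRACTION * np.maximum(S.max(axis=1, keepdims=True), 1e-300)
    S = np.maximum(S, floor)
    y = np.log(S)
    w = S  # sqrt-weights: WLS with weights S^2
    # per-voxel weighted normal equations
    Xw = w[:, :, None] * X[None, :, :]
    yw = w * y
    XtX = np.einsum("vki,vkj->vij", Xw, Xw)
    Xty = np.einsum("vki,vk->vi", Xw, yw)
    beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    s0 = np.exp(beta[:, 0])
    comps = beta[:, 1:]
    return comps.reshape(lead + (6,)), s0.reshape(lead)


def fit_tensor_nonlinear(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    init_components: np.ndarray,
    init_s0: np.ndarray,
    max_iter: int = 200,
    rtol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unweighted nonlinear least squares on signal amplitudes.

    Minimises sum_i (S_i - S0 exp(-b_i g_i^T D g_i))^2 per voxel by
    Gauss–Newton in beta = (log S0, D6) with step halving, vectorised over
    voxels.  Convergence: relative cost change < ``rtol``; voxels that
    exhaust ``max_iter`` are flagged, not raised.

    Returns
    -------
    components : (..., 6)
    s0 : (...)
    converged : (...) bool
    """
    X = scheme.design_matrix()
    _check_design(X)
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    lead = S.shape[:-1]
    S = S.reshape(-1, S.shape[-1])
    c0 = np.asarray(init_components, dtype=float).reshape(-1, 6)
    s0 = np.asarray(init_s0, dtype=float).reshape(-1)
    beta = np.concatenate([np.log(np.maximum(s0, 1e-300))[:, None], c0], axis=1)

    def cost(b):
        m = np.exp(b @ X.T)
        r = S - m
        return np.einsum("vk,vk->v", r, r), m, r

    c_prev, m, r = cost(beta)
    # voxels already at numerically-zero cost (relative to signal energy)
    # count as converged; the relative-change test is meaningless there
    cost_floor = 1e-24 * np.einsum("vk,vk->v", S, S)
    converged = c_prev <= cost_floor
    active = ~converged
    for _ in range(max_iter):
        if not active.any():
            break
        # Gauss-Newton step on active voxels: J = -m[:, :, None] * X
        mA, rA = m[active], r[active]
        J = mA[:, :, None] * X[None, :, :]
        JtJ = np.einsum("vki,vkj->vij", J, J)
        Jtr = np.einsum("vki,vk->vi", J, rA)
        JtJ += 1e-14 * np.eye(7) * np.trace(JtJ, axis1=1, axis2=2)[:, None, None]
        try:
            step = np.linalg.solve(JtJ, Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(a, b_, rcond=None)[0]
                             for a, b_ in zip(JtJ, Jtr)])
        idx = np.flatnonzero(active)
        new_beta = beta[idx] + step
        # step halving where the full step does not reduce the cost
        for _halve in range(25):
            m_new = np.exp(new_beta @ X.T)
            r_new = S[idx] - m_new
            c_new = np.einsum("vk,vk->v", r_new, r_new)
            worse = c_new > c_prev[idx]
            if not worse.any():
                break
            step[worse] *= 0.5
            new_beta[worse] = beta[idx[worse]] + step[worse]
        rel = np.abs(c_prev[idx] - c_new) / np.maximum(c_prev[idx], 1e-300)
        improved = c_new <= c_prev[idx]
        beta[idx[improved]] = new_beta[improved]
        c_prev[idx[improved]] = c_new[improved]
        m[idx[improved]] = m_new[improved]
        r[idx[improved]] = r_new[improved]
        done = idx[(rel < rtol) | ~improved | (c_new <= cost_floor[idx])]
        converged[done] = True
        active[done] = False
    comps = beta[:, 1:]
    s0_out = np.exp(beta[:, 0])
    return (comps.reshape(lead + (6,)), s0_out.reshape(lead),
            converged.reshape(lead))


# ---------------------------------------------------------------------------
# eigensystem and metrics
# ---------------------------------------------------------------------------

def eigensystem(
    D: np.ndarray, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Descending eigendecomposition of symmetric tensors.

    Parameters
    ----------
    D : (..., 3, 3) or (..., 6) symmetric tensors
    clamp : replace negative eigenvalues by 1e-12 and flag the voxel

    Returns
    -------
    evals : (..., 3) with l1 >= l2 >= l3
    evecs : (..., 3, 3), column k is the eigenvector of eigenvalue k
    clamped : (...) bool, True where clamping occurred
    """
    D = np.asarray(D, dtype=float)
    if D.shape[-1] == 6:
        D = components_to_tensor(D)
    w, v = np.linalg.eigh(D)  # ascending
    w = w[..., ::-1]
    v = v[..., ::-1]
    clamped = np.any(w < 0, axis=-1)
    if clamp:
        w = np.where(w < 0, _EIG_CLAMP, w)
    return w, v, clamped


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (..., 3) eigenvalues; 0 for all-zero."""
    l = np.asarray(evals, dtype=float)
    l1, l2, l3 = l[..., 0], l[..., 1], l[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num / np.where(den > 0, den, 1.0))
    return np.where(den > 0, fa, 0.0)


def westin_from_eigenvalues(
    evals: np.ndarray, convention: str = "trace"
) -> tuple[np.ndarray, np.ndarray]:
    """Westin linear (WL) and planar (WP) anisotropy.

    convention="trace":   WL = (l1-l2)/T,  WP = 2(l2-l3)/T
    convention="lambda1": WL = (l1-l2)/l1, WP = (l2-l3)/l1
    """
    l = np.asarray(evals, dtype=float)
    l1, l2, l3 = l[..., 0], l[..., 1], l[..., 2]
    if convention == "trace":
        den = l1 + l2 + l3
        wl_num, wp_num = l1 - l2, 2.0 * (l2 - l3)
    elif convention == "lambda1":
        den = l1
        wl_num, wp_num = l1 - l2, l2 - l3
    else:
        raise ValueError(f"unknown Westin convention: {convention!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.where(den > 0, den, 1.0)
        wl = np.where(den > 0, wl_num / safe, 0.0)
        wp = np.where(den > 0, wp_num / safe, 0.0)
    return wl, wp


def compute_metrics(
    evals: np.ndarray, westin_convention: str = "trace"
) -> dict[str, np.ndarray]:
    """The six scalar metrics from sorted eigenvalues.

    Returns a dict with keys FA, T, AD, RD, WL, WP plus "degenerate"
    (True where all eigenvalues are zero; metrics there are 0).
    """
    l = np.asarray(evals, dtype=float)
    if np.any(l[..., :-1] < l[..., 1:] - 1e-30):
        raise ValueError("eigenvalues must be sorted descending")
    l1, l2, l3 = l[..., 0], l[..., 1], l[..., 2]
    T = l1 + l2 + l3
    wl, wp = westin_from_eigenvalues(l, westin_convention)
    return {
        "FA": fa_from_eigenvalues(l),
        "T": T,
        "AD": l1,
        "RD": 0.5 * (l2 + l3),
        "WL": wl,
        "WP": wp,
        "degenerate": T <= 0,
    }


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass
class TensorModel:
    """Single diffusion tensor model for a set of DWI signals.

    Parameters
    ----------
    scheme : AcquisitionScheme
    signals : (..., n_volumes) measured amplitudes; any leading shape
        (a flat voxel list or a 3D volume grid).
    """

    scheme: AcquisitionScheme
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape[-1] != self.scheme.n_volumes:
            raise ValueError(
                f"signals last axis {self.signals.shape[-1]} != scheme "
                f"volume count {self.scheme.n_volumes}"
            )

    def fit(self, nonlinear: bool = True, mask: np.ndarray | None = None
            ) -> "TensorFitResult":
        """Log-linear WLS initialisation, optionally refined by nonlinear
        least squares; fitting restricted to ``mask`` when given."""
        lead = self.signals.shape[:-1]
        S = self.signals.reshape(-1, self.scheme.n_volumes)
        if mask is not None:
            flat_mask = np.asarray(mask, bool).reshape(-1)
        else:
            flat_mask = np.ones(S.shape[0], dtype=bool)
        comps = np.zeros((S.shape[0], 6))
        s0 = np.zeros(S.shape[0])
        converged = np.ones(S.shape[0], dtype=bool)
        if flat_mask.any():
            c, z = fit_tensor_loglinear(S[flat_mask], self.scheme)
            if nonlinear:
                c, z, conv = fit_tensor_nonlinear(S[flat_mask], self.scheme, c, z)
                converged[flat_mask] = conv
            comps[flat_mask] = c
            s0[flat_mask] = z
        return TensorFitResult(
            model=self,
            components=comps.reshape(lead + (6,)),
            s0=s0.reshape(lead),
            mask=flat_mask.reshape(lead),
            converged=converged.reshape(lead),
        )


@dataclass
class TensorFitResult:
    """Fitted tensors plus derived quantities."""

    model: TensorModel
    components: np.ndarray  # (..., 6)
    s0: np.ndarray
    mask: np.ndarray
    converged: np.ndarray
    _eig: tuple | None = field(default=None, repr=False)

    @property
    def tensors(self) -> np.ndarray:
        return components_to_tensor(self.components)

    def eigensystem(self, clamp: bool = True):
        if self._eig is None:
            self._eig = eigensystem(self.components, clamp=clamp)
        return self._eig

    def metrics(self, westin_convention: str = "trace") -> dict[str, np.ndarray]:
        evals, _, _ = self.eigensystem()
        out = compute_metrics(evals, westin_convention)
        for k in METRIC_NAMES:
            out[k] = np.where(self.mask, out[k], 0.0)
        return out

    def predicted_signals(self) -> np.ndarray:
        X = self.model.scheme.design_matrix()
        lead = self.components.shape[:-1]
        beta = np.concatenate(
            [np.log(np.maximum(self.s0.reshape(-1, 1), 1e-300)),
             self.components.reshape(-1, 6)], axis=1)
        return np.exp(beta @ X.T).reshape(lead + (X.shape[0],))

    def summary(self) -> str:
        n = int(self.mask.sum())
        evals, _, clamped = self.eigensystem()
        m = self.metrics()
        lines = [
            "Diffusion tensor fit",
            "====================",
            f"voxels fitted        : {n} of {self.mask.size}",
            f"converged            : {int(self.converged[self.mask].sum())} / {n}",
            f"eigenvalue-clamped   : {int(clamped[self.mask].sum())}",
        ]
        for k in METRIC_NAMES:
            vals = m[k][self.mask]
            if n:
                lines.append(f"mean {k:<4} over mask  : {vals.mean():.6g}")
        return "\n".join(lines)


def metric_maps(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    westin_convention: str = "trace",
    nonlinear: bool = True,
    mask_fraction: float = 0.05,
) -> dict[str, np.ndarray]:
    """Whole-volume pipeline: mask -> log-linear -> nonlinear -> metrics.

    ``dwi`` has shape grid + (n_volumes,).  Background voxels, identified
    by mean b=0 signal below ``mask_fraction`` of its maximum, are left
    zero in every output.  Returns the six metric maps plus "tensor"
    ((...,6) components), "S0", "mask" and "converged".
    """
    dwi = np.asarray(dwi, dtype=float)
    b0 = dwi[..., scheme.b_values == 0].mean(axis=-1)
    mask = b0 > mask_fraction * b0.max() if b0.max() > 0 else np.zeros_like(b0, bool)
    fit = TensorModel(scheme, dwi).fit(nonlinear=nonlinear, mask=mask)
    out = fit.metrics(westin_convention)
    out.pop("degenerate", None)
    out["tensor"] = np.where(mask[..., None], fit.components, 0.0)
    out["S0"] = np.where(mask, fit.s0, 0.0)
    out["mask"] = mask
    out["converged"] = fit.converged
    return out
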