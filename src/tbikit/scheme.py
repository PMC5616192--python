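"""Multi-shell diffusion acquisition schemes.

The default protocol mirrors a high-field ex vivo mouse acquisition: two
low-b shells (b = 250 and 500 s/mm^2) with a small number of directions and
two high-b shells (b = 1500 and 3000 s/mm^2) with a denser direction set,
plus at least one b=0 reference volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionScheme", "make_scheme", "sphere_directions"]

#: Default shell b-values, s/mm^2.
LOW_SHELL_BVALS = (250.0, 500.0)
HIGH_SHELL_BVALS = (1500.0, 3000.0)


class InvalidSchemeError(ValueError):
    """Raised when a direction/b-value layout cannot define a valid scheme."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    ``b_values[i]`` and ``directions[i]`` describe DWI volume *i*;
    ``n_b0`` counts the b=0 reference volumes (direction stored as +z
    by convention, never applied because b=0).
    """

    b_values: np.ndarray
    directions: np.ndarray
    n_b0: int = field(default=0)

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        g = np.asarray(self.directions, dtype=float)
        if b.ndim != 1 or g.shape != (b.size, 3):
            raise InvalidSchemeError(
                f"need matching b-values (n,) and directions (n, 3); "
                f"got {b.shape} and {g.shape}"
            )
        if np.any(b < 0):
            raise InvalidSchemeError("b-values must be non-negative")
        norms = np.linalg.norm(g, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise InvalidSchemeError("all gradient directions must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.b_values.size

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    def design_matrix(self) -> np.ndarray:
        """Design matrix X with rows [1, -b gx^2, -b gy^2, -b gz^2,
        -2b gx gy, -2b gx gz, -2b gy gz] so that log S = X @ [log S0, D6].

        The tensor component order is (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz).
        """
        b = self.b_values
        gx, gy, gz = self.directions.T
        X = np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -b * gy * gy,
                -b * gz * gz,
                -2.0 * b * gx * gy,
                -2.0 * b * gx * gz,
                -2.0 * b * gy * gz,
            ]
        )
        return X

    # -- I/O ------------------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.bval`` (one line), ``<prefix>.bvec`` (one
        direction per line) and ``<prefix>.json`` (combined)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        with open(prefix.with_suffix(".bval"), "w") as fh:
            fh.write(" ".join(f"{b:.6g}" for b in self.b_values) + "\n")
        with open(prefix.with_suffix(".bvec"), "w") as fh:
            for g in self.directions:
                fh.write(f"{g[0]:.17g} {g[1]:.17g} {g[2]:.17g}\n")
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "b_values": self.b_values.tolist(),
                    "directions": self.directions.tolist(),
                    "n_b0": self.n_b0,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, prefix: str | Path) -> "AcquisitionScheme":
        prefix = Path(prefix)
        jpath = prefix.with_suffix(".json")
        if jpath.exists():
            with open(jpath) as fh:
                d = json.load(fh)
            return cls(np.asarray(d["b_values"]), np.asarray(d["directions"]), d["n_b0"])
        try:
            b = np.loadtxt(prefix.with_suffix(".bval"), ndmin=1)
            g = np.loadtxt(prefix.with_suffix(".bvec"), ndmin=2)
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise InvalidSchemeError(f"cannot parse scheme files at {prefix}: {exc}") from exc
        n_b0 = int(np.sum(b == 0))
        return cls(b, g, n_b0)


def sphere_directions(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (spherical Fibonacci
    lattice).  Reproducible: no randomness involved."""
    if n < 1:
        raise InvalidSchemeError("need at least one direction")
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    g = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def make_scheme(
    low_shell_dirs: int = 6,
    high_shell_dirs: int = 32,
    n_b0: int = 1,
    low_bvals: tuple[float, float] = LOW_SHELL_BVALS,
    high_bvals: tuple[float, float] = HIGH_SHELL_BVALS,
) -> AcquisitionScheme:
    """Build the four-shell scheme: two low-b shells with
    ``low_shell_dirs`` directions each and two high-b shells with
    ``high_shell_dirs`` directions each, preceded by ``n_b0`` b=0 volumes.

    Raises
    ------
    InvalidSchemeError
        If either direction count is below 6 (a tensor has six unknowns)
        or ``n_b0 < 1``.
    """
    if low_shell_dirs < 6 or high_shell_dirs < 6:
        raise InvalidSchemeError("each shell needs at least 6 directions")
    if n_b0 < 1:
        raise InvalidSchemeError("need at least one b=0 volume")
    b_list = [np.zeros(n_b0)]
    g_list = [np.tile([0.0, 0.0, 1.0], (n_b0, 1))]
    for bval in low_bvals:
        b_list.append(np.full(low_shell_dirs, float(bval)))
        g_list.append(sphere_directions(low_shell_dirs))
    for bval in high_bvals:
        b_list.append(np.full(high_shell_dirs, float(bval)))
        g_list.append(sphere_directions(high_shell_dirs))
    return AcquisitionScheme(np.concatenate(b_list), np.vstack(g_list), n_b0=n_b0)
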