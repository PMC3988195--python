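"""Spatial proximity kernels over variant positions.

The K x K matrix C encodes how strongly two sites share association signal as
a function of their physical distance.  The compactly supported tri-weight
kernel c(d) = (1 - (d/d_max)^2)^3 for d < d_max (0 beyond) is the default;
an identity kernel discards spatial information entirely and recovers the
adaptive combination of P-values (ADA) test.

The kernel is not required to be positive semi-definite: the region statistic
is only used through permutation ranks, so indefiniteness is harmless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_D_MAX = 20_000.0  # bp


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric K x K proximity matrix with entries in [0, 1] and unit diagonal."""

    values: np.ndarray
    d_max: float
    measure: str  # "triweight" | "identity"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(v, v.T):
            raise ValueError("kernel must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("kernel diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("kernel entries must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    @property
    def is_identity(self) -> bool:
        return self.measure == "identity"


def pairwise_distances(positions) -> np.ndarray:
    """Absolute base-pair distance matrix D[i, j] = |pos_i - pos_j|."""
    pos = np.asarray(positions, dtype=np.float64)
    return np.abs(pos[:, None] - pos[None, :])


def triweight_kernel(D: np.ndarray, d_max: float = DEFAULT_D_MAX) -> KernelMatrix:
    """Tri-weight kernel c(d) = (1 - (d/d_max)^2)^3 on [0, d_max), 0 beyond.

    d_max is the user-specified maximum distance at which two sites can share
    signal (default 20 kb).  The closed form is continuous at the boundary:
    c(d_max) = 0.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    D = np.asarray(D, dtype=np.float64)
    r2 = (D / d_max) ** 2
    C = np.where(D < d_max, (1.0 - np.minimum(r2, 1.0)) ** 3, 0.0)
    np.fill_diagonal(C, 1.0)
    return KernelMatrix(C, d_max=float(d_max), measure="triweight")


def identity_kernel(K: int) -> KernelMatrix:
    """Identity kernel: no spatial information (the ADA special case)."""
    if K < 1:
        raise ValueError("need at least one site")
    return KernelMatrix(np.eye(K), d_max=0.0, measure="identity")
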