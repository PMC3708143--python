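"""Direct-component profiles and bivariate-normal ellipse summaries.

A cluster's *direct component* (DC) is a piecewise-Gaussian temporal
activation profile derived directly from its pooled (onset, offset)
statistics: it peaks at the mid-phase Z = (X + Y)/2, rises with width
sigma1 = (Z - X)/3 + sigma_X and falls with width sigma2 = (Y - Z)/3 +
sigma_Y, and nominally spans (X - 3 sigma_X, Y + 3 sigma_Y).  Unlike
factorization components, the DC is read off the cluster geometry rather
than fitted.

Each cluster's phase-plane scatter is modelled as a correlated bivariate
normal; its 1-SD summary is the ellipse

    u^2 + v^2 - 2 u v rho = 1 - rho^2,
    u = (x - X)/sigma_X,  v = (y - Y)/sigma_Y,

which touches the +/-1 SD rectangle exactly at (u, v) = (+/-1, +/-rho) and
(+/-rho, +/-1) (matching signs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import PooledStats
from .errors import DegenerateEllipseError, InvalidClusterError

#: evaluation grid used for DC output files
DC_GRID = np.linspace(-0.5, 1.5, 1000)


@dataclass(frozen=True)
class DirectComponent:
    """Piecewise-Gaussian activation profile of one cluster."""

    cluster_id: int
    z: float  # peak phase
    sigma1: float  # rising-side width
    sigma2: float  # falling-side width
    support: tuple[float, float]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InvalidClusterError("DC widths must be positive")
        if not self.support[0] <= self.z <= self.support[1]:
            raise InvalidClusterError("DC peak outside its support")
        if self.amplitude < 0:
            raise InvalidClusterError("DC amplitude must be non-negative")


def derive_direct_component(pooled: PooledStats, cluster_id: int = 0,
                            amplitude: float = 1.0) -> DirectComponent:
    """Build the DC of a cluster from its pooled phase statistics."""
    if pooled.y <= pooled.x:
        raise InvalidClusterError(
            f"cluster {cluster_id}: mean offset {pooled.y} <= mean onset {pooled.x}"
        )
    z = 0.5 * (pooled.x + pooled.y)
    sigma1 = (z - pooled.x) / 3.0 + pooled.sx
    sigma2 = (pooled.y - z) / 3.0 + pooled.sy
    support = (pooled.x - 3.0 * pooled.sx, pooled.y + 3.0 * pooled.sy)
    return DirectComponent(cluster_id=cluster_id, z=z, sigma1=sigma1,
                           sigma2=sigma2, support=support, amplitude=amplitude)


def evaluate_dc(dc: DirectComponent, t, mode: str = "squared"):
    """Activation of a DC at phase(s) ``t``.

    ``mode="squared"`` (default) uses exp(-(t-Z)^2 / (2 sigma^2)), a proper
    Gaussian in phase units; ``mode="literal"`` uses exp(-(t-Z)^2 / (2 sigma))
    for comparison.  The profile is continuous, equals ``amplitude`` at Z,
    and its Gaussian tails are not truncated at the nominal support.
    """
    t_arr = np.asarray(t, dtype=float)
    if mode == "squared":
        den1, den2 = 2.0 * dc.sigma1**2, 2.0 * dc.sigma2**2
    elif mode == "literal":
        den1, den2 = 2.0 * dc.sigma1, 2.0 * dc.sigma2
    else:
        raise ValueError(f"unknown DC exponent mode: {mode!r}")
    d2 = (t_arr - dc.z) ** 2
    out = dc.amplitude * np.where(
        t_arr < dc.z, np.exp(-d2 / den1), np.exp(-d2 / den2)
    )
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class ClusterEllipse:
    """1-SD correlated bivariate-normal ellipse of a cluster."""

    center: tuple[float, float]
    axes_sd: tuple[float, float]
    rho: float

    def __post_init__(self) -> None:
        if abs(self.rho) >= 1.0:
            raise DegenerateEllipseError(f"|rho| = {abs(self.rho)} >= 1")
        if self.axes_sd[0] <= 0 or self.axes_sd[1] <= 0:
            raise DegenerateEllipseError("ellipse SDs must be positive")

    @classmethod
    def from_pooled(cls, pooled: PooledStats) -> "ClusterEllipse":
        return cls(center=(pooled.x, pooled.y), axes_sd=(pooled.sx, pooled.sy),
                   rho=pooled.rho)

    def residual(self, x, y):
        """|u^2 + v^2 - 2 u v rho - (1 - rho^2)| at the given point(s)."""
        u = (np.asarray(x, dtype=float) - self.center[0]) / self.axes_sd[0]
        v = (np.asarray(y, dtype=float) - self.center[1]) / self.axes_sd[1]
        return np.abs(u**2 + v**2 - 2 * u * v * self.rho - (1 - self.rho**2))

    @property
    def area(self) -> float:
        """pi * sigma_X * sigma_Y * sqrt(1 - rho^2)."""
        return float(np.pi * self.axes_sd[0] * self.axes_sd[1]
                     * np.sqrt(1 - self.rho**2))


def ellipse_points(e: ClusterEllipse, m: int = 100) -> np.ndarray:
    """``m`` boundary points of the ellipse, uniform in parameter angle.

    In normalized (u, v) coordinates the boundary is the level set
    Q(u, v) = (1 - rho^2) of the quadratic form Q with matrix
    [[1, -rho], [-rho, 1]]; points are Q^{-1/2} applied to a circle of
    radius sqrt(1 - rho^2), then mapped back through the SDs and center.
    """
    if m < 8:
        raise ValueError("need at least 8 boundary samples")
    rho = e.rho
    A = np.array([[1.0, -rho], [-rho, 1.0]])
    w, V = np.linalg.eigh(A)
    inv_sqrt = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
    theta = np.linspace(0.0, 2.0 * np.pi, m, endpoint=False)
    circle = np.sqrt(1.0 - rho**2) * np.stack([np.cos(theta), np.sin(theta)])
    uv = inv_sqrt @ circle
    x = e.center[0] + e.axes_sd[0] * uv[0]
    y = e.center[1] + e.axes_sd[1] * uv[1]
    return np.column_stack([x, y])


def ellipse_tangency(e: ClusterEllipse) -> np.ndarray:
    """The four points where the ellipse touches its +/-1 SD rectangle.

    In (u, v) these are (1, rho), (-1, -rho), (rho, 1), (-rho, -1); the
    first pair lies on the vertical rectangle edges, the second on the
    horizontal ones.
    """
    rho = e.rho
    uv = np.array([(1.0, rho), (-1.0, -rho), (rho, 1.0), (-rho, -1.0)])
    x = e.center[0] + e.axes_sd[0] * uv[:, 0]
    y = e.center[1] + e.axes_sd[1] * uv[:, 1]
    return np.column_stack([x, y])
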