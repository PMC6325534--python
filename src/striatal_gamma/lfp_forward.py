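"""Reconstruct multichannel model LFPs from per-neuron currents.

Each neuron's contribution to an electrode is its synaptic current weighted
by a spatial Gaussian kernel of the distance (SD ~300 um, zero beyond 1.5 mm)
and by an orientation affinity: the single-unit field is a unit vector in 3D,
and the affinity is the difference between the electrode distances of the
vector's origin and tip (+1 when pointing straight at a distant electrode, 0
when perpendicular). Three composites are supported: all fields pointing
toward the electrode (affinity 1), all sharing one random direction, or
per-neuron random directions. Reconstructed LFPs reuse the analysis-side
TimeSeries container so the full event/PAC/spectral pipeline runs unchanged
on model output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fsi_network import MESH_SPACING_UM, SimulationResult
from .signal_core import TimeSeries

__all__ = [
    "ElectrodeGrid",
    "OrientationField",
    "spatial_kernel",
    "orientation_affinity",
    "reconstruct",
]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Recording points (um) with kernel SD and cutoff."""

    positions: np.ndarray  # n_electrodes x 3, um
    sigma: float = 300.0  # um (~2.65 mesh units)
    cutoff: float = 1500.0  # um (13 mesh units at full scale)

    def __post_init__(self):
        if self.sigma <= 0 or self.cutoff <= self.sigma:
            raise ValueError("need sigma > 0 and cutoff > sigma")
        object.__setattr__(
            self, "positions", np.atleast_2d(np.asarray(self.positions, float))
        )

    @classmethod
    def default_array(cls, spacing_um: float = 750.0, side: int = 4, origin: float = 0.0):
        """The standard 4x4x4 array of 64 electrodes spaced ~750 um."""
        g = np.arange(side) * spacing_um + origin
        pos = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
        return cls(pos)

    @classmethod
    def centered(cls, n_side: int, n_electrodes: int = 1, spacing_um: float = 750.0):
        """A small electrode set centered in an ``n_side`` mesh (reduced-scale
        simulations)."""
        c = (n_side - 1) / 2.0 * MESH_SPACING_UM
        if n_electrodes == 1:
            pos = np.array([[c, c, c]])
        else:
            side = int(np.ceil(n_electrodes ** (1 / 3)))
            g = (np.arange(side) - (side - 1) / 2) * spacing_um + c
            pos = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
            pos = pos[:n_electrodes]
        return cls(pos)


@dataclass(frozen=True)
class OrientationField:
    """Per-neuron field orientation.

    Modes: ``toward_electrode`` (affinity fixed at 1), ``uniform_direction``
    (one shared random direction), ``random`` (per-neuron zenith in [0, pi)
    and azimuth in [0, 2*pi), each uniform — as printed, this is uniform in
    the angles, not uniform on the sphere; ``sphere_uniform=True`` switches
    to area-uniform sampling).
    """

    mode: str = "toward_electrode"
    seed: int = 0
    sphere_uniform: bool = False

    def __post_init__(self):
        if self.mode not in ("toward_electrode", "uniform_direction", "random"):
            raise ValueError(f"unknown orientation mode {self.mode!r}")

    @classmethod
    def toward_electrode(cls):
        return cls("toward_electrode")

    def draw_angles(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(self.seed)
        size = 1 if self.mode == "uniform_direction" else n
        if self.sphere_uniform:
            zen = np.arccos(rng.uniform(-1, 1, size))
        else:
            zen = rng.uniform(0, np.pi, size)
        azi = rng.uniform(0, 2 * np.pi, size)
        if self.mode == "uniform_direction":
            zen = np.full(n, zen[0])
            azi = np.full(n, azi[0])
        return zen, azi


def spatial_kernel(
    electrode: np.ndarray,
    neuron: np.ndarray,
    sigma: float = 300.0,
    cutoff: float = 1500.0,
) -> float | np.ndarray:
    """Gaussian distance kernel (1/(sqrt(2*pi)*sigma)) * exp(-d^2/(2 sigma^2)),
    zero beyond the cutoff.

    The 1D Gaussian prefactor is applied to the 3D kernel as printed in the
    source formulation.
    """
    d2 = np.sum((np.asarray(neuron, float) - np.asarray(electrode, float)) ** 2, axis=-1)
    w = np.exp(-d2 / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
    return np.where(d2 > cutoff**2, 0.0, w)


def _unit_vectors(zenith: np.ndarray, azimuth: np.ndarray) -> np.ndarray:
    """Spherical unit vector with zenith rho and azimuth phi:
    (sin(rho)cos(phi), sin(rho)sin(phi), cos(rho))."""
    return np.stack(
        [
            np.sin(zenith) * np.cos(azimuth),
            np.sin(zenith) * np.sin(azimuth),
            np.cos(zenith),
        ],
        axis=-1,
    )


def orientation_affinity(
    neuron: np.ndarray,
    zenith: float | np.ndarray,
    azimuth: float | np.ndarray,
    electrode: np.ndarray,
) -> float | np.ndarray:
    """Affinity = d_origin - d_tip of the unit field vector; in [-1, 1].

    Approaches +1 when the field points straight at a distant electrode and 0
    when perpendicular. If a neuron coincides with the electrode, the origin
    distance is 0 and the affinity is -d_tip.
    """
    neuron = np.asarray(neuron, float)
    electrode = np.asarray(electrode, float)
    d_o = np.sqrt(np.sum((neuron - electrode) ** 2, axis=-1))
    tip = neuron + _unit_vectors(np.asarray(zenith), np.asarray(azimuth))
    d_s = np.sqrt(np.sum((tip - electrode) ** 2, axis=-1))
    return d_o - d_s


def reconstruct(
    result: SimulationResult,
    grid: ElectrodeGrid,
    orientation: OrientationField,
    positions: np.ndarray | None = None,
) -> list[TimeSeries]:
    """Multichannel LFP: V(e, t) = sum_n xi_n * K(e, n) * I_n(t).

    ``positions`` defaults to the cubic mesh implied by the number of neurons
    in ``result``. Returns one TimeSeries per electrode.
    """
    n = result.syn_currents.shape[0]
    if positions is None:
        n_side = int(round(n ** (1 / 3)))
        if n_side**3 != n:
            raise ValueError("cannot infer mesh positions; pass them explicitly")
        g = np.arange(n_side) * MESH_SPACING_UM
        positions = np.array(np.meshgrid(g, g, g, indexing="ij")).reshape(3, -1).T
    if positions.shape[0] != n:
        raise ValueError("positions do not match the current traces")

    if orientation.mode == "toward_electrode":
        xi = None
    else:
        zen, azi = orientation.draw_angles(n)

    out = []
    # orientation affinity is computed in mesh units so |xi| <= 1 corresponds
    # to moving the unit tip by one lattice spacing
    for e in grid.positions:
        w = np.asarray(spatial_kernel(e, positions, grid.sigma, grid.cutoff))
        if orientation.mode != "toward_electrode":
            xi = orientation_affinity(
                positions / MESH_SPACING_UM,
                zen,
                azi,
                e / MESH_SPACING_UM,
            )
            w = w * xi
        sig = w.astype(np.float32) @ result.syn_currents
        out.append(TimeSeries(np.asarray(sig, float), result.current_rate))
    return out
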