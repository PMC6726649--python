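"""Extracellular cytokine transport: 2-D diffusion on a circular domain.

Each secreted cytokine obeys

    dphi/dt = D (phi_xx + phi_yy) + f(phi, r, t)

with a zero-Dirichlet (absorbing) boundary on a circle of radius 4
length-units and point/footprint sources from the secreting cells.  One
length-unit corresponds to 100 um, so the literature diffusion coefficient
1800 um^2/min becomes D = 0.18 units^2/min.  The solver is an explicit
5-point finite-difference scheme with substeps guarded by the stability
bound dt_sub <= 0.9 h^2 / (4D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LENGTH_UNIT_UM",
    "D_DEFAULT",
    "Field",
    "DiffusionParams",
    "SourceMap",
    "rasterize_sources",
    "step_field",
    "sample_field",
    "FieldBlowupError",
]

LENGTH_UNIT_UM = 100.0
#: 1800 um^2/min expressed in (100 um)^2/min
D_DEFAULT = 1800.0 / LENGTH_UNIT_UM**2


class FieldBlowupError(RuntimeError):
    """Raised when the field develops non-finite values."""


@dataclass
class Field:
    """A concentration field on a regular grid over [-L, L]^2.

    ``values[i, j]`` is the concentration at (x[i], y[j]); values vanish on
    and outside the boundary circle of radius ``radius``.
    """

    radius: float
    coords: np.ndarray
    values: np.ndarray
    mask: np.ndarray

    @property
    def spacing(self) -> float:
        return float(self.coords[1] - self.coords[0])

    @classmethod
    def create(cls, radius: float = 4.0, n: int = 81) -> "Field":
        coords = np.linspace(-radius, radius, n)
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        mask = xx**2 + yy**2 < radius**2
        return cls(radius=radius, coords=coords, values=np.zeros((n, n)), mask=mask)

    def copy(self) -> "Field":
        return Field(self.radius, self.coords, self.values.copy(), self.mask)

    def total_mass(self) -> float:
        return float(self.values.sum() * self.spacing**2)


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion coefficient (units^2/min), macro step and stability margin."""

    D: float = D_DEFAULT
    dt: float = 0.1
    safety: float = 0.9

    def __post_init__(self) -> None:
        if self.D < 0 or self.dt <= 0 or not (0 < self.safety <= 1):
            raise ValueError("require D >= 0, dt > 0 and safety in (0, 1]")


@dataclass
class SourceMap:
    """Cytokine depositions: (position, rate) with rate in conc*area/time."""

    entries: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def add(self, position, rate: float) -> None:
        if rate < 0:
            raise ValueError("source rates must be nonnegative")
        self.entries.append((np.asarray(position, dtype=float), float(rate)))


def rasterize_sources(
    sources: SourceMap | None,
    fld: Field,
    mode: str = "nearest",
    width: float = 0.25,
) -> np.ndarray:
    """Convert point sources to a rate-density raster (conc/time per cell).

    ``nearest`` deposits the full rate into the closest cell; ``footprint``
    spreads it over a truncated Gaussian of standard deviation ``width``
    (the cell-body scale), normalized to conserve the deposited amount.
    """
    h = fld.spacing
    dens = np.zeros_like(fld.values)
    if sources is None:
        return dens
    n = fld.coords.size
    for pos, rate in sources.entries:
        if rate == 0.0:
            continue
        if mode == "nearest":
            i = int(np.clip(np.rint((pos[0] + fld.radius) / h), 0, n - 1))
            j = int(np.clip(np.rint((pos[1] + fld.radius) / h), 0, n - 1))
            dens[i, j] += rate / h**2
        elif mode == "footprint":
            half = max(1, int(np.ceil(3 * width / h)))
            i0 = int(np.clip(np.rint((pos[0] + fld.radius) / h), 0, n - 1))
            j0 = int(np.clip(np.rint((pos[1] + fld.radius) / h), 0, n - 1))
            isl = slice(max(0, i0 - half), min(n, i0 + half + 1))
            jsl = slice(max(0, j0 - half), min(n, j0 + half + 1))
            gx = fld.coords[isl] - pos[0]
            gy = fld.coords[jsl] - pos[1]
            w = np.exp(-(gx[:, None] ** 2 + gy[None, :] ** 2) / (2 * width**2))
            total = w.sum()
            if total > 0:
                dens[isl, jsl] += rate * w / (total * h**2)
        else:
            raise ValueError(f"unknown deposition mode {mode!r}")
    return dens


def _laplacian(v: np.ndarray, h: float) -> np.ndarray:
    lap = np.zeros_like(v)
    lap[1:-1, 1:-1] = (
        v[2:, 1:-1] + v[:-2, 1:-1] + v[1:-1, 2:] + v[1:-1, :-2] - 4.0 * v[1:-1, 1:-1]
    ) / h**2
    return lap


def step_field(
    fld: Field,
    sources: SourceMap | np.ndarray | None = None,
    params: DiffusionParams | None = None,
    mode: str = "nearest",
    width: float = 0.25,
) -> Field:
    """Advance the field one macro step ``dt``.

    The source term acts continuously during the diffusion substeps.
    ``sources`` may be a :class:`SourceMap` or a precomputed rate-density
    raster.  The Dirichlet boundary is re-imposed after every substep.
    """
    params = params or DiffusionParams()
    h = fld.spacing
    if isinstance(sources, np.ndarray):
        dens = sources
    else:
        dens = rasterize_sources(sources, fld, mode=mode, width=width)
    if params.D > 0:
        dt_max = params.safety * h**2 / (4.0 * params.D)
        n_sub = max(1, int(np.ceil(params.dt / dt_max)))
    else:
        n_sub = 1
    dt_sub = params.dt / n_sub
    out = fld.copy()
    v = out.values
    for _ in range(n_sub):
        v += dt_sub * (params.D * _laplacian(v, h) + dens)
        v[~fld.mask] = 0.0
    if not np.all(np.isfinite(v)):
        raise FieldBlowupError(
            f"non-finite field values after step (dt={params.dt}, D={params.D}, h={h})"
        )
    return out


def sample_field(fld: Field, position) -> float:
    """Bilinear interpolation of the field at a point inside the domain."""
    x, y = np.asarray(position, dtype=float)
    if x * x + y * y >= fld.radius**2:
        raise ValueError(f"position {position!r} is outside the domain")
    h = fld.spacing
    n = fld.coords.size
    fx = (x + fld.radius) / h
    fy = (y + fld.radius) / h
    i = int(np.clip(np.floor(fx), 0, n - 2))
    j = int(np.clip(np.floor(fy), 0, n - 2))
    tx = fx - i
    ty = fy - j
    v = fld.values
    return float(
        v[i, j] * (1 - tx) * (1 - ty)
        + v[i + 1, j] * tx * (1 - ty)
        + v[i, j + 1] * (1 - tx) * ty
        + v[i + 1, j + 1] * tx * ty
    )
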