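"""Materials and interaction physics: cross sections, stopping powers, sampling.

Photon mass interaction coefficients (photoelectric, incoherent/Compton,
coherent/Rayleigh, pair production) and electron collision stopping powers
are read from the embedded per-element fixtures in ``gridmc/data`` and
combined with the mixture rule (mass-weighted sum of elemental
coefficients).  Lookups are log–log interpolated on the table grid and
never extrapolated.

The built-in registry covers the five media of the simulated treatment
head and phantom: water, air, PMMA (the accessory tray), brass and
cerrobend (the two grid-block alloys).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .physics_tables import (
    ELECTRON_REST_MEV,
    PAIR_THRESHOLD_MEV,
    klein_nishina_mean_scatter_fraction,
)

PROCESSES = ("photoelectric", "incoherent", "coherent", "pair")

_WEIGHT_FRACTION_TOL = 1e-9


class UnknownElementError(KeyError):
    pass


@dataclass(frozen=True)
class ElementData:
    """Per-element physics tables on the embedded energy grids."""

    symbol: str
    atomic_number: int
    atomic_mass: float  # g/mol
    energy_grid: np.ndarray  # MeV, ascending, photons
    cross_sections: dict[str, np.ndarray]  # process -> cm^2/g
    electron_energy_grid: np.ndarray  # MeV, ascending
    stopping_power: np.ndarray  # MeV cm^2/g
    csda_range: np.ndarray  # g/cm^2, residual range from the 0.5 MeV cutoff


def _load_elements() -> dict[str, ElementData]:
    import pandas as pd

    data = resources.files("gridmc.data")
    with (data / "photon_xs.csv").open("r") as fh:
        ph = pd.read_csv(fh, comment="#")
    with (data / "electron_sp.csv").open("r") as fh:
        el = pd.read_csv(fh, comment="#")
    out: dict[str, ElementData] = {}
    for sym in ph["symbol"].unique():
        p = ph[ph["symbol"] == sym]
        e = el[el["symbol"] == sym]
        out[str(sym)] = ElementData(
            symbol=str(sym),
            atomic_number=int(p["Z"].iloc[0]),
            atomic_mass=float(p["A"].iloc[0]),
            energy_grid=np.asarray(p["energy_MeV"], dtype=float),
            cross_sections={
                "photoelectric": np.asarray(p["pe"], dtype=float),
                "incoherent": np.asarray(p["incoherent"], dtype=float),
                "coherent": np.asarray(p["coherent"], dtype=float),
                "pair": np.asarray(p["pair"], dtype=float),
            },
            electron_energy_grid=np.asarray(e["energy_MeV"], dtype=float),
            stopping_power=np.asarray(e["stopping_power"], dtype=float),
            csda_range=np.asarray(e["csda_range"], dtype=float),
        )
    return out


ELEMENTS: dict[str, ElementData] = _load_elements()

_ANY = next(iter(ELEMENTS.values()))
PHOTON_GRID: np.ndarray = _ANY.energy_grid
ELECTRON_GRID: np.ndarray = _ANY.electron_energy_grid

# mean fraction of the photon energy kept by the Compton-scattered photon,
# tabulated once on the master grid (used for the kerma-mode dose estimator)
_KN_SCATTER_FRACTION = np.asarray(klein_nishina_mean_scatter_fraction(PHOTON_GRID))


@dataclass(frozen=True)
class Material:
    """A compound medium with density and derived mixture-rule lookups."""

    name: str
    density: float  # g/cm^3
    composition: Mapping[str, float]  # element symbol -> weight fraction
    mass_coefficients: dict[str, np.ndarray] = field(repr=False, default=None)
    mass_stopping_power: np.ndarray = field(repr=False, default=None)
    mass_csda_range: np.ndarray = field(repr=False, default=None)

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, self.composition,
                        self.mass_coefficients, self.mass_stopping_power,
                        self.mass_csda_range)


def build_material(composition: Mapping[str, float], density: float,
                   name: str = "custom") -> Material:
    """Build a :class:`Material` from element weight fractions and density.

    Weight fractions must be positive and sum to 1 (no silent
    renormalisation); every element must exist in the embedded tables.
    """
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    for sym in composition:
        if sym not in ELEMENTS:
            raise UnknownElementError(
                f"element {sym!r} is not in the embedded physics tables")
    fractions = np.array(list(composition.values()), dtype=float)
    if np.any(fractions <= 0):
        raise ValueError("weight fractions must be positive")
    total = fractions.sum()
    if abs(total - 1.0) > _WEIGHT_FRACTION_TOL:
        raise ValueError(
            f"weight fractions sum to {total!r}, not 1 (no silent renormalisation)")

    coeffs = {p: np.zeros_like(PHOTON_GRID) for p in PROCESSES}
    s_mass = np.zeros_like(ELECTRON_GRID)
    for sym, w in composition.items():
        el = ELEMENTS[sym]
        for p in PROCESSES:
            coeffs[p] += w * el.cross_sections[p]
        s_mass += w * el.stopping_power
    # residual CSDA range of the mixture from the mixed stopping power
    fine = np.linspace(ELECTRON_GRID[0], ELECTRON_GRID[-1], 2001)
    inv_s = 1.0 / np.interp(fine, ELECTRON_GRID, s_mass)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (inv_s[1:] + inv_s[:-1]) * np.diff(fine))])
    r_mass = np.interp(ELECTRON_GRID, fine, cum)
    return Material(name, float(density), dict(composition), coeffs, s_mass, r_mass)


def _check_span(energy, grid, what: str):
    e = np.asarray(energy, dtype=float)
    if np.any(e < grid[0] - 1e-12) or np.any(e > grid[-1] + 1e-12):
        raise ValueError(
            f"{what} energy outside table span [{grid[0]:g}, {grid[-1]:g}] MeV"
            " (no extrapolation)")
    return np.clip(e, grid[0], grid[-1])


def _loglog_interp(e: np.ndarray, grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    floor = 1e-30
    return np.exp(np.interp(np.log(e), np.log(grid), np.log(np.maximum(values, floor))))


def mass_attenuation(material: Material, energy) -> dict[str, np.ndarray]:
    """Per-process mass attenuation coefficients (cm^2/g) at ``energy``."""
    e = _check_span(energy, PHOTON_GRID, "photon")
    out = {}
    for p in PROCESSES:
        if p == "pair":
            v = np.interp(e, PHOTON_GRID, material.mass_coefficients[p])
            v = np.where(e <= PAIR_THRESHOLD_MEV, 0.0, v)
        else:
            v = _loglog_interp(e, PHOTON_GRID, material.mass_coefficients[p])
        out[p] = v
    return out


def mu_total(material: Material, energy):
    """Linear attenuation coefficient (1/cm) and per-process partials.

    Returns ``(mu_total, partials)`` where ``partials`` maps process name to
    the linear partial coefficient; the total is their exact sum.
    """
    mass = mass_attenuation(material, energy)
    partials = {p: material.density * v for p, v in mass.items()}
    total = sum(partials.values())
    return total, partials


def sample_interaction(material: Material, energy, rng: np.random.Generator):
    """Draw interaction process labels with probability partial_i / mu_total."""
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    total, partials = mu_total(material, e)
    probs = np.stack([np.broadcast_to(partials[p], e.shape) for p in PROCESSES])
    cdf = np.cumsum(probs, axis=0) / total
    u = rng.random(e.shape)
    idx = (u[None, :] >= cdf).sum(axis=0)
    labels = np.array(PROCESSES, dtype=object)[idx]
    return labels if np.ndim(energy) else labels[0]


def klein_nishina_sample(energy, rng: np.random.Generator, n: int | None = None):
    """Sample Compton-scattered photon energies and polar angles.

    Free-electron Klein–Nishina sampling by the standard composition–
    rejection method (mixture of 1/eps and eps densities with the
    angular rejection factor), where ``eps = E'/E``.

    Returns ``(e_scattered, theta)``; shapes follow ``energy`` or ``n``.
    """
    scalar = np.ndim(energy) == 0 and n is None
    if n is not None:
        e = np.full(n, float(energy))
    else:
        e = np.atleast_1d(np.asarray(energy, dtype=float)).copy()
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    k = e / ELECTRON_REST_MEV
    eps_min = 1.0 / (1.0 + 2.0 * k)
    alpha1 = -np.log(eps_min)
    alpha2 = 0.5 * (1.0 - eps_min**2)
    eps = np.empty_like(e)
    todo = np.ones(e.shape, dtype=bool)
    while np.any(todo):
        m = int(todo.sum())
        u1, u2, u3 = rng.random((3, m))
        km = k[todo]
        em = eps_min[todo]
        pick_log = u1 < alpha1[todo] / (alpha1[todo] + alpha2[todo])
        cand = np.where(pick_log,
                        em * np.exp(alpha1[todo] * u2),
                        np.sqrt(em**2 + (1.0 - em**2) * u2))
        cos_t = 1.0 - (1.0 - cand) / (km * cand)
        sin2 = np.clip(1.0 - cos_t**2, 0.0, 1.0)
        accept = u3 <= 1.0 - cand * sin2 / (1.0 + cand**2)
        idx = np.flatnonzero(todo)
        ok = idx[accept]
        eps[ok] = cand[accept]
        todo[ok] = False
    cos_theta = np.clip(1.0 - (1.0 - eps) / (k * eps), -1.0, 1.0)
    e_out = eps * e
    theta = np.arccos(cos_theta)
    if scalar:
        return float(e_out[0]), float(theta[0])
    return e_out, theta


def electron_stopping_and_range(material: Material, energy):
    """Total stopping power (MeV/cm) and residual CSDA range (cm).

    The range is measured down to the 0.5 MeV electron transport cutoff,
    consistent with integrating 1/S over the transport window.
    """
    e = _check_span(energy, ELECTRON_GRID, "electron")
    s = np.interp(e, ELECTRON_GRID, material.mass_stopping_power) * material.density
    r = np.interp(e, ELECTRON_GRID, material.mass_csda_range) / material.density
    if np.ndim(energy) == 0:
        return float(s), float(r)
    return s, r


def compton_scatter_fraction(energy) -> np.ndarray:
    """Mean fraction of energy kept by the scattered photon (table lookup)."""
    e = _check_span(energy, PHOTON_GRID, "photon")
    return np.interp(e, PHOTON_GRID, _KN_SCATTER_FRACTION)


def kerma_factor(material: Material, energy):
    """Track-length collision-kerma response: E * mu_tr (MeV/cm).

    Mean energy transferred to charged particles per unit photon path:
    photoelectric transfers everything, Compton the Klein–Nishina mean
    recoil fraction, pair production everything above 1.022 MeV, coherent
    scattering nothing.  Multiplying fluence (track length / volume) by
    this factor gives collision kerma, which equals absorbed dose under
    charged-particle equilibrium.
    """
    e = np.asarray(energy, dtype=float)
    _, partials = mu_total(material, e)
    f_c = 1.0 - compton_scatter_fraction(e)
    transfer = (partials["photoelectric"] * e
                + partials["incoherent"] * f_c * e
                + partials["pair"] * np.maximum(e - PAIR_THRESHOLD_MEV, 0.0))
    return transfer


_REGISTRY_SPECS = {
    # name: (composition, density g/cm^3)  -- densities are handbook values
    "water": ({"H": 0.1119, "O": 0.8881}, 1.000),
    "air": ({"N": 0.755, "O": 0.232, "Ar": 0.013}, 0.0012),
    "pmma": ({"H": 0.0805418, "C": 0.5998482, "O": 0.3196100}, 1.19),
    "brass": ({"Zn": 0.37, "Cu": 0.63}, 8.49),
    "cerrobend": ({"Cd": 0.10, "Sn": 0.133, "Pb": 0.267, "Bi": 0.50}, 9.38),
}

REGISTRY: dict[str, Material] = {
    name: build_material(comp, rho, name=name)
    for name, (comp, rho) in _REGISTRY_SPECS.items()
}


def get_material(name: str, density: float | None = None) -> Material:
    """Look up a registry material by name, optionally overriding density."""
    try:
        mat = REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; registry has {sorted(REGISTRY)}") from None
    return mat.with_density(density) if density is not None else mat
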