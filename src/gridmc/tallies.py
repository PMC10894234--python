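"""Scoring structures: dose meshes, fluence spectra, in-air plane, per-MU.

Every tally keeps one accumulator slice per statistical batch; means and
standard errors are formed over batches.  Voxel boundaries are half-open
``[lower, upper)``; depth is measured from the phantom surface along the
beam axis.

The geometry mirrors the standard grid-dosimetry scoring setup:

* ``cyl_dose``  — cylindrical central-axis mesh, 4 mm radius x 2 mm height
  voxels over 0-30 cm depth, energy deposition, tag-resolved.
* ``kerma``     — the same mesh scored with the track-length collision-kerma
  estimator (low-variance dose under charged-particle equilibrium).
* ``flu_mesh``  — energy-integrated photon track-length fluence on the same
  mesh, tag-resolved (the percentage-depth-fluence input).
* ``rect``      — rectangular 0.5 x 0.5 x 0.1 cm^3 voxels in the plane at
  10 cm depth (lateral dose profiles).
* ``spec_p`` / ``spec_e`` — photon (100 bins, 0.01-6.02 MeV) and electron
  (92 bins, 0.5-6.02 MeV) track-length fluence spectra in 4 mm radius x
  2 mm height cylinders at depths 1.5, 5 and 10 cm, tag-resolved.
* ``in_air``    — track-length fluence in a 50 x 50 x 0.1 cm^3 slab with its
  top face 35 cm upstream of the isocenter (below the grid).

Scoring is implemented twice on purpose: the python ``score_*`` methods
define the binning semantics and serve the unit tests; the transport
kernel reimplements the identical rules in compiled code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .analysis import DepthCurve, LateralProfile

# mesh geometry (cm)
CYL_RADIUS = 0.4
CYL_DZ = 0.2
CYL_ZMAX = 30.0
N_CYL = int(round(CYL_ZMAX / CYL_DZ))  # 150
CYL_VOXEL_CM3 = np.pi * CYL_RADIUS**2 * CYL_DZ

RECT_DX = 0.5
RECT_DZ = 0.1
RECT_HALF = 14.0
N_RECT = int(round(2 * RECT_HALF / RECT_DX))  # 56
RECT_DEPTH = 10.0
RECT_VOXEL_CM3 = RECT_DX * RECT_DX * RECT_DZ

SPEC_DEPTHS = (1.5, 5.0, 10.0)
N_PHOTON_BINS = 100
PHOTON_EDGES = np.linspace(0.01, 6.02, N_PHOTON_BINS + 1)
N_ELECTRON_BINS = 92
ELECTRON_EDGES = np.linspace(0.5, 6.02, N_ELECTRON_BINS + 1)
SPEC_VOXEL_CM3 = CYL_VOXEL_CM3

IN_AIR_Z = 65.0  # cm from source (top face), 35 cm upstream of isocenter
IN_AIR_THICKNESS = 0.1
IN_AIR_HALF = 25.0
IN_AIR_VOLUME = (2 * IN_AIR_HALF) ** 2 * IN_AIR_THICKNESS

MEV_PER_G_TO_CGY = 1.602176634e-8  # 1 MeV/g in cGy

N_TAGS = 2  # primary, scattered
TAG_NAMES = ("primary", "scattered")

# counter slots
CTR_ENERGY_IN = 0
CTR_DEPOSITED = 1
CTR_ESCAPED = 2
CTR_ROULETTE_NET = 3
CTR_STACK_LOST = 4
CTR_OUT_OF_MESH = 5
CTR_SPEC_OVERFLOW = 6
N_COUNTERS = 8


def _tag_index(tag) -> int:
    if tag in (0, 1):
        return int(tag)
    return TAG_NAMES.index(tag)


@dataclass
class CylMeshTally:
    """Tag-resolved energy deposition on the central-axis cylinder mesh."""

    n_batches: int
    data: np.ndarray = None  # (nb, 2, N_CYL) MeV
    out_of_mesh: float = 0.0

    def __post_init__(self):
        if self.data is None:
            self.data = np.zeros((self.n_batches, N_TAGS, N_CYL))

    def score_dose(self, batch: int, depth_cm: float, r_cm: float,
                   deposit_mev: float, tag) -> None:
        if deposit_mev < 0:
            raise ValueError("negative energy deposit")
        i = int(np.floor(depth_cm / CYL_DZ))
        if 0 <= i < N_CYL and r_cm <= CYL_RADIUS and depth_cm >= 0:
            self.data[batch, _tag_index(tag), i] += deposit_mev
        else:
            self.out_of_mesh += deposit_mev


@dataclass
class RectMeshTally:
    """Energy deposition in the lateral-profile voxel plane at 10 cm."""

    n_batches: int
    data: np.ndarray = None  # (nb, N_RECT, N_RECT) MeV

    def __post_init__(self):
        if self.data is None:
            self.data = np.zeros((self.n_batches, N_RECT, N_RECT))

    def score_dose(self, batch: int, x_cm: float, y_cm: float,
                   deposit_mev: float) -> None:
        ix = int(np.floor((x_cm + RECT_HALF) / RECT_DX))
        iy = int(np.floor((y_cm + RECT_HALF) / RECT_DX))
        if 0 <= ix < N_RECT and 0 <= iy < N_RECT:
            self.data[batch, ix, iy] += deposit_mev


@dataclass
class SpectrumTally:
    """Track-length fluence spectra in the small cylinders at 3 depths."""

    species: str  # "photon" | "electron"
    n_batches: int
    data: np.ndarray = None  # (nb, 3, 2, nbins) 1/cm^2
    overflow: float = 0.0
    underflow: float = 0.0

    def __post_init__(self):
        nbins = N_PHOTON_BINS if self.species == "photon" else N_ELECTRON_BINS
        if self.data is None:
            self.data = np.zeros((self.n_batches, len(SPEC_DEPTHS), N_TAGS, nbins))

    @property
    def edges(self) -> np.ndarray:
        return PHOTON_EDGES if self.species == "photon" else ELECTRON_EDGES

    def score_fluence(self, batch: int, depth_index: int, chord_cm: float,
                      energy_mev: float, weight: float, tag) -> None:
        if chord_cm < 0:
            raise ValueError("negative chord length")
        edges = self.edges
        contribution = weight * chord_cm / SPEC_VOXEL_CM3
        if energy_mev < edges[0]:
            self.underflow += contribution
            return
        if energy_mev > edges[-1]:
            self.overflow += contribution
            return
        i = min(int((energy_mev - edges[0]) / (edges[1] - edges[0])),
                len(edges) - 2)
        self.data[batch, depth_index, _tag_index(tag), i] += contribution


@dataclass
class InAirTally:
    """Track-length fluence in the 50 x 50 x 0.1 cm^3 slab below the grid."""

    n_batches: int
    data: np.ndarray = None  # (nb, 2) 1/cm^2

    def __post_init__(self):
        if self.data is None:
            self.data = np.zeros((self.n_batches, N_TAGS))

    def score_fluence(self, batch: int, chord_cm: float, weight: float,
                      tag) -> None:
        if chord_cm < 0:
            raise ValueError("negative chord length")
        self.data[batch, _tag_index(tag)] += weight * chord_cm / IN_AIR_VOLUME


@dataclass
class TallySet:
    """All tallies of one simulation run plus bookkeeping counters."""

    n_batches: int
    n_histories: int
    meta: dict = field(default_factory=dict)
    histories_per_mu: float | None = None

    def __post_init__(self):
        nb = self.n_batches
        self.cyl = CylMeshTally(nb)
        self.kerma = np.zeros((nb, N_CYL))  # MeV/g via track-length estimator
        self.flu_mesh = np.zeros((nb, N_TAGS, N_CYL))  # 1/cm^2
        self.rect = RectMeshTally(nb)
        self.spec_p = SpectrumTally("photon", nb)
        self.spec_e = SpectrumTally("electron", nb)
        self.in_air = InAirTally(nb)
        self.counters = np.zeros((nb, N_COUNTERS))

    # ---------------- statistics helpers ----------------

    def _mean_sigma(self, per_batch: np.ndarray):
        """Mean and standard error per history from per-batch sums."""
        nb = self.n_batches
        per_hist = per_batch * nb / self.n_histories  # batch means per history
        mean = per_hist.mean(axis=0)
        sigma = per_hist.std(axis=0, ddof=1) / np.sqrt(nb) if nb > 1 \
            else np.zeros_like(mean)
        return mean, sigma

    def _unit_factor(self, per: str, mass_g: float) -> float:
        if per == "history":
            return 1.0
        if per == "mu":
            if self.histories_per_mu is None:
                raise ValueError("per-MU requested but calibration is missing; "
                                 "run per_mu_normalize first")
            return self.histories_per_mu
        raise ValueError(f"unknown unit request {per!r}")

    # ---------------- accessors ----------------

    @staticmethod
    def depth_axis() -> np.ndarray:
        return (np.arange(N_CYL) + 0.5) * CYL_DZ

    def cyl_dose_depth_curve(self, tag: str = "total",
                             per: str = "history") -> DepthCurve:
        """Central-axis depth-dose curve in cGy (per history or per MU)."""
        if tag == "total":
            per_batch = self.cyl.data.sum(axis=1)
        else:
            per_batch = self.cyl.data[:, _tag_index(tag), :]
        mass = CYL_VOXEL_CM3  # water, rho = 1
        mean, sigma = self._mean_sigma(per_batch)
        f = MEV_PER_G_TO_CGY / mass * self._unit_factor(per, mass)
        return DepthCurve(self.depth_axis(), mean * f, sigma * f)

    def kerma_depth_curve(self, per: str = "history") -> DepthCurve:
        mean, sigma = self._mean_sigma(self.kerma)
        f = MEV_PER_G_TO_CGY * self._unit_factor(per, 1.0)
        return DepthCurve(self.depth_axis(), mean * f, sigma * f)

    def fluence_depth_curve(self, tag: str = "total",
                            per: str = "history") -> DepthCurve:
        if tag == "total":
            per_batch = self.flu_mesh.sum(axis=1)
        else:
            per_batch = self.flu_mesh[:, _tag_index(tag), :]
        mean, sigma = self._mean_sigma(per_batch)
        f = self._unit_factor(per, 1.0)
        return DepthCurve(self.depth_axis(), mean * f, sigma * f)

    def dose_in_axial_voxel(self, depth_cm: float, height_cm: float = 0.4,
                            estimator: str = "kerma", per: str = "history"):
        """Dose in a 4 mm radius axial voxel centred at ``depth_cm``.

        ``estimator`` selects the track-length collision-kerma mesh
        (low variance; equals dose under CPE) or the analog energy
        deposition mesh.  Returns (value_cGy, sigma_cGy).
        """
        half = height_cm / 2.0
        i0 = int(np.floor((depth_cm - half) / CYL_DZ + 1e-9))
        i1 = int(np.ceil((depth_cm + half) / CYL_DZ - 1e-9))
        sel = slice(max(i0, 0), min(i1, N_CYL))
        nvox = sel.stop - sel.start
        if estimator == "kerma":
            per_batch = self.kerma[:, sel].mean(axis=1)
            f = MEV_PER_G_TO_CGY
        elif estimator == "pedep":
            per_batch = self.cyl.data.sum(axis=1)[:, sel].sum(axis=1)
            f = MEV_PER_G_TO_CGY / (CYL_VOXEL_CM3 * nvox)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        mean, sigma = self._mean_sigma(per_batch)
        f *= self._unit_factor(per, 1.0)
        return float(mean * f), float(sigma * f)

    def photon_spectrum(self, depth_cm: float, tag: str = "total",
                        per: str = "history"):
        return self._spectrum(self.spec_p, depth_cm, tag, per)

    def electron_spectrum(self, depth_cm: float, tag: str = "total",
                          per: str = "history"):
        return self._spectrum(self.spec_e, depth_cm, tag, per)

    def _spectrum(self, tally: SpectrumTally, depth_cm, tag, per):
        d = SPEC_DEPTHS.index(depth_cm)
        if tag == "total":
            per_batch = tally.data[:, d, :, :].sum(axis=1)
        else:
            per_batch = tally.data[:, d, _tag_index(tag), :]
        mean, sigma = self._mean_sigma(per_batch)
        f = self._unit_factor(per, 1.0)
        return tally.edges, mean * f, sigma * f

    def profile(self, per: str = "history") -> LateralProfile:
        """Lateral dose profile along x through the axis at 10 cm depth.

        The mesh has an even voxel count, so the two central y-rows are
        averaged.
        """
        mid = N_RECT // 2
        rows = self.rect.data[:, :, mid - 1: mid + 1].mean(axis=2)
        mean, sigma = self._mean_sigma(rows)
        f = MEV_PER_G_TO_CGY / RECT_VOXEL_CM3 * self._unit_factor(per, 1.0)
        x = (np.arange(N_RECT) + 0.5) * RECT_DX - RECT_HALF
        return LateralProfile(x, mean * f, sigma * f)

    def in_air_fluence(self, tag: str = "total", per: str = "history"):
        if tag == "total":
            per_batch = self.in_air.data.sum(axis=1)
        else:
            per_batch = self.in_air.data[:, _tag_index(tag)]
        mean, sigma = self._mean_sigma(per_batch)
        f = self._unit_factor(per, 1.0)
        return float(mean * f), float(sigma * f)

    def counter(self, slot: int) -> float:
        return float(self.counters[:, slot].sum())

    # ---------------- normalisation ----------------

    def per_mu_normalize(self, histories_per_mu: float | None = None) -> None:
        """Attach the histories-per-MU calibration to this tally set.

        The calibration comes from a reference run (open 10x10, SSD 100):
        the number of histories that deliver 1 cGy at the depth of
        maximum dose.  After normalisation all ``per="mu"`` accessors
        return fluence in 1/cm^2/MU and dose in cGy/MU.
        """
        if histories_per_mu is None:
            if self.histories_per_mu is None:
                raise ValueError("no calibration available: pass the "
                                 "histories-per-MU value from a reference run")
            return
        if histories_per_mu <= 0:
            raise ValueError("histories per MU must be positive")
        self.histories_per_mu = float(histories_per_mu)

    # ---------------- persistence ----------------

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["n_batches"] = self.n_batches
            f.attrs["n_histories"] = self.n_histories
            f.attrs["meta"] = json.dumps(self.meta)
            if self.histories_per_mu is not None:
                f.attrs["histories_per_mu"] = self.histories_per_mu
            g = f.create_group("tallies")
            g.create_dataset("cyl_dose", data=self.cyl.data)
            g.create_dataset("kerma", data=self.kerma)
            g.create_dataset("flu_mesh", data=self.flu_mesh)
            g.create_dataset("rect", data=self.rect.data)
            g.create_dataset("spec_p", data=self.spec_p.data)
            g.create_dataset("spec_e", data=self.spec_e.data)
            g.create_dataset("in_air", data=self.in_air.data)
            g.create_dataset("counters", data=self.counters)

    @classmethod
    def load(cls, path) -> "TallySet":
        import h5py

        with h5py.File(path, "r") as f:
            ts = cls(int(f.attrs["n_batches"]), int(f.attrs["n_histories"]),
                     meta=json.loads(f.attrs["meta"]))
            if "histories_per_mu" in f.attrs:
                ts.histories_per_mu = float(f.attrs["histories_per_mu"])
            g = f["tallies"]
            ts.cyl.data[:] = g["cyl_dose"][...]
            ts.kerma[:] = g["kerma"][...]
            ts.flu_mesh[:] = g["flu_mesh"][...]
            ts.rect.data[:] = g["rect"][...]
            ts.spec_p.data[:] = g["spec_p"][...]
            ts.spec_e.data[:] = g["spec_e"][...]
            ts.in_air.data[:] = g["in_air"][...]
            ts.counters[:] = g["counters"][...]
        return ts


def export_curve_csv(path, coordinate, value, sigma, header: str) -> None:
    """Write a 1-D tally as CSV: '#' header, columns coordinate,value,sigma."""
    arr = np.column_stack([coordinate, value, sigma])
    np.savetxt(path, arr, delimiter=",", header=header, comments="# ")
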