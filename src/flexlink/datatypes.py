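"""Core containers shared across the pipeline.

Units are fixed package-wide: coordinates and distances in Å, momentum
transfer q in Å⁻¹, concentrations in µM, chemical shifts in ppm,
relaxation rates in s⁻¹, correlation times in ns, and the magnetic field
stated as the ¹H resonance frequency in MHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


@dataclass
class SAXSProfile:
    """A reduced small-angle scattering curve I(q) with point-wise errors.

    Parameters
    ----------
    q : array
        Momentum transfer grid in Å⁻¹, strictly increasing and positive.
    I : array
        Scattered intensity, arbitrary units.
    sigma : array
        One-standard-deviation uncertainty per point, same units as ``I``.
    label : str
        Free-text identifier (sample name, concentration, ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.q)
        if not (len(self.I) == len(self.sigma) == n):
            raise ValueError("q, I, sigma must have equal length")
        if n < 8:
            raise FormatError(f"profile needs >= 8 points, got {n}")
        if np.any(self.q <= 0):
            raise ValueError("q must be positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        if not (np.all(np.isfinite(self.I)) and np.all(np.isfinite(self.sigma))):
            raise ValueError("I and sigma must be finite")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class ShiftTable:
    """Per-residue amide ¹H/¹⁵N shifts over a titration ladder.

    ``dH`` and ``dN`` are DataFrames indexed by residue id with one column
    per titration point; NaN marks a residue whose peak was not observed
    (broadened or unassigned) at that point.  ``P0`` and ``L0`` give the
    protein and ligand concentration (µM) of each point; point 0 is the
    ligand-free reference.
    """

    dH: pd.DataFrame
    dN: pd.DataFrame
    P0: np.ndarray
    L0: np.ndarray
    domains: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P0 = np.asarray(self.P0, dtype=float)
        self.L0 = np.asarray(self.L0, dtype=float)
        npts = len(self.P0)
        if len(self.L0) != npts:
            raise ValueError("P0 and L0 must have equal length")
        if self.dH.shape[1] != npts or self.dN.shape[1] != npts:
            raise FormatError("shift tables must have one column per point")
        if not self.dH.index.equals(self.dN.index):
            raise FormatError("dH and dN must list the same residues")
        if self.dH.index.has_duplicates:
            raise FormatError("duplicated residue id in shift table")
        if npts and self.L0[0] != 0:
            raise FormatError("titration must start from a ligand-free point (L0 = 0)")
        if np.any(self.P0 < 0) or np.any(self.L0 < 0):
            raise ValueError("concentrations must be non-negative")
        ref = self.dH.iloc[:, 0]
        if ref.isna().any() or self.dN.iloc[:, 0].isna().any():
            missing = list(self.dH.index[ref.isna() | self.dN.iloc[:, 0].isna()])
            raise FormatError(f"residues missing at the reference point: {missing}")

    @property
    def residues(self) -> np.ndarray:
        return self.dH.index.to_numpy()

    @property
    def n_points(self) -> int:
        return len(self.P0)

    def broadened(self) -> dict[int, int]:
        """Residues that vanish during the titration.

        Returns a mapping residue id -> first point index at which the peak
        is missing.  Such residues are excluded from isotherm fitting but
        counted in reports.
        """
        out: dict[int, int] = {}
        mask = self.dH.isna() | self.dN.isna()
        for res in self.dH.index:
            row = mask.loc[res].to_numpy()
            if row.any():
                out[int(res)] = int(np.argmax(row))
        return out


@dataclass
class IntensityTable:
    """Peak intensities versus relaxation delay for one experiment type.

    ``experiment`` is one of ``R1``, ``R2``, ``NOE_sat``, ``NOE_ref``.
    For rate experiments ``delays`` holds the relaxation delays in seconds;
    for the NOE pair a single pseudo-delay of 0 is used.
    """

    residues: np.ndarray
    delays: np.ndarray
    intensities: np.ndarray  # shape (n_residues, n_delays)
    experiment: str
    field_mhz: float = 600.0

    VALID = ("R1", "R2", "NOE_sat", "NOE_ref")

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.delays = np.asarray(self.delays, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.experiment not in self.VALID:
            raise ValueError(f"experiment must be one of {self.VALID}")
        if self.intensities.shape != (len(self.residues), len(self.delays)):
            raise ValueError("intensity matrix shape mismatch")
        if np.any(self.delays < 0):
            raise ValueError("delays must be non-negative")
        if self.experiment in ("R1", "R2") and len(np.unique(self.delays)) < 5:
            raise FormatError("rate experiments need >= 5 distinct delays")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class BeadModel:
    """One bead (Cα) per residue coarse model of a multidomain chain.

    ``domains`` labels each residue (e.g. ``UIM``/``linker``/``SH3``);
    ``flexible`` is the set of residue ids at which the backbone may pivot.
    """

    coords: np.ndarray  # (n, 3) Å
    residues: np.ndarray
    domains: np.ndarray
    flexible: frozenset[int] = frozenset()

    BOND_RANGE = (2.9, 4.1)
    CLASH_CUTOFF = 3.0  # hard-core, Å; non-adjacent beads may not approach closer

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residues = np.asarray(self.residues, dtype=int)
        self.domains = np.asarray(self.domains, dtype=object)
        n = len(self.residues)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if len(self.domains) != n:
            raise ValueError("one domain label per residue required")
        if n >= 2:
            d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
            lo, hi = self.BOND_RANGE
            bad = np.where((d < lo) | (d > hi))[0]
            if bad.size:
                i = bad[0]
                raise ValueError(
                    f"bead distance {d[i]:.2f} Å between residues "
                    f"{self.residues[i]} and {self.residues[i + 1]} outside {self.BOND_RANGE}"
                )
        if n >= 3 and self.min_nonadjacent_distance() < self.CLASH_CUTOFF:
            raise ValueError("non-adjacent bead clash below hard-core cutoff")

    def __len__(self) -> int:
        return len(self.residues)

    def min_nonadjacent_distance(self) -> float:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        idx = np.arange(len(self))
        sep = np.abs(idx[:, None] - idx[None, :])
        dist[sep <= 1] = np.inf
        return float(dist.min())

    def rg(self) -> float:
        """Radius of gyration of the bead cloud (uniform weights), Å."""
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum(axis=1).mean()))

    def with_coords(self, coords: np.ndarray) -> "BeadModel":
        return BeadModel(coords, self.residues.copy(), self.domains.copy(), self.flexible)


@dataclass
class RelaxationRecord:
    """Fitted ¹⁵N relaxation observables for one residue."""

    residue: int
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    NOE: float
    NOE_err: float
    field_mhz: float = 600.0
    domain: str = ""

    def validate(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise ValueError("relaxation rates must be positive")
        if self.NOE > 1.05:
            raise ValueError("NOE above theoretical ceiling")


@dataclass
class SpectralDensities:
    """Reduced spectral densities J(0), J(ωN), J(0.87ωH) in s/rad."""

    residue: int
    J0: float
    JwN: float
    JwH: float
    flagged: bool = False  # negative J0 (exchange or noise) — value kept, flagged


def as_float_array(x: Sequence[float]) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite value in input")
    return a
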