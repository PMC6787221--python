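"""Synthetic data with the statistical structure the analyses assume.

The generators emulate a two-rigid-body protein — a short N-terminal
helix (UIM-like) and a compact globular domain (SH3-like) joined by a
disordered linker — and produce titration shift tables following the
fast-exchange isotherms, relaxation decays from Lipari–Szabo spectral
densities with distinct per-domain tumbling times, and SAXS curves as
noisy weighted mixtures of conformer profiles.  Every generator is
deterministic under a fixed seed and records a :class:`SyntheticTruth`
sufficient to regenerate the dataset bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import relaxation as rx
from .datatypes import BeadModel, IntensityTable, SAXSProfile, ShiftTable
from .ensemble import ConformerPool
from .titration import binding_curve_1to1, binding_curve_2to1

log = logging.getLogger(__name__)

BOND = 3.8  # Å, consecutive-bead distance
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST = np.deg2rad(100.0)
SHELL_SPACING = 4.0  # Å between spiral shells of the globule
HARD_CORE = 3.2  # Å, generation-time clearance (above BeadModel hard core)

# default noise levels: meaningful but not fragile recovery tests
DEFAULT_SHIFT_NOISE = 0.005  # ppm on the 1H component
DEFAULT_INTENSITY_NOISE = 0.02  # fractional
DEFAULT_SAXS_NOISE_A = 0.01  # sigma = a*sqrt(I(0)*I(q))

#: fixed convention for splitting a combined CSP back into components
DELTA_N_OVER_DELTA_H = 2.0
_SPLIT_H = np.sqrt(50.0 / 29.0)  # so that the recombined CSP equals the input


@dataclass
class SyntheticTruth:
    """Ground-truth record serialized alongside every generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    _INT_KEYED = ("dd_bound", "S2", "residue_domains", "weights")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        for key in cls._INT_KEYED:  # JSON stringifies integer map keys
            if key in data.get("params", {}):
                data["params"][key] = {int(k): v for k, v in data["params"][key].items()}
        return cls(**data)


# ------------------------------------------------------------- bead model

def _ideal_helix(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([
        HELIX_RADIUS * np.cos(HELIX_TWIST * i),
        HELIX_RADIUS * np.sin(HELIX_TWIST * i),
        HELIX_RISE * i,
    ])


def _spiral_globule(n: int) -> np.ndarray:
    """Concentric spherical-spiral ("yarn-ball") packing of ``n`` beads.

    Consecutive beads sit one bond apart along the spiral; shells are one
    shell spacing apart and alternate winding direction so the chain
    crosses between shells with a single radial step.  Deterministic and
    clash-free by construction.
    """
    pts = [np.zeros(3)]
    shell = 0
    direction = np.array([0.0, 0.0, 1.0])  # pole at which the next shell starts
    while len(pts) < n:
        shell += 1
        r = SHELL_SPACING * shell
        c = 2.0 * np.pi * r / SHELL_SPACING  # phi turns per unit theta
        # frame: z-axis along the entry pole
        z = direction
        x = np.array([1.0, 0.0, 0.0])
        if abs(z @ x) > 0.9:
            x = np.array([0.0, 1.0, 0.0])
        x = x - (x @ z) * z
        x /= np.linalg.norm(x)
        y = np.cross(z, x)
        # walk the spiral in fine increments, dropping a bead whenever the
        # straight-line (chord) distance from the last bead reaches one bond
        theta, phi = 0.0, 0.0
        shell_pts = [r * z]
        last = shell_pts[0]
        while theta < np.pi:
            speed = r * np.sqrt(1.0 + (c * np.sin(theta)) ** 2)  # |dp/dθ|
            theta += BOND / (50.0 * speed)
            if theta >= np.pi:
                break
            phi = c * theta
            p = r * (np.sin(theta) * (np.cos(phi) * x + np.sin(phi) * y) + np.cos(theta) * z)
            if np.linalg.norm(p - last) >= BOND:
                shell_pts.append(p)
                last = p
        pts.extend(shell_pts)
        direction = shell_pts[-1] / np.linalg.norm(shell_pts[-1])
    return np.array(pts[:n])


def _grow_saw(start: np.ndarray, n: int, occupied: np.ndarray,
              rng: np.random.Generator, bias: np.ndarray | None = None,
              max_restarts: int = 200) -> np.ndarray:
    """Self-avoiding walk of ``n`` beads with fixed bond length, keeping
    every new bead at least HARD_CORE from all previously placed beads."""
    for _ in range(max_restarts):
        chain = [start]
        ok = True
        for k in range(1, n):
            placed = False
            for _ in range(60):
                d = rng.normal(size=3)
                if bias is not None and k <= 2:
                    d = d + 2.0 * bias  # escape the parent domain surface
                d /= np.linalg.norm(d)
                cand = chain[-1] + BOND * d
                others = np.vstack([occupied] + [np.asarray(c) for c in chain[:-1]]) if chain[:-1] else occupied
                if np.min(np.linalg.norm(others - cand, axis=1)) >= HARD_CORE:
                    chain.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(chain)
    raise RuntimeError("self-avoiding linker placement failed after bounded retries")


def make_two_domain_model(helix_len: int = 15, linker_len: int = 20,
                          globule_len: int = 60, seed: int = 0) -> BeadModel:
    """Bead model of helix + disordered linker + globular domain.

    The chain runs helix (UIM-like, ideal-helix geometry), linker
    (self-avoiding, flexible), globule (SH3-like spherical-spiral
    packing).  ``helix_len`` may be 0 to emulate a UIM-deletion
    construct.  Residues are numbered 1..n; the linker residues form the
    flexible set.
    """
    if linker_len <= 0 or globule_len <= 0 or helix_len < 0:
        raise ValueError("lengths must be positive (helix_len may be 0)")
    rng = np.random.default_rng(seed)

    # geometric construction runs globule -> linker -> helix, then the
    # chain is reversed so the helix is N-terminal
    globule = _spiral_globule(globule_len)
    g_end = globule[-1]
    out_dir = g_end / np.linalg.norm(g_end)
    linker_start = g_end + BOND * out_dir
    for attempt in range(200):
        if np.min(np.linalg.norm(globule - linker_start, axis=1)) >= min(HARD_CORE, BOND):
            break
        d = rng.normal(size=3) + 2 * out_dir
        d /= np.linalg.norm(d)
        linker_start = g_end + BOND * d
    linker = _grow_saw(linker_start, linker_len, globule, rng, bias=out_dir)

    if helix_len > 0:
        occupied = np.vstack([globule, linker])
        for attempt in range(500):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            helix = _ideal_helix(helix_len)
            # random rigid orientation
            Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            helix = helix @ Q.T
            d = rng.normal(size=3) + 2 * (linker[-1] - globule.mean(axis=0)) / np.linalg.norm(linker[-1] - globule.mean(axis=0))
            d /= np.linalg.norm(d)
            helix = helix - helix[0] + linker[-1] + BOND * d
            dmin = np.min(np.linalg.norm(occupied[:, None, :] - helix[None, :, :], axis=-1))
            if dmin >= HARD_CORE and np.linalg.norm(helix[0] - linker[-1]) <= 4.1:
                break
        else:
            raise RuntimeError("helix placement failed after bounded retries")
        coords = np.vstack([globule, linker, helix])
        labels = ["SH3"] * globule_len + ["linker"] * linker_len + ["UIM"] * helix_len
    else:
        coords = np.vstack([globule, linker])
        labels = ["SH3"] * globule_len + ["linker"] * linker_len

    coords = coords[::-1].copy()
    labels = labels[::-1]
    n = len(coords)
    residues = np.arange(1, n + 1)
    flexible = frozenset(int(residues[i]) for i, lab in enumerate(labels) if lab == "linker")
    return BeadModel(coords=coords, residues=residues, domains=np.array(labels, dtype=object),
                     flexible=flexible)


# -------------------------------------------------------------- titration

def simulate_titration(Kd: float, dd_bound: dict[int, float], model: str,
                       P0: float, L0_ladder, noise: float = DEFAULT_SHIFT_NOISE,
                       seed: int = 0, domains: dict[int, str] | None = None,
                       ) -> tuple[ShiftTable, SyntheticTruth]:
    """Shift table for a titration following the 1:1 or 2:1 isotherm.

    Each residue gets a random but fixed baseline (δH, δN); the combined
    CSP predicted by the isotherm is split into components with the fixed
    convention ΔδN = 2 ΔδH, and Gaussian noise of width ``noise`` ppm
    (¹H) and 5×``noise`` ppm (¹⁵N) is added at every point.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    L0 = np.asarray(L0_ladder, dtype=float)
    if L0[0] != 0:
        raise ValueError("ladder must start at L0 = 0")
    curve = binding_curve_1to1 if model == "1to1" else binding_curve_2to1
    rng = np.random.default_rng(seed)
    residues = sorted(dd_bound)
    base_H = rng.uniform(7.5, 9.5, size=len(residues))
    base_N = rng.uniform(105.0, 130.0, size=len(residues))
    dH = {}
    dN = {}
    for i, res in enumerate(residues):
        csp = curve(Kd, dd_bound[res], P0, L0)
        # split: ΔδH = Δδ·sqrt(50/29), ΔδN = 2·ΔδH recombines to Δδ exactly
        dh = base_H[i] + csp * _SPLIT_H
        dn = base_N[i] + csp * _SPLIT_H * DELTA_N_OVER_DELTA_H
        dH[res] = dh + rng.normal(0.0, noise, size=len(L0)) if noise else dh
        dN[res] = dn + rng.normal(0.0, 5 * noise, size=len(L0)) if noise else dn
    table = ShiftTable(
        dH=pd.DataFrame.from_dict(dH, orient="index"),
        dN=pd.DataFrame.from_dict(dN, orient="index"),
        P0=np.full(len(L0), float(P0)),
        L0=L0,
        domains=dict(domains or {}),
    )
    truth = SyntheticTruth(kind="titration", seed=seed, params={
        "Kd": float(Kd), "dd_bound": {int(k): float(v) for k, v in dd_bound.items()},
        "model": model, "P0": float(P0), "L0": [float(x) for x in L0], "noise": float(noise),
    })
    return table, truth


def default_two_domain_dynamics(helix_len: int = 15, linker_len: int = 20,
                                globule_len: int = 60) -> tuple[dict[int, float], dict[int, str]]:
    """Default per-residue order parameters and domain map for a
    helix-linker-globule construct: rigid cores (S² = 0.85/0.87) and a
    flexible linker (S² = 0.4)."""
    S2: dict[int, float] = {}
    dom: dict[int, str] = {}
    res = 1
    for _ in range(helix_len):
        S2[res], dom[res] = 0.85, "UIM"
        res += 1
    for _ in range(linker_len):
        S2[res], dom[res] = 0.4, "linker"
        res += 1
    for _ in range(globule_len):
        S2[res], dom[res] = 0.87, "SH3"
        res += 1
    return S2, dom


# ------------------------------------------------------------- relaxation

R1_DELAYS = np.array([0.04, 0.08, 0.16, 0.32, 0.48, 0.72, 1.0, 1.4, 1.9, 2.4])  # s
R2_DELAYS = np.array([0.008, 0.016, 0.032, 0.048, 0.080, 0.112, 0.160, 0.224])  # s


def simulate_relaxation(tau_c: dict[str, float], S2: dict[int, float],
                        residue_domains: dict[int, str], tau_e_ps: float = 50.0,
                        field_mhz: float = 600.0, noise: float = DEFAULT_INTENSITY_NOISE,
                        seed: int = 0) -> tuple[dict[str, IntensityTable], SyntheticTruth]:
    """Relaxation decays from Lipari–Szabo spectral densities.

    ``tau_c`` maps domain label -> correlation time (ns); ``S2`` maps
    residue -> order parameter; each residue tumbles with its domain's
    τc.  Rates come from the full dipolar+CSA expressions and are
    rendered as noisy monoexponential intensity decays on the standard
    delay ladders, plus a saturated/reference NOE intensity pair.
    """
    for lab, tc in tau_c.items():
        if not 1.0 <= tc <= 30.0:
            raise ValueError(f"tau_c[{lab!r}] = {tc} ns outside the physical range 1-30 ns")
    for res, s2 in S2.items():
        if not 0.0 <= s2 <= 1.0:
            raise ValueError(f"S2[{res}] = {s2} outside [0, 1]")
    rng = np.random.default_rng(seed)
    constants = rx.PhysicalConstantsSet(field_mhz=field_mhz)
    residues = sorted(S2)
    rates = {}
    for res in residues:
        tc = tau_c[residue_domains[res]] * 1e-9
        j = lambda w, tc=tc, s2=S2[res]: rx.lipari_szabo_j(w, tc, s2, tau_e_ps * 1e-12)
        rates[res] = rx.rates_from_j(j, constants)

    I0 = 100.0

    def decay_table(exp: str, delays: np.ndarray, idx: int) -> IntensityTable:
        mat = np.empty((len(residues), len(delays)))
        for i, res in enumerate(residues):
            ideal = I0 * np.exp(-rates[res][idx] * delays)
            mat[i] = ideal + rng.normal(0.0, noise * I0, size=len(delays)) if noise else ideal
        return IntensityTable(residues=np.array(residues), delays=delays,
                              intensities=mat, experiment=exp, field_mhz=field_mhz)

    tables = {
        "R1": decay_table("R1", R1_DELAYS, 0),
        "R2": decay_table("R2", R2_DELAYS, 1),
    }
    sat = np.array([[rates[res][2] * I0] for res in residues])
    ref = np.full((len(residues), 1), I0)
    if noise:
        sat = sat + rng.normal(0.0, noise * I0, size=sat.shape)
        ref = ref + rng.normal(0.0, noise * I0, size=ref.shape)
    tables["NOE_sat"] = IntensityTable(np.array(residues), np.array([0.0]), sat, "NOE_sat", field_mhz)
    tables["NOE_ref"] = IntensityTable(np.array(residues), np.array([0.0]), ref, "NOE_ref", field_mhz)
    truth = SyntheticTruth(kind="relaxation", seed=seed, params={
        "tau_c_ns": {k: float(v) for k, v in tau_c.items()},
        "S2": {int(k): float(v) for k, v in S2.items()},
        "residue_domains": {int(k): v for k, v in residue_domains.items()},
        "tau_e_ps": float(tau_e_ps), "field_mhz": float(field_mhz), "noise": float(noise),
    })
    return tables, truth


# ------------------------------------------------------------------ SAXS

def simulate_saxs(pool: ConformerPool, weights: dict[int, float],
                  noise_a: float = DEFAULT_SAXS_NOISE_A, noise_b: float = 0.0,
                  seed: int = 0) -> tuple[SAXSProfile, SyntheticTruth]:
    """Noisy SAXS curve of a weighted conformer mixture.

    I(q) is the weight-combination of member Debye profiles;
    σ(q) = a·√(I(0)·I(q)) + b and Gaussian noise of width σ is applied.
    """
    if not weights:
        raise ValueError("weights must be non-empty")
    idx = sorted(weights)
    w = np.array([weights[i] for i in idx], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    I = w @ pool.profiles[idx]
    sigma = noise_a * np.sqrt(I[0] * I) + noise_b
    if np.any(sigma <= 0):
        raise ValueError("noise model produced non-positive sigma")
    rng = np.random.default_rng(seed)
    noisy = I + rng.normal(0.0, sigma)
    truth = SyntheticTruth(kind="saxs", seed=seed, params={
        "weights": {int(i): float(weights[i]) for i in idx},
        "noise_a": float(noise_a), "noise_b": float(noise_b),
        "pool_seed": pool.seed,
    })
    return SAXSProfile(pool.qgrid.copy(), noisy, sigma, label="synthetic mixture"), truth
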