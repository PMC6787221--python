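"""Coarse-grained scattering profiles, χ scoring, conformer sampling and
N-state ensemble selection for flexible multidomain proteins.

A single SAXS curve of a flexible protein is a population-weighted
average over conformations.  The pipeline therefore (i) computes a
Debye-formula profile per bead-model conformer, (ii) scores any model
profile against experiment with the σ-weighted χ (optimal scale folded
in analytically), and (iii) searches for the N-state weighted mixture
(N = 1..5) that best reproduces the experimental curve, reporting the
Rg distribution of the top-scoring models.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .datatypes import BeadModel, SAXSProfile

log = logging.getLogger(__name__)

DEFAULT_QGRID = np.linspace(0.01, 0.35, 171)  # Å⁻¹, typical reduced BM29 range
CLASH_DISTANCE = 4.0  # Å, between sequence-separated beads during sampling
MIN_SEQ_SEP = 3


def debye_profile(model: BeadModel | np.ndarray, qgrid: np.ndarray | None = None,
                  f: float = 1.0) -> np.ndarray:
    """Debye-formula intensity of a bead model with uniform form factor f:
    I(q) = Σᵢⱼ f² sin(q rᵢⱼ)/(q rᵢⱼ), diagonal terms included, so
    I(q→0) = (n f)².

    Rotation/translation invariant by construction (depends only on the
    pairwise distance multiset).
    """
    coords = model.coords if isinstance(model, BeadModel) else np.asarray(model, dtype=float)
    if len(coords) < 2:
        raise ValueError("need >= 2 beads")
    q = DEFAULT_QGRID if qgrid is None else np.asarray(qgrid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    iu, ju = np.triu_indices(len(coords), k=1)
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    if np.any(d < 1e-9):
        raise ValueError("coincident beads")
    n = len(coords)
    I = np.full(len(q), float(n))  # diagonal: n * sinc(0)
    # chunk the pair loop to bound memory on large models
    step = max(1, int(2e7 / max(len(q), 1)))
    for a in range(0, len(d), step):
        qr = np.outer(q, d[a : a + step])
        I += 2.0 * (np.sin(qr) / qr).sum(axis=1)
    return f * f * I


def chi_score(exp: SAXSProfile, model_I: np.ndarray,
              model_q: np.ndarray | None = None) -> tuple[float, float]:
    """σ-weighted χ between experiment and a model profile, with the
    closed-form optimal scale c = Σ(I_e I_m/σ²) / Σ(I_m²/σ²):

        χ = sqrt( (1/M) Σ ((I_e − c I_m)/σ)² )
    """
    model_I = np.asarray(model_I, dtype=float)
    if model_q is not None:
        model_q = np.asarray(model_q, dtype=float)
        if exp.q[0] < model_q[0] - 1e-12 or exp.q[-1] > model_q[-1] + 1e-12:
            raise ValueError("experimental q-range extends beyond the model grid")
        model_I = np.interp(exp.q, model_q, model_I)
    elif len(model_I) != len(exp):
        raise ValueError("model profile length mismatch (pass model_q to interpolate)")
    w = 1.0 / exp.sigma**2
    c = float(np.sum(w * exp.I * model_I) / np.sum(w * model_I**2))
    chi = float(np.sqrt(np.mean(((exp.I - c * model_I) / exp.sigma) ** 2)))
    return chi, c


@dataclass
class ConformerPool:
    """Conformers sharing one topology, with profiles on a common q-grid."""

    conformers: list[BeadModel]
    qgrid: np.ndarray
    profiles: np.ndarray  # (n_conformers, n_q)
    rgs: np.ndarray
    seed: int | None = None
    n_proposed: int = 0
    n_accepted: int = 0

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class EnsembleModel:
    """A weighted N-state mixture with its fit quality."""

    n_states: int
    members: tuple[int, ...]
    weights: np.ndarray  # normalized, each > 0
    chi: float
    scale: float
    member_rgs: np.ndarray

    def mixture_profile(self, pool: ConformerPool) -> np.ndarray:
        return self.weights @ pool.profiles[list(self.members)]


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _pivot_clash(coords: np.ndarray, pivot: int) -> bool:
    """Clash between the fixed (<= pivot) and moved (> pivot) segments,
    ignoring pairs closer than MIN_SEQ_SEP in sequence."""
    fixed = coords[: pivot + 1]
    moved = coords[pivot + 1 :]
    if len(fixed) == 0 or len(moved) == 0:
        return False
    d2 = ((fixed[:, None, :] - moved[None, :, :]) ** 2).sum(axis=-1)
    i = np.arange(pivot + 1)[:, None]
    j = np.arange(pivot + 1, len(coords))[None, :]
    d2[(j - i) < MIN_SEQ_SEP] = np.inf
    if (d2 < CLASH_DISTANCE**2).any():
        return True
    # hard-core check for the one sequence-separation-2 pair whose
    # distance the pivot changes, so conformers stay valid BeadModels
    if pivot >= 1 and len(moved):
        d = np.linalg.norm(coords[pivot - 1] - coords[pivot + 1])
        if d < BeadModel.CLASH_CUTOFF:
            return True
    return False


def generate_conformers(topology: BeadModel, n: int, seed: int = 0,
                        moves_per_snapshot: int | None = None,
                        qgrid: np.ndarray | None = None,
                        max_attempts_factor: int = 200) -> ConformerPool:
    """Sample ``n`` conformers by random pivot rotations at flexible beads.

    Each move rotates the chain C-terminal of a randomly chosen flexible
    residue about a random axis through that bead; moves creating a
    contact below 4.0 Å between the moved and unmoved segments (pairs at
    sequence separation >= 3) are rejected.  Rigid domains stay internally
    fixed since pivots act only at flexible residues.  A snapshot is taken
    every ``moves_per_snapshot`` accepted moves (default: the flexible-set
    size) so successive conformers decorrelate.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    q = DEFAULT_QGRID if qgrid is None else np.asarray(qgrid, dtype=float)
    flex_pos = [i for i, r in enumerate(topology.residues) if int(r) in topology.flexible]
    if not flex_pos:
        log.info("no flexible residues: returning %d identical copies", n)
        prof = debye_profile(topology, q)
        return ConformerPool(
            conformers=[topology.with_coords(topology.coords.copy()) for _ in range(n)],
            qgrid=q, profiles=np.tile(prof, (n, 1)),
            rgs=np.full(n, topology.rg()), seed=seed, n_proposed=0, n_accepted=0,
        )
    stride = moves_per_snapshot or len(flex_pos)
    coords = topology.coords.copy()
    conformers: list[BeadModel] = []
    proposed = accepted = 0
    max_attempts = max_attempts_factor * n * stride
    while len(conformers) < n:
        if proposed > max_attempts:
            raise RuntimeError("pivot acceptance rate too low; loosen the topology or flexible set")
        pivot = flex_pos[rng.integers(len(flex_pos))]
        axis = rng.normal(size=3)
        angle = rng.uniform(-np.pi, np.pi)
        proposed += 1
        Rm = _rotation_matrix(axis, angle)
        new = coords.copy()
        new[pivot + 1 :] = (new[pivot + 1 :] - new[pivot]) @ Rm.T + new[pivot]
        # clash check only between segments whose relative geometry changed
        if _pivot_clash(new, pivot):
            continue
        coords = new
        accepted += 1
        if accepted % stride == 0:
            conformers.append(topology.with_coords(coords.copy()))
    if proposed and accepted / proposed < 0.01:
        raise RuntimeError(f"acceptance rate {accepted / proposed:.2%} < 1 %; loosen the topology")
    log.info("pivot sampling: %d/%d moves accepted (%.0f%%)", accepted, proposed,
             100 * accepted / max(proposed, 1))
    profiles = np.array([debye_profile(c, q) for c in conformers])
    rgs = np.array([c.rg() for c in conformers])
    return ConformerPool(conformers=conformers, qgrid=q, profiles=profiles, rgs=rgs,
                         seed=seed, n_proposed=proposed, n_accepted=accepted)


def _fit_subset(pool: ConformerPool, exp: SAXSProfile, subset: tuple[int, ...],
                A_cache: np.ndarray, b: np.ndarray) -> EnsembleModel | None:
    w, _ = nnls(A_cache[:, list(subset)], b)
    if not np.any(w > 0):
        return None
    mix = w @ pool.profiles[list(subset)]
    chi, c = chi_score(exp, mix)
    keep = w > 0
    members = tuple(m for m, k in zip(subset, keep) if k)
    wk = w[keep]
    return EnsembleModel(
        n_states=len(subset), members=members, weights=wk / wk.sum(),
        chi=chi, scale=c * wk.sum(),
        member_rgs=pool.rgs[list(members)],
    )


def _rank_key(m: EnsembleModel):
    # equal chi broken by smaller N, then lexicographic members (reproducible)
    return (round(m.chi, 12), m.n_states, m.members)


def multistate_fit(pool: ConformerPool, exp: SAXSProfile, n_states: int,
                   keep: int = 1000, enumerate_limit: int = 10**6,
                   seed: int = 0, n_restarts: int = 200) -> list[EnsembleModel]:
    """Best N-state weighted ensembles ranked by χ.

    For each candidate member subset, weights are fitted by non-negative
    least squares on σ-weighted intensities and normalised (the overall
    scale folds into c).  Subsets are enumerated exhaustively when
    C(pool, N) <= ``enumerate_limit``; otherwise a seeded stochastic
    search with greedy local member swaps is used.
    """
    if not 1 <= n_states <= 5:
        raise ValueError("n_states must be in 1..5")
    if n_states > len(pool):
        raise ValueError("n_states exceeds pool size")
    if exp.q[0] < pool.qgrid[0] - 1e-12 or exp.q[-1] > pool.qgrid[-1] + 1e-12:
        raise ValueError("experimental q-range extends beyond the pool grid")
    # interpolate pool profiles onto the experimental grid once
    P = np.array([np.interp(exp.q, pool.qgrid, prof) for prof in pool.profiles])
    pool_on_exp = ConformerPool(pool.conformers, exp.q, P, pool.rgs, pool.seed)
    A = (P / exp.sigma).T  # (M, n_conformers)
    b = exp.I / exp.sigma

    results: dict[tuple[int, ...], EnsembleModel] = {}
    n_comb = math.comb(len(pool), n_states)
    if n_comb <= enumerate_limit:
        for subset in itertools.combinations(range(len(pool)), n_states):
            m = _fit_subset(pool_on_exp, exp, subset, A, b)
            if m is not None:
                results[subset] = m
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            subset = tuple(sorted(rng.choice(len(pool), size=n_states, replace=False)))
            best = _fit_subset(pool_on_exp, exp, subset, A, b)
            if best is None:
                continue
            improved = True
            while improved:
                improved = False
                for pos in range(n_states):
                    for cand in rng.choice(len(pool), size=min(50, len(pool)), replace=False):
                        if cand in subset:
                            continue
                        trial = tuple(sorted(subset[:pos] + (int(cand),) + subset[pos + 1 :]))
                        m = _fit_subset(pool_on_exp, exp, trial, A, b)
                        if m is not None and m.chi < best.chi - 1e-12:
                            best, subset, improved = m, trial, True
            results[subset] = best
    ranked = sorted(results.values(), key=_rank_key)
    return ranked[:keep]


def rg_distribution(models: list[EnsembleModel], pool: ConformerPool,
                    bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Rg histogram over a list of ensemble models.

    Each model contributes with uniform rank weight; within a model each
    member contributes its fitted weight.  Returns (bin_edges, density
    normalised to unit sum).
    """
    if not models:
        raise ValueError("empty model list")
    lo = np.floor(pool.rgs.min())
    hi = np.ceil(pool.rgs.max()) + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for m in models:
        idx = np.clip(np.searchsorted(edges, m.member_rgs, side="right") - 1, 0, len(hist) - 1)
        np.add.at(hist, idx, m.weights / len(models))
    return edges, hist
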