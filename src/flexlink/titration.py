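"""Chemical-shift-perturbation titrations and binding-isotherm fitting.

Amide CSPs are combined as Δδ = [((ΔδH)² + (ΔδN/5)²)/2]^½ and modelled
in the fast-exchange limit, where the observed perturbation is the
population-weighted average between the free state (Δδ = 0) and the
bound state (Δδ = Δδ_bound).  Two isotherms are provided:

* 1:1 — one ligand binding one protein site,
      Δδ = Δδ_b (L0+P0+Kd − √((L0+P0+Kd)² − 4 L0 P0)) / (2 P0)
* 2:1 — a bivalent ligand (e.g. Lys63-linked diubiquitin) whose two
  moieties each engage one site, so the effective ligand-site
  concentration is doubled,
      Δδ = Δδ_b (2L0+P0+Kd − √((2L0+P0+Kd)² − 8 L0 P0)) / (2 P0)

Both are monotone non-decreasing in L0 and bounded by Δδ_bound; the 2:1
curve evaluated at L0/2 equals the 1:1 curve at L0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datatypes import ShiftTable, as_float_array

log = logging.getLogger(__name__)

#: endpoint-CSP floor below which a residue is excluded from domain
#: aggregation (below typical shift-measurement precision)
DEFAULT_CSP_FLOOR = 0.02

KD_BOUNDS = (1e-12, 1e5)  # µM


def compute_csp(dH, dN):
    """Combined amide CSP (ppm) from ¹H and ¹⁵N shift changes.

    The ¹⁵N change is scaled by 1/5 to account for its larger shift
    dispersion before the root-mean-square combination.
    """
    dH = as_float_array(dH)
    dN = as_float_array(dN)
    return np.sqrt((dH**2 + (dN / 5.0) ** 2) / 2.0)


def _isotherm(Kd, dd_bound, P0, Ltot):
    # shared closed form: Ltot is the ligand-site concentration
    s = Ltot + P0 + Kd
    disc = s**2 - 4.0 * Ltot * P0
    return dd_bound * (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * P0)


def binding_curve_1to1(Kd, dd_bound, P0, L0):
    """Fast-exchange 1:1 isotherm, Δδ(L0) in ppm."""
    Kd, P0, L0 = float(Kd), np.asarray(P0, float), np.asarray(L0, float)
    if Kd < 0 or np.any(P0 <= 0) or np.any(L0 < 0):
        raise ValueError("require Kd >= 0, P0 > 0, L0 >= 0")
    return _isotherm(Kd, dd_bound, P0, L0)


def binding_curve_2to1(Kd, dd_bound, P0, L0):
    """Fast-exchange 2:1 isotherm for a bivalent ligand, Δδ(L0) in ppm."""
    Kd, P0, L0 = float(Kd), np.asarray(P0, float), np.asarray(L0, float)
    if Kd < 0 or np.any(P0 <= 0) or np.any(L0 < 0):
        raise ValueError("require Kd >= 0, P0 > 0, L0 >= 0")
    return _isotherm(Kd, dd_bound, P0, 2.0 * L0)


_MODELS = {"1to1": binding_curve_1to1, "2to1": binding_curve_2to1}


@dataclass
class TitrationSeries:
    """Combined CSPs of one residue along the ligand ladder."""

    residue: int
    csp: np.ndarray
    P0: np.ndarray
    L0: np.ndarray
    domain: str = ""


@dataclass
class ResidueFit:
    residue: int
    Kd: float
    Kd_err: float
    dd_bound: float
    dd_bound_err: float
    resnorm: float
    converged: bool
    max_csp: float
    domain: str = ""


@dataclass
class BindingFit:
    """Per-residue and per-domain isotherm-fit results.

    ``domain_kd`` maps domain label -> (mean Kd, SD across residues),
    the SD serving as the error estimate of the aggregate.
    """

    model: str
    mode: str
    residues: list[ResidueFit]
    domain_kd: dict[str, tuple[float, float]]
    excluded: list[int] = field(default_factory=list)
    broadened: list[int] = field(default_factory=list)


def series_from_table(table: ShiftTable) -> list[TitrationSeries]:
    """Turn a ShiftTable into per-residue CSP series.

    CSPs are computed relative to the ligand-free reference point.
    Residues that broaden out mid-titration are returned with their
    observed points only flagged via NaN; downstream fitting skips them.
    """
    out = []
    for res in table.residues:
        dH = table.dH.loc[res].to_numpy(float) - float(table.dH.loc[res].iloc[0])
        dN = table.dN.loc[res].to_numpy(float) - float(table.dN.loc[res].iloc[0])
        csp = np.full(table.n_points, np.nan)
        ok = np.isfinite(dH) & np.isfinite(dN)
        csp[ok] = compute_csp(dH[ok], dN[ok])
        out.append(
            TitrationSeries(
                residue=int(res),
                csp=csp,
                P0=table.P0.copy(),
                L0=table.L0.copy(),
                domain=table.domains.get(int(res), ""),
            )
        )
    return out


def _fit_one(series: TitrationSeries, model: str) -> ResidueFit:
    ok = np.isfinite(series.csp)
    csp, P0, L0 = series.csp[ok], series.P0[ok], series.L0[ok]
    curve = _MODELS[model]
    max_csp = float(np.nanmax(csp))
    # damped least squares; Kd started at the ladder median, amplitude
    # slightly above the largest observed CSP
    x0 = (max(float(np.median(L0[L0 > 0])), 1e-3), max(1.2 * max_csp, 1e-3))

    def resid(x):
        return curve(x[0], x[1], P0, L0) - csp

    try:
        sol = least_squares(
            resid, x0, bounds=([KD_BOUNDS[0], 1e-9], [KD_BOUNDS[1], np.inf]), method="trf"
        )
    except Exception:  # pragma: no cover - optimizer hard failure
        return ResidueFit(series.residue, np.nan, np.nan, np.nan, np.nan, np.inf, False, max_csp, series.domain)
    # covariance-based errors from the Jacobian at the solution
    dof = max(len(csp) - 2, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        errs = np.array([np.inf, np.inf])
    converged = bool(sol.success) and sol.x[0] < 0.99 * KD_BOUNDS[1]
    return ResidueFit(
        residue=series.residue,
        Kd=float(sol.x[0]),
        Kd_err=float(errs[0]),
        dd_bound=float(sol.x[1]),
        dd_bound_err=float(errs[1]),
        resnorm=float(np.sum(sol.fun**2)),
        converged=converged,
        max_csp=max_csp,
        domain=series.domain,
    )


def _fit_global(series_list, model):
    """Shared Kd across residues, residue-specific amplitudes."""
    curve = _MODELS[model]
    usable = [s for s in series_list if np.isfinite(s.csp).sum() >= 4]
    x0 = [max(float(np.median(usable[0].L0[usable[0].L0 > 0])), 1e-3)]
    x0 += [max(1.2 * float(np.nanmax(s.csp)), 1e-3) for s in usable]

    def resid(x):
        parts = []
        for amp, s in zip(x[1:], usable):
            ok = np.isfinite(s.csp)
            parts.append(curve(x[0], amp, s.P0[ok], s.L0[ok]) - s.csp[ok])
        return np.concatenate(parts)

    lb = [KD_BOUNDS[0]] + [1e-9] * len(usable)
    ub = [KD_BOUNDS[1]] + [np.inf] * len(usable)
    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
    npar = len(x0)
    dof = max(len(sol.fun) - npar, 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
        kd_err = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        kd_err = np.inf
    fits = []
    for i, s in enumerate(usable):
        fits.append(
            ResidueFit(
                residue=s.residue,
                Kd=float(sol.x[0]),
                Kd_err=kd_err,
                dd_bound=float(sol.x[1 + i]),
                dd_bound_err=np.nan,
                resnorm=float(np.sum(sol.fun**2)),
                converged=bool(sol.success),
                max_csp=float(np.nanmax(s.csp)),
                domain=s.domain,
            )
        )
    return fits


def fit_kd(
    series_list: list[TitrationSeries],
    model: str = "1to1",
    mode: str = "per-residue",
    csp_floor: float = DEFAULT_CSP_FLOOR,
) -> BindingFit:
    """Fit the chosen isotherm to a set of per-residue CSP series.

    In ``per-residue`` mode each residue gets its own (Kd, Δδ_bound) and
    the domain-level Kd is the mean over its residues with the SD across
    residues as the error estimate.  In ``global`` mode a single Kd is
    shared by all residues of the set, with residue-specific amplitudes.

    Residues whose endpoint CSP never exceeds ``csp_floor`` are excluded
    from aggregation (their perturbation is within measurement noise), as
    are residues whose fit fails to converge.  Residues with fewer than 4
    observed points (broadened peaks) are skipped and reported.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {sorted(_MODELS)}")
    if mode not in ("per-residue", "global"):
        raise ValueError("mode must be 'per-residue' or 'global'")

    broadened = [s.residue for s in series_list if np.isfinite(s.csp).sum() < 4]
    usable = [s for s in series_list if np.isfinite(s.csp).sum() >= 4]
    if broadened:
        log.info("excluding %d broadened residue(s) from fitting: %s", len(broadened), broadened)

    if mode == "global":
        fits = _fit_global(usable, model)
    else:
        fits = [_fit_one(s, model) for s in usable]

    excluded = [f.residue for f in fits if f.max_csp < csp_floor or not f.converged]
    kept = [f for f in fits if f.residue not in excluded]

    domain_kd: dict[str, tuple[float, float]] = {}
    for dom in sorted({f.domain for f in kept}):
        kds = np.array([f.Kd for f in kept if f.domain == dom])
        if len(kds) < 2:
            raise RuntimeError(f"fewer than 2 usable residues in domain {dom!r}")
        domain_kd[dom] = (float(kds.mean()), float(kds.std(ddof=1)))

    return BindingFit(model=model, mode=mode, residues=fits, domain_kd=domain_kd,
                      excluded=excluded, broadened=broadened)


def csp_significance(series_list: list[TitrationSeries], threshold: float = 0.4) -> dict[str, list[int]]:
    """Residues whose endpoint CSP meets the significance threshold (ppm).

    The boundary is inclusive; results are grouped per domain.  Broadened
    residues use their last observed point.
    """
    out: dict[str, list[int]] = {}
    for s in series_list:
        finite = s.csp[np.isfinite(s.csp)]
        if len(finite) == 0:
            continue
        if finite[-1] >= threshold:
            out.setdefault(s.domain, []).append(s.residue)
    return out
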