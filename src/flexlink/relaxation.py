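"""¹⁵N spin relaxation: rate extraction, reduced spectral density mapping,
per-domain correlation times, and the R₂-vs-mass "molecular ruler".

The relaxation of a backbone amide ¹⁵N is driven by the ¹H–¹⁵N dipolar
interaction and the ¹⁵N chemical-shift anisotropy.  With the dipolar
strength d = (μ0/4π) ħ γH γN / rNH³ and the CSA strength c = ΔσN ωN/√3,
the standard expressions are

    R1  = (d²/4) [J(ωH−ωN) + 3 J(ωN) + 6 J(ωH+ωN)] + c² J(ωN)
    R2  = (d²/8) [4 J(0) + J(ωH−ωN) + 3 J(ωN) + 6 J(ωH) + 6 J(ωH+ωN)]
          + (c²/6) [4 J(0) + 3 J(ωN)]
    σNH = (d²/4) [6 J(ωH+ωN) − J(ωH−ωN)],   NOE = 1 + (γH/γN) σNH / R1

Reduced spectral density mapping collapses the high-frequency terms onto
a single effective frequency 0.87 ωH, after which (R1, R2, σNH) and
(J(0), J(ωN), J(0.87ωH)) are related by an exactly invertible 3×3 linear
system; no assumption about the rotational-diffusion model is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit

from .datatypes import IntensityTable, RelaxationRecord, SpectralDensities

log = logging.getLogger(__name__)

MU0_OVER_4PI = 1e-7  # T·m/A
HBAR = 1.054571817e-34  # J·s
GAMMA_H = 2.6752218744e8  # rad s⁻¹ T⁻¹
GAMMA_N = -2.7126e7  # rad s⁻¹ T⁻¹ (negative gyromagnetic ratio)


@dataclass(frozen=True)
class PhysicalConstantsSet:
    """Interaction strengths of the ¹⁵N relaxation mechanisms.

    rNH (Å) and ΔσN (ppm) default to the standard backbone-amide values
    1.02 Å and −160 ppm.  ``d2`` and ``c2`` are the squared dipolar and
    CSA strengths (rad²/s²) entering the rate expressions; c² scales with
    the square of the field.
    """

    field_mhz: float = 600.0
    rNH: float = 1.02
    delta_sigma_N: float = -160.0

    @property
    def omega_H(self) -> float:
        return 2 * np.pi * self.field_mhz * 1e6

    @property
    def omega_N(self) -> float:
        # ¹⁵N Larmor frequency (magnitude) at the same field
        return self.omega_H * abs(GAMMA_N) / GAMMA_H

    @property
    def d2(self) -> float:
        d = MU0_OVER_4PI * HBAR * GAMMA_H * abs(GAMMA_N) / (self.rNH * 1e-10) ** 3
        return d * d

    @property
    def c2(self) -> float:
        c = self.delta_sigma_N * 1e-6 * self.omega_N / np.sqrt(3.0)
        return c * c


def lorentzian_j(omega: np.ndarray, tau_c: float) -> np.ndarray:
    """Rigid isotropic spectral density J(ω) = (2/5) τc / (1 + (ωτc)²)."""
    return 0.4 * tau_c / (1.0 + (omega * tau_c) ** 2)


def lipari_szabo_j(omega, tau_c: float, S2: float, tau_e: float):
    """Model-free spectral density with order parameter S² and internal
    correlation time τe (1/τ' = 1/τc + 1/τe).  All times in seconds."""
    omega = np.asarray(omega, dtype=float)
    j = S2 * tau_c / (1.0 + (omega * tau_c) ** 2)
    if tau_e > 0 and S2 < 1.0:
        tp = 1.0 / (1.0 / tau_c + 1.0 / tau_e)
        j = j + (1.0 - S2) * tp / (1.0 + (omega * tp) ** 2)
    return 0.4 * j


def rates_from_j(jfunc, constants: PhysicalConstantsSet):
    """Forward-compute (R1, R2, NOE) from a spectral density function.

    Uses the full five-frequency expressions; ``jfunc`` maps ω (rad/s)
    to J(ω) (s/rad).
    """
    wH, wN = constants.omega_H, constants.omega_N
    d2, c2 = constants.d2, constants.c2
    JmHN, JN, JH, JpHN, J0 = jfunc(np.array([wH - wN, wN, wH, wH + wN, 0.0]))
    R1 = (d2 / 4.0) * (JmHN + 3 * JN + 6 * JpHN) + c2 * JN
    R2 = (d2 / 8.0) * (4 * J0 + JmHN + 3 * JN + 6 * JH + 6 * JpHN) + (c2 / 6.0) * (4 * J0 + 3 * JN)
    sigma = (d2 / 4.0) * (6 * JpHN - JmHN)
    NOE = 1.0 + (GAMMA_H / GAMMA_N) * sigma / R1
    return float(R1), float(R2), float(NOE)


def rates_from_reduced_j(J0: float, JwN: float, JwH: float, constants: PhysicalConstantsSet):
    """Forward model of the reduced mapping (high-frequency terms collapsed
    onto 0.87 ωH); exact inverse of :func:`reduced_sdm`."""
    d2, c2 = constants.d2, constants.c2
    R1 = (d2 / 4.0) * (3 * JwN + 7 * JwH) + c2 * JwN
    R2 = (d2 / 8.0) * (4 * J0 + 3 * JwN + 13 * JwH) + (c2 / 6.0) * (4 * J0 + 3 * JwN)
    sigma = (d2 / 4.0) * 5.0 * JwH
    NOE = 1.0 + (GAMMA_H / GAMMA_N) * sigma / R1
    return float(R1), float(R2), float(NOE)


def reduced_sdm(rec: RelaxationRecord, constants: PhysicalConstantsSet | None = None) -> SpectralDensities:
    """Map (R1, R2, NOE) to J(0), J(ωN), J(0.87ωH) by exact inversion
    of the reduced linear system (Rex assumed zero).

    A negative J(0) is physically impossible for pure dipolar/CSA
    relaxation and signals conformational exchange or noise; the value is
    returned as computed but flagged.
    """
    constants = constants or PhysicalConstantsSet(field_mhz=rec.field_mhz)
    d2, c2 = constants.d2, constants.c2
    sigma = rec.R1 * (rec.NOE - 1.0) * GAMMA_N / GAMMA_H
    JwH = 4.0 * sigma / (5.0 * d2)
    JwN = (rec.R1 - (7.0 * d2 / 4.0) * JwH) / (3.0 * d2 / 4.0 + c2)
    J0 = (rec.R2 - (d2 / 8.0) * (3 * JwN + 13 * JwH) - (c2 / 2.0) * JwN) / (d2 / 2.0 + 2.0 * c2 / 3.0)
    flagged = J0 < 0
    if flagged:
        log.warning("residue %d: negative J(0) = %.3g (exchange or noise)", rec.residue, J0)
    return SpectralDensities(residue=rec.residue, J0=float(J0), JwN=float(JwN), JwH=float(JwH), flagged=bool(flagged))


@dataclass
class RateFit:
    residue: int
    rate: float
    rate_err: float
    I0: float
    determined: bool


def fit_exponential(delays: np.ndarray, intensities: np.ndarray, residue: int = 0) -> RateFit:
    """Two-parameter monoexponential fit I(t) = I0 exp(−R t).

    The error is taken from the fit covariance.  A non-decaying series
    (non-positive fitted rate) is flagged as not-determined.
    """
    delays = np.asarray(delays, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if len(np.unique(delays)) < 5:
        raise ValueError("need >= 5 distinct delays")
    if intensities[np.argmin(delays)] <= 0:
        raise ValueError("intensity at shortest delay must be positive")
    # log-linear initial guess on positive points
    pos = intensities > 0
    slope, icpt = np.polyfit(delays[pos], np.log(intensities[pos]), 1)
    if slope >= 0:
        return RateFit(residue, np.nan, np.nan, float(np.exp(icpt)), determined=False)
    p0 = (float(np.exp(icpt)), float(-slope))
    try:
        popt, pcov = curve_fit(lambda t, I0, R: I0 * np.exp(-R * t), delays, intensities, p0=p0, maxfev=5000)
    except RuntimeError:
        return RateFit(residue, np.nan, np.nan, p0[0], determined=False)
    if popt[1] <= 0:
        return RateFit(residue, float(popt[1]), np.nan, float(popt[0]), determined=False)
    err = float(np.sqrt(max(pcov[1, 1], 0.0)))
    return RateFit(residue, float(popt[1]), err, float(popt[0]), determined=True)


def compute_noe(I_sat, I_ref, sigma_sat: float = 0.0, sigma_ref: float = 0.0):
    """Steady-state heteronuclear NOE = I_sat / I_ref, with its error
    propagated in quadrature from the two intensity errors."""
    I_sat, I_ref = float(I_sat), float(I_ref)
    if I_ref == 0:
        raise ValueError("reference intensity must be non-zero")
    noe = I_sat / I_ref
    err = abs(noe) * np.sqrt(
        (sigma_sat / I_sat) ** 2 + (sigma_ref / I_ref) ** 2
    ) if I_sat != 0 else abs(sigma_sat / I_ref)
    return noe, float(err)


def records_from_tables(
    r1_table: IntensityTable,
    r2_table: IntensityTable,
    noe_sat: IntensityTable,
    noe_ref: IntensityTable,
    domains: dict[int, str] | None = None,
) -> list[RelaxationRecord]:
    """Extract per-residue R1, R2 and NOE from intensity tables.

    Residues must be present in all four tables; NOE errors derive from
    the root-mean-square fit residuals of the rate experiments used as a
    proxy for the intensity noise floor.
    """
    domains = domains or {}
    common = sorted(set(r1_table.residues) & set(r2_table.residues) & set(noe_sat.residues) & set(noe_ref.residues))
    ix1, ix2, ixs, ixr = ({int(r): i for i, r in enumerate(t.residues)}
                          for t in (r1_table, r2_table, noe_sat, noe_ref))
    out = []
    for res in common:
        f1 = fit_exponential(r1_table.delays, r1_table.intensities[ix1[res]], res)
        f2 = fit_exponential(r2_table.delays, r2_table.intensities[ix2[res]], res)
        if not (f1.determined and f2.determined):
            log.warning("residue %d: rate not determined, skipping", res)
            continue
        isat = float(noe_sat.intensities[ixs[res]][0])
        iref = float(noe_ref.intensities[ixr[res]][0])
        noise = 0.02 * abs(iref)  # nominal 2 % intensity noise floor
        noe, noe_err = compute_noe(isat, iref, noise, noise)
        out.append(
            RelaxationRecord(
                residue=res, R1=f1.rate, R1_err=f1.rate_err, R2=f2.rate, R2_err=f2.rate_err,
                NOE=noe, NOE_err=noe_err, field_mhz=r1_table.field_mhz,
                domain=domains.get(res, ""),
            )
        )
    return out


def _r2_over_r1(tau_c: float, constants: PhysicalConstantsSet) -> float:
    R1, R2, _ = rates_from_j(lambda w: lorentzian_j(w, tau_c), constants)
    return R2 / R1


def tau_c_from_ratio(R2_over_R1: float, constants: PhysicalConstantsSet,
                     bounds_ns: tuple[float, float] = (0.5, 50.0)) -> float:
    """Invert the rigid-Lorentzian R2/R1 ratio to a correlation time (ns)
    by bisection; the ratio is monotone increasing in τc."""
    lo, hi = bounds_ns
    f = lambda tc_ns: _r2_over_r1(tc_ns * 1e-9, constants) - R2_over_R1
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"R2/R1 = {R2_over_R1:.2f} outside invertible range for τc in {bounds_ns} ns")
    return brentq(f, lo, hi, xtol=1e-6)


def estimate_tau_c(
    records: list[RelaxationRecord],
    domain: str | None = None,
    noe_cutoff: float = 0.65,
    trim_fraction: float = 0.10,
    constants: PhysicalConstantsSet | None = None,
) -> tuple[float, float]:
    """Per-domain rotational correlation time (ns) from R2/R1 ratios.

    Flexible residues (NOE < ``noe_cutoff``) are removed first, then the
    ``trim_fraction`` of residues with the most extreme R2/R1 relative to
    the median; each survivor's ratio is inverted individually and the
    trimmed mean ± SD is returned.  Requires >= 5 residues after trimming.
    """
    recs = [r for r in records if domain is None or r.domain == domain]
    rigid = [r for r in recs if r.NOE >= noe_cutoff]
    if not rigid:
        raise RuntimeError(f"no rigid residues (NOE >= {noe_cutoff}) in domain {domain!r}")
    ratios = np.array([r.R2 / r.R1 for r in rigid])
    med = np.median(ratios)
    n_drop = int(np.floor(trim_fraction * len(ratios)))
    keep_idx = np.argsort(np.abs(ratios - med))[: len(ratios) - n_drop] if n_drop else np.arange(len(ratios))
    kept = ratios[keep_idx]
    if len(kept) < 5:
        raise RuntimeError(f"only {len(kept)} residues left after trimming; need >= 5")
    constants = constants or PhysicalConstantsSet(field_mhz=rigid[0].field_mhz)
    taus = np.array([tau_c_from_ratio(r, constants) for r in kept])
    return float(taus.mean()), float(taus.std(ddof=1))


@dataclass
class RulerResult:
    slope: float
    intercept: float
    predicted_R2: float
    residual_rms: float
    extrapolated: bool


def molecular_ruler(calibrants: list[tuple[float, float]], query_mass: float) -> RulerResult:
    """Least-squares line R2 = a·mass + b through >= 3 calibrant proteins.

    R2 scales roughly linearly with molecular mass in this size regime, so
    the line serves as a "molecular ruler": a domain whose observed R2 sits
    above the prediction for its mass tumbles slower than an isolated
    protein of that size (domain coupling).  Queries outside the calibrant
    mass range are flagged as extrapolations.
    """
    if len(calibrants) < 3:
        raise ValueError("need >= 3 calibrants")
    mass = np.array([m for m, _ in calibrants], dtype=float)
    r2 = np.array([r for _, r in calibrants], dtype=float)
    a, b = np.polyfit(mass, r2, 1)
    resid = r2 - (a * mass + b)
    extrapolated = not (mass.min() <= query_mass <= mass.max())
    if extrapolated:
        log.warning("query mass %.1f kDa outside calibrant range [%.1f, %.1f]", query_mass, mass.min(), mass.max())
    return RulerResult(
        slope=float(a), intercept=float(b),
        predicted_R2=float(a * query_mass + b),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        extrapolated=extrapolated,
    )
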