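"""SAXS analysis: concentration-series merging, Guinier fits,
dimensionless Kratky representation, and indirect Fourier inversion to
the pair-distance distribution P(r).

The Guinier law I(q) ≈ I(0) exp(−q²Rg²/3) holds for qRg ≲ 1.3; Rg and
I(0) follow from a weighted linear fit of ln I versus q².  In the
dimensionless Kratky representation (qRg)² I(q)/I(0) versus qRg, an
ideal globular particle peaks at height 3/e ≈ 1.104 at qRg = √3,
whereas disordered chains rise monotonically — a scale-free flexibility
diagnostic.  P(r) is recovered by regularised inversion of
I(q) = 4π ∫ P(r) sin(qr)/(qr) dr with P(0) = P(Dmax) = 0 and P ≥ 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .datatypes import SAXSProfile

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- merging

def merge_profiles(low_c: SAXSProfile, high_c: SAXSProfile,
                   overlap: tuple[float, float]) -> SAXSProfile:
    """Merge a low- and a high-concentration curve of the same sample.

    The high-c curve (better high-q statistics) is scaled onto the low-c
    curve (artifact-free low q) by least squares over the stated overlap
    q-window; the merged curve takes low-c points below the overlap
    midpoint and scaled high-c points above it.
    """
    qlo, qhi = overlap
    in_lo = (low_c.q >= qlo) & (low_c.q <= qhi)
    in_hi = (high_c.q >= qlo) & (high_c.q <= qhi)
    if in_lo.sum() < 10 or in_hi.sum() < 10:
        raise ValueError("overlap window must contain >= 10 points of each curve")
    # interpolate high-c onto the low-c grid inside the overlap
    hi_on_lo = np.interp(low_c.q[in_lo], high_c.q, high_c.I)
    w = 1.0 / low_c.sigma[in_lo] ** 2
    scale = float(np.sum(w * low_c.I[in_lo] * hi_on_lo) / np.sum(w * hi_on_lo**2))
    mid = 0.5 * (qlo + qhi)
    keep_lo = low_c.q <= mid
    keep_hi = high_c.q > mid
    q = np.concatenate([low_c.q[keep_lo], high_c.q[keep_hi]])
    I = np.concatenate([low_c.I[keep_lo], scale * high_c.I[keep_hi]])
    s = np.concatenate([low_c.sigma[keep_lo], scale * high_c.sigma[keep_hi]])
    order = np.argsort(q)
    log.info("merged profiles with scale %.4g at q = %.3f", scale, mid)
    return SAXSProfile(q[order], I[order], s[order], label=f"{low_c.label}+{high_c.label} merged")


# ---------------------------------------------------------------- Guinier

@dataclass
class GuinierResult:
    Rg: float
    Rg_err: float
    I0: float
    I0_err: float
    qmin_Rg: float
    qmax_Rg: float
    n_points: int
    n_dropped_low_q: int
    residual_runs_z: float  # runs-test z of fit residuals (trend diagnostic)


def _runs_z(resid: np.ndarray) -> float:
    """Wald–Wolfowitz runs-test z statistic of the residual signs.

    A large negative z means too few sign runs, i.e. systematic curvature.
    """
    s = np.sign(resid)
    s = s[s != 0]
    n1, n2 = int((s > 0).sum()), int((s < 0).sum())
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int((np.diff(s) != 0).sum())
    mu = 1 + 2 * n1 * n2 / (n1 + n2)
    var = 2 * n1 * n2 * (2 * n1 * n2 - n1 - n2) / ((n1 + n2) ** 2 * (n1 + n2 - 1))
    return float((runs - mu) / np.sqrt(var)) if var > 0 else 0.0


def _weighted_linfit(x, y, w):
    W = np.sum(w)
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (x - xm) ** 2)
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    icpt = ym - slope * xm
    resid = y - (slope * x + icpt)
    dof = max(len(x) - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    return slope, icpt, np.sqrt(s2 / sxx), np.sqrt(s2 * (1.0 / W + xm**2 / sxx)), resid


def guinier_fit(p: SAXSProfile, qRg_max: float = 1.3, min_points: int = 8) -> GuinierResult:
    """Self-consistent Guinier fit over the largest low-q window with
    qmax·Rg <= ``qRg_max``.

    ln I is fit against q² with weights (I/σ)²; the window is iterated
    until the implied Rg and the window bound agree.  Leading points are
    dropped (and counted) while the runs statistic of the residuals
    signals curvature, which absorbs beam-stop-like artifacts.
    """
    pos = p.I > 0
    q, I, s = p.q[pos], p.I[pos], p.sigma[pos]
    if pos.sum() < min_points:
        raise ValueError("too few positive-intensity points for Guinier fit")

    def fit_window(i0: int):
        # iterate the qmax*Rg <= bound window to self-consistency
        hi = len(q)
        for _ in range(50):
            qq, yy = q[i0:hi] ** 2, np.log(I[i0:hi])
            ww = (I[i0:hi] / s[i0:hi]) ** 2
            if hi - i0 < min_points:
                return None
            slope, icpt, serr, ierr, resid = _weighted_linfit(qq, yy, ww)
            if slope >= 0:
                raise ValueError("non-negative Guinier slope (aggregation-like upturn)")
            rg = np.sqrt(-3.0 * slope)
            new_hi = int(np.searchsorted(q, qRg_max / rg, side="right"))
            new_hi = max(new_hi, i0 + min_points)
            new_hi = min(new_hi, len(q))
            if new_hi == hi:
                return slope, icpt, serr, ierr, resid, hi, rg
            hi = new_hi
        return slope, icpt, serr, ierr, resid, hi, rg

    i0 = 0
    result = fit_window(i0)
    if result is None:
        raise ValueError("no self-consistent Guinier window")
    # drop leading points while curvature is flagged (runs z < -2)
    while i0 < 10:
        slope, icpt, serr, ierr, resid, hi, rg = result
        if _runs_z(resid) >= -2.0:
            break
        nxt = fit_window(i0 + 1)
        if nxt is None:
            break
        i0 += 1
        result = nxt
    slope, icpt, serr, ierr, resid, hi, rg = result
    # shrink the high-q side while systematic curvature persists: when the
    # data deviate from the Guinier law inside the nominal qRg bound (e.g.
    # compact spheres), the runs statistic stays negative until the window
    # is small enough that noise dominates the residuals
    while hi - i0 > min_points and _runs_z(resid) < -2.0:
        hi = max(i0 + min_points, i0 + int(0.9 * (hi - i0)))
        qq, yy = q[i0:hi] ** 2, np.log(I[i0:hi])
        ww = (I[i0:hi] / s[i0:hi]) ** 2
        slope, icpt, serr, ierr, resid = _weighted_linfit(qq, yy, ww)
        if slope >= 0:
            raise ValueError("non-negative Guinier slope (aggregation-like upturn)")
        rg = np.sqrt(-3.0 * slope)
    if i0:
        log.info("Guinier: dropped %d leading point(s) for curvature", i0)
    I0 = float(np.exp(icpt))
    return GuinierResult(
        Rg=float(rg),
        Rg_err=float(3.0 * serr / (2.0 * rg)),
        I0=I0,
        I0_err=float(I0 * ierr),
        qmin_Rg=float(q[i0] * rg),
        qmax_Rg=float(q[hi - 1] * rg),
        n_points=int(hi - i0),
        n_dropped_low_q=i0,
        residual_runs_z=_runs_z(resid),
    )


# ---------------------------------------------------------------- Kratky

@dataclass
class KratkyCurve:
    x: np.ndarray  # qRg
    y: np.ndarray  # (qRg)^2 I/I0
    peak_x: float | None
    peak_y: float | None

    @property
    def has_interior_peak(self) -> bool:
        return self.peak_x is not None


def dimensionless_kratky(p: SAXSProfile, g: GuinierResult) -> KratkyCurve:
    """Dimensionless Kratky transform (qRg)² I(q)/I(0) versus qRg.

    The interior maximum (if any) is located on the grid and refined by
    parabolic interpolation through its three surrounding samples.  The
    transform is parameter-free: any curve in the Guinier regime maps to
    the universal peak (√3, 3/e) regardless of Rg and I(0).
    """
    x = p.q * g.Rg
    y = x**2 * p.I / g.I0
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return KratkyCurve(x, y, None, None)  # monotone: disordered-limit shape
    # parabolic vertex through (x[i-1..i+1], y[i-1..i+1])
    x0, x1, x2 = x[i - 1 : i + 2]
    y0, y1, y2 = y[i - 1 : i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        return KratkyCurve(x, y, float(x[i]), float(y[i]))
    px = -b / (2 * a)
    c = y1 - a * x1**2 - b * x1
    return KratkyCurve(x, y, float(px), float(a * px**2 + b * px + c))


# ---------------------------------------------------------------- P(r)

@dataclass
class PofR:
    r: np.ndarray
    P: np.ndarray
    Dmax: float
    Rg_real: float
    I0_real: float
    lambda_used: float
    chi: float  # back-fit chi against the input profile


def _fourier_kernel(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Trapezoid-integrated kernel T with I(q) = T @ P on the r grid."""
    qr = np.outer(q, r)
    sinc = np.ones_like(qr)
    nz = qr != 0
    sinc[nz] = np.sin(qr[nz]) / qr[nz]
    w = np.full(len(r), r[1] - r[0])
    w[0] *= 0.5
    w[-1] *= 0.5
    return 4.0 * np.pi * sinc * w[None, :]


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def _solve_pofr(p: SAXSProfile, Dmax: float, lam: float, n_r: int):
    r = np.linspace(0.0, Dmax, n_r)
    T = _fourier_kernel(p.q, r)
    # endpoint constraints: P(0) = P(Dmax) = 0 -> solve interior only
    Ti = T[:, 1:-1] / p.sigma[:, None]
    b = p.I / p.sigma
    D = _second_difference(n_r)[:, 1:-1]
    A = np.vstack([Ti, np.sqrt(lam) * D])
    rhs = np.concatenate([b, np.zeros(D.shape[0])])
    try:
        sol, _ = nnls(A, rhs, maxiter=50 * A.shape[1])
    except RuntimeError:  # active-set cycling at extreme λ; robust fallback
        from scipy.optimize import lsq_linear
        sol = np.maximum(lsq_linear(A, rhs, bounds=(0.0, np.inf)).x, 0.0)
    P = np.zeros(n_r)
    P[1:-1] = sol
    model = T @ P
    chi = float(np.sqrt(np.mean(((p.I - model) / p.sigma) ** 2)))
    rough = float(np.sum((D @ sol) ** 2))
    return r, P, chi, rough


def _lcurve_lambda(p: SAXSProfile, Dmax: float, n_r: int) -> float:
    """Pick λ at the corner of the (log residual, log roughness) L-curve,
    by maximum distance from the chord between the extreme points."""
    lams = np.logspace(-8, 2, 21) * len(p) / n_r
    pts = []
    for lam in lams:
        _, _, chi, rough = _solve_pofr(p, Dmax, lam, n_r)
        pts.append((np.log10(max(chi, 1e-12)), np.log10(max(rough, 1e-30))))
    pts = np.array(pts)
    a, bpt = pts[0], pts[-1]
    chord = bpt - a
    nrm = np.linalg.norm(chord)
    if nrm == 0:
        return float(lams[len(lams) // 2])
    # signed distance of each point from the chord
    d = (chord[0] * (pts[:, 1] - a[1]) - chord[1] * (pts[:, 0] - a[0])) / nrm
    return float(lams[int(np.argmax(np.abs(d)))])


def pofr_invert(p: SAXSProfile, Dmax: float, lam: float | None = None,
                n_r: int = 101) -> PofR:
    """Regularised indirect Fourier transform of I(q) to P(r).

    Minimises ||(I − T·P)/σ||² + λ||Δ²P||² subject to P >= 0 and
    P(0) = P(Dmax) = 0, with T the trapezoid-integrated Fourier kernel
    4π sin(qr)/(qr).  λ defaults to an L-curve corner choice.  Rg and
    I(0) are recomputed from the moments of P:  I(0) = 4π∫P dr and
    Rg² = ∫r²P dr / (2∫P dr).
    """
    if Dmax <= 0:
        raise ValueError("Dmax must be positive")
    if p.q[0] > np.pi / Dmax:
        log.warning("qmin = %.4g exceeds π/Dmax = %.4g; low-r features underdetermined", p.q[0], np.pi / Dmax)
    if lam is None:
        lam = _lcurve_lambda(p, Dmax, n_r)
    r, P, chi, _ = _solve_pofr(p, Dmax, lam, n_r)
    integral = np.trapezoid(P, r)
    if integral <= 0:
        raise RuntimeError("P(r) inversion collapsed to zero; try adjusting λ in [1e-6, 1e2]")
    Rg_real = float(np.sqrt(np.trapezoid(r**2 * P, r) / (2.0 * integral)))
    return PofR(r=r, P=P, Dmax=float(Dmax), Rg_real=Rg_real,
                I0_real=float(4.0 * np.pi * integral), lambda_used=float(lam), chi=chi)


@dataclass
class DmaxScan:
    Dmax: float
    candidates: np.ndarray
    chis: np.ndarray
    plateau_chi: float
    warning: str | None


def dmax_scan(p: SAXSProfile, candidates, lam: float | None = None,
              n_r: int = 101, plateau_tol: float = 0.05) -> DmaxScan:
    """Choose Dmax as the smallest candidate whose back-fit χ is within
    ``plateau_tol`` of the large-Dmax plateau.

    The plateau is the median χ over the upper half of the candidate
    list.  If no candidate reaches it, the widest candidate is returned
    with a warning (the true Dmax likely exceeds the scanned range).
    """
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if len(candidates) < 5:
        raise ValueError("need >= 5 candidate Dmax values")
    if lam is None:
        lam = _lcurve_lambda(p, float(candidates[-1]), n_r)
    chis = np.array([_solve_pofr(p, float(d), lam, n_r)[2] for d in candidates])
    plateau = float(np.median(chis[len(chis) // 2 :]))
    ok = chis <= plateau * (1.0 + plateau_tol)
    warning = None
    # chi still falling steeply at the widest candidate: the scanned range
    # likely ends below the true Dmax
    if (np.all(np.diff(chis[-3:]) < 0)
            and chis[-3] - chis[-1] > plateau_tol * (chis[-1] + 1e-12)):
        warning = "chi still decreasing at the widest candidate; scanned range may end below the true Dmax"
        log.warning(warning)
    if not ok.any():
        warning = "no candidate reached the chi plateau; true Dmax may exceed the scanned range"
        log.warning(warning)
        best = float(candidates[-1])
    else:
        best = float(candidates[int(np.argmax(ok))])
    return DmaxScan(Dmax=best, candidates=candidates, chis=chis, plateau_chi=plateau, warning=warning)


# ------------------------------------------------------- analytic oracles

def sphere_intensity(q, R: float, I0: float = 1.0):
    """Closed-form scattering of a homogeneous sphere of radius R."""
    q = np.asarray(q, dtype=float)
    qR = q * R
    amp = 3.0 * (np.sin(qR) - qR * np.cos(qR)) / qR**3
    return I0 * amp**2


def sphere_pofr(r, R: float):
    """Closed-form distance distribution of a homogeneous sphere,
    p(r) ∝ r²(1 − 3r/(4R) + r³/(16R³)) for 0 <= r <= 2R."""
    r = np.asarray(r, dtype=float)
    x = r / R
    p = r**2 * (1.0 - 0.75 * x + x**3 / 16.0)
    return np.where((r >= 0) & (r <= 2 * R), p, 0.0)
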