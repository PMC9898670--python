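"""Model-free analysis of scattering curves and melting curves.

Guinier analysis fits ln I = ln I(0) - Rg^2 Q^2 / 3 at low angle (valid for
Q*Rg up to ~1.3) to give the radius of gyration and forward intensity.  The
pair-distance distribution P(r) is obtained either from a curve by a
regularised indirect Fourier transform (non-negative P on [0, Dmax] with a
second-difference smoothness penalty, the regularisation weight chosen by an
L-curve corner search) or directly from a sphere model as a radius-convolved
pairwise distance histogram.  P(r) yields the real-space Rg, the maximum
dimension L (where P(r) falls to zero -- operationally, below 1% of its peak)
and the most common distance M (the P(r) mode).

Thermal melts of triple helices are analysed as two-state transitions with
linear folded and unfolded baselines: the fraction folded is
F(T) = (signal - unfolded)/(folded - unfolded) and the melting temperature
T_m is where F crosses 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, nnls

from .scattering import ScatteringCurve

__all__ = [
    "GuinierFit", "DistanceDistribution", "MeltingCurve",
    "guinier_fit", "pr_from_curve", "pr_from_model", "melting_analysis",
    "pr_forward_transform",
]

QRG_LIMIT = 1.3


@dataclass(frozen=True)
class GuinierFit:
    rg: float                  # nm
    i0: float
    q_range: tuple[float, float]
    max_qrg: float
    residual_rms: float        # rms of ln I residuals

    def __post_init__(self):
        if self.rg <= 0:
            raise ValueError("Guinier fit produced non-positive Rg")


@dataclass
class DistanceDistribution:
    r: np.ndarray              # nm
    p: np.ndarray              # density, >= 0, arbitrary normalisation
    length: float              # L, nm: support end (P below 1% of peak)
    span: float                # geometric maximum extent, nm
    mode: float                # M, nm: r at the P(r) peak
    rg_real: float             # nm, from the second moment of P

    def __post_init__(self):
        if np.any(self.p < -1e-9):
            raise ValueError("P(r) must be non-negative")


@dataclass
class MeltingCurve:
    temperature: np.ndarray    # C, strictly increasing
    signal: np.ndarray         # ellipticity, arbitrary units
    label: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal must have equal length")


# ---------------------------------------------------------------------------
# Guinier
# ---------------------------------------------------------------------------

def _guinier_wls(q, i, sigma):
    x = q ** 2
    y = np.log(i)
    w = np.ones_like(y) if sigma is None else (i / sigma) ** 2
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    resid = y - (slope * x + intercept)
    return slope, intercept, float(np.sqrt(np.mean(resid ** 2)))


def guinier_fit(curve: ScatteringCurve,
                q_range: tuple[float, float] | None = None) -> GuinierFit:
    """Guinier fit of ln I vs Q^2 (weighted when uncertainties are present).

    With an explicit ``q_range`` the fit uses exactly that window.  Otherwise
    the largest low-Q window with max(Q)*Rg <= 1.3 is found by fixed-point
    iteration (at most 20 rounds, convergence 0.01 on Q*Rg).
    """
    if q_range is not None:
        sub = curve.crop(*q_range)
        if len(sub.q) < 5:
            raise ValueError(f"fewer than 5 points in Q range {q_range}")
        if np.any(sub.i <= 0):
            raise ValueError("non-positive intensities in the Guinier range")
        slope, intercept, rms = _guinier_wls(sub.q, sub.i, sub.sigma)
        if slope >= 0:
            raise ValueError("Guinier fit has non-negative slope (no decay)")
        rg = float(np.sqrt(-3.0 * slope))
        return GuinierFit(rg, float(np.exp(intercept)),
                          (float(sub.q[0]), float(sub.q[-1])),
                          float(sub.q[-1] * rg), rms)

    pos = curve.i > 0
    q, i = curve.q[pos], curve.i[pos]
    sig = None if curve.sigma is None else curve.sigma[pos]
    if len(q) < 5:
        raise ValueError("fewer than 5 positive-intensity points")
    qmax = q[min(9, len(q) - 1)]
    last_qrg = np.inf
    for _ in range(20):
        m = q <= qmax
        if m.sum() < 5:
            m = np.zeros_like(q, dtype=bool)
            m[:5] = True
        slope, intercept, rms = _guinier_wls(q[m], i[m],
                                             None if sig is None else sig[m])
        if slope >= 0:
            # noisy window too short to see the decay: widen and retry
            if qmax < q[-1]:
                qmax = min(2.0 * qmax, q[-1])
                continue
            raise ValueError("Guinier auto-range failed: non-decaying curve")
        rg = float(np.sqrt(-3.0 * slope))
        qrg = q[m][-1] * rg
        if abs(qrg - QRG_LIMIT) < 0.01 or abs(qrg - last_qrg) < 1e-4:
            break
        last_qrg = qrg
        qmax = QRG_LIMIT / rg
    else:
        raise ValueError("Guinier auto-range did not converge in 20 iterations")
    qs = q[m]
    return GuinierFit(rg, float(np.exp(intercept)),
                      (float(qs[0]), float(qs[-1])), float(qs[-1] * rg), rms)


# ---------------------------------------------------------------------------
# P(r) by regularised indirect transform
# ---------------------------------------------------------------------------

def pr_forward_transform(r: np.ndarray, p: np.ndarray,
                         q: np.ndarray) -> np.ndarray:
    """I(Q) = integral P(r) sinc(Qr) dr (Debye kernel, trapezoid rule)."""
    qr = np.outer(q, r)
    kern = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)
    w = np.gradient(r)
    return kern @ (p * w)


def _solve_pr(kern_w, i_obs, w_exp, alpha, nr):
    d2 = np.zeros((nr - 2, nr))
    for k in range(nr - 2):
        d2[k, k:k + 3] = (1.0, -2.0, 1.0)
    a_stack = np.vstack([w_exp[:, None] * kern_w, alpha * d2])
    b_stack = np.concatenate([w_exp * i_obs, np.zeros(nr - 2)])
    p, _ = nnls(a_stack, b_stack)
    return p


def pr_from_curve(curve: ScatteringCurve, dmax: float, alpha: float | None = None,
                  nr: int = 101) -> DistanceDistribution:
    """P(r) from a scattering curve by regularised indirect transform.

    P is represented on ``nr`` points of [0, Dmax] with P(0) = P(Dmax) = 0 and
    P >= 0, fitted to the curve through the Debye kernel with a
    second-difference smoothness penalty.  When ``alpha`` is omitted it is
    chosen by an L-curve corner search over a fixed logarithmic grid.
    Raises when Dmax is clearly too small (the misfit blows up).
    """
    if dmax <= 0:
        raise ValueError("Dmax must be positive")
    if curve.q[-1] * dmax < np.pi:
        raise ValueError("curve does not span Q*Dmax >= pi; increase the Q "
                         "range or Dmax is meaningless")
    r = np.linspace(0.0, dmax, nr)
    w = np.gradient(r)
    qr = np.outer(curve.q, r)
    kern = np.where(qr > 1e-12, np.sin(qr) / np.where(qr > 1e-12, qr, 1.0), 1.0)
    kern_w = kern * w[None, :]
    # fix the endpoints to zero by dropping those columns
    inner = slice(1, nr - 1)
    kw = kern_w[:, inner]
    scale = np.abs(curve.i).max()
    i_obs = curve.i / scale
    w_exp = np.ones_like(i_obs) if curve.sigma is None else \
        scale / np.maximum(curve.sigma, 1e-12 * scale)
    w_exp = w_exp / w_exp.max()

    def solve(a):
        d2 = np.zeros((nr - 4, nr - 2))
        for k in range(nr - 4):
            d2[k, k:k + 3] = (1.0, -2.0, 1.0)
        a_stack = np.vstack([w_exp[:, None] * kw, a * d2])
        b_stack = np.concatenate([w_exp * i_obs, np.zeros(nr - 4)])
        p_in, _ = nnls(a_stack, b_stack)
        resid = np.linalg.norm(w_exp * (kw @ p_in - i_obs))
        rough = np.linalg.norm(np.diff(p_in, 2))
        return p_in, resid, rough

    if alpha is None:
        alphas = np.logspace(-4, 2, 13)
        fits = [solve(a) for a in alphas]
        lr = np.log10([max(f[1], 1e-12) for f in fits])
        lx = np.log10([max(f[2], 1e-12) for f in fits])
        # L-curve corner: point farthest from the chord between the ends
        p0 = np.array([lr[0], lx[0]])
        p1 = np.array([lr[-1], lx[-1]])
        chord = p1 - p0
        chord = chord / max(np.linalg.norm(chord), 1e-12)
        pts = np.stack([lr, lx], axis=1) - p0
        dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
        best = int(np.argmax(dist))
        p_in, resid, _ = fits[best]
    else:
        p_in, resid, _ = solve(alpha)

    base = np.linalg.norm(w_exp * i_obs)
    if resid > 0.5 * base:
        raise ValueError("P(r) fit residual is very large; Dmax is likely too "
                         "small -- scan larger Dmax values")
    p = np.zeros(nr)
    p[inner] = p_in
    return _summarise_pr(r, p * scale)


def _summarise_pr(r: np.ndarray, p: np.ndarray) -> DistanceDistribution:
    total = np.trapezoid(p, r)
    if total <= 0:
        raise ValueError("P(r) is identically zero")
    rg2 = np.trapezoid(p * r ** 2, r) / (2.0 * total)
    peak = p.max()
    mode = float(r[np.argmax(p)])
    above = np.where(p >= 0.01 * peak)[0]
    length = float(r[above[-1]]) if len(above) else float(r[-1])
    span = float(r[np.nonzero(p)[0][-1]]) if np.any(p > 0) else float(r[-1])
    return DistanceDistribution(r, p, length, span, mode, float(np.sqrt(rg2)))


def pr_from_model(spheres, bin_width: float = 0.05) -> DistanceDistribution:
    """P(r) of a sphere model as a radius-convolved distance histogram.

    The centre-centre distance histogram is convolved with the finite-sphere
    kernel (the self-convolution of a uniform sphere's axial profile), and
    the intra-sphere term is added, so P has support out to the geometric
    maximum span + 2R.  ``length`` carries the 1%-of-peak support end used
    throughout; ``span`` carries max pairwise distance + 2R.
    """
    from scipy.spatial.distance import pdist
    if spheres.n_spheres < 2:
        raise ValueError("need at least 2 spheres for a distance distribution")
    radius = spheres.radius
    d = pdist(spheres.centres)
    span = float(d.max() + 2.0 * radius)
    r = np.arange(0.0, span + 3.0 * bin_width, bin_width)
    hist, _ = np.histogram(d, bins=len(r) - 1, range=(0.0, r[-2] + bin_width))
    # kernel: distribution of the axial-projection difference of two uniform
    # spheres (Epanechnikov profile self-convolved), support [-2R, 2R]
    half = int(np.ceil(2.0 * radius / bin_width))
    u = np.arange(-half, half + 1) * bin_width / radius
    prof = np.maximum(1 - (np.arange(-half, half + 1) * bin_width / (2 * radius)) ** 2, 0.0)
    kern = np.convolve(prof, prof)
    kern = kern / kern.sum()
    smeared = np.convolve(hist, kern, mode="full")[half * 2:half * 2 + len(r) - 1]
    # intra-sphere contribution: n spheres' self-distance density
    rr = (r[:-1] + 0.5 * bin_width) / radius
    self_p = np.where(rr <= 2.0,
                      3.0 * rr ** 2 * (1 - 0.75 * rr + rr ** 3 / 16.0), 0.0)
    # Debye weighting: n self terms, 2 per unordered centre pair
    self_p = self_p / max(self_p.sum(), 1e-12) * spheres.n_spheres
    pair_p = smeared / max(smeared.sum(), 1e-12) * (2.0 * len(d))
    p = np.concatenate([[0.0], self_p + pair_p])
    p[-1] = 0.0
    out = _summarise_pr(r, p)
    out.span = span
    # the mode reports the inter-sphere structure; the sub-resolution
    # intra-sphere spread is not a structural distance
    out.mode = float(r[1:][np.argmax(pair_p)])
    return out


# ---------------------------------------------------------------------------
# melting curves
# ---------------------------------------------------------------------------

def _two_state(T, tm, width, af, bf, au, bu):
    from scipy.special import expit
    f = expit(-(T - tm) / width)
    return f * (af + bf * T) + (1 - f) * (au + bu * T)


def melting_analysis(curve: MeltingCurve) -> float:
    """Melting temperature T_m (C) of a two-state melt.

    Linear folded/unfolded baselines are estimated by fitting the full
    two-state model; the fraction folded F(T) is then computed pointwise
    from the baselines and T_m is the linear interpolation of F = 0.5.
    """
    T, y = curve.temperature, curve.signal
    span = y.max() - y.min()
    if span < 1e-9 * max(1.0, abs(y).max()):
        raise ValueError("flat signal: no melting transition present")
    # initial guess: steepest descent of a lightly smoothed signal
    k = max(3, len(T) // 25)
    ys = np.convolve(y, np.ones(k) / k, mode="same")
    tm0 = float(T[np.argmax(np.abs(np.gradient(ys, T)))])
    p0 = (tm0, max((T[-1] - T[0]) / 20.0, 0.5),
          y[:3].mean(), 0.0, y[-3:].mean(), 0.0)
    try:
        popt, _ = curve_fit(_two_state, T, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise ValueError(f"two-state fit failed: {exc}") from None
    _, _, af, bf, au, bu = popt
    folded = af + bf * T
    unfolded = au + bu * T
    denom = folded - unfolded
    if np.all(np.abs(denom) < 1e-9 * span):
        raise ValueError("degenerate baselines: folded and unfolded coincide")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (y - unfolded) / denom
    ok = np.isfinite(frac)
    Tg, fg = T[ok], frac[ok]
    crossings = np.where(np.diff(np.sign(fg - 0.5)) != 0)[0]
    if len(crossings) == 0:
        raise ValueError("fraction folded never crosses 0.5 in the "
                         "temperature window")
    j = crossings[len(crossings) // 2]
    t0, t1 = Tg[j], Tg[j + 1]
    f0, f1 = fg[j], fg[j + 1]
    return float(t0 + (0.5 - f0) * (t1 - t0) / (f1 - f0))
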