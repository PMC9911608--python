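"""TCSPC decay modelling: IRF-convolved bi-exponential model, lifetime
summaries, Förster/FRET efficiencies, and Poisson maximum-likelihood fitting.

The fluorescence decay measured by time-correlated single photon counting
(TCSPC) is modelled as a two-component exponential convolved with a Gaussian
instrument response function (IRF) of width ``tauG``:

    F(t) = F0 * [P1 * H(t; t0, tau1, tauG) + (1 - P1) * H(t; t0, tau2, tauG)]

where H is the closed-form Gaussian (x) exponential convolution

    H(t; t0, tau, tauG) = 1/2 * exp(tauG^2 / (2 tau^2) - (t - t0)/tau)
                              * erfc((tauG^2 - tau (t - t0)) / (sqrt(2) tau tauG))

normalised so that H -> exp(-(t - t0)/tau) as tauG -> 0.  FRET efficiency is
derived from the amplitude-weighted lifetime tau_a = P1 tau1 + (1 - P1) tau2
of the donor with (DA) and without (D) acceptor:  E = 1 - tau_a,DA / tau_a,D.

For low-photon structures the first moment of the decay histogram (the
center-of-mass "mean lifetime") is the robust surrogate; no background
subtraction is applied to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import erfc, erfcx

from .errors import ConvergenceError, InsufficientPhotonsError, InvalidParameterError

__all__ = [
    "DecayParams",
    "DecayHistogram",
    "LifetimeSummary",
    "FretResult",
    "FitDiagnostics",
    "convolved_exponential",
    "decay_model",
    "amplitude_weighted_lifetime",
    "fret_efficiency",
    "forster_efficiency",
    "mean_lifetime",
    "fit_biexponential",
    "wrapped_exponential_mean",
]

#: lifetimes closer than this (ns) are flagged as effectively mono-exponential
DEGENERATE_TAU_GAP_NS = 0.05

#: default minimum photon count for a bi-exponential fit
MIN_PHOTONS_BIEXP = 10_000


@dataclass
class DecayParams:
    """Parameters of the IRF-convolved bi-exponential decay.

    Attributes
    ----------
    F0 : float
        Peak amplitude before convolution (photons per bin).
    P1 : float
        Fraction of the first component, in [0, 1].
    tau1, tau2 : float
        Component lifetimes (ns).  Canonical ordering ``tau1 <= tau2`` is
        enforced on construction; if the inputs are reversed the components
        are swapped (``P1 <-> 1 - P1``).
    tauG : float
        Gaussian IRF width (ns).
    t0 : float
        Time offset of the excitation pulse (ns).
    """

    F0: float
    P1: float
    tau1: float
    tau2: float
    tauG: float
    t0: float

    def __post_init__(self):
        if not (0.0 <= self.P1 <= 1.0):
            raise InvalidParameterError(f"P1 must be in [0, 1], got {self.P1}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise InvalidParameterError(
                f"lifetimes must be positive, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.tauG <= 0:
            raise InvalidParameterError(f"tauG must be positive, got {self.tauG}")
        if self.F0 < 0:
            raise InvalidParameterError(f"F0 must be non-negative, got {self.F0}")
        if self.tau1 > self.tau2:  # canonical order: swap components
            self.tau1, self.tau2 = self.tau2, self.tau1
            self.P1 = 1.0 - self.P1

    @property
    def tau_a(self) -> float:
        """Amplitude-weighted lifetime P1*tau1 + (1-P1)*tau2 (ns)."""
        return amplitude_weighted_lifetime(self.P1, self.tau1, self.tau2)


@dataclass
class DecayHistogram:
    """Binned photon arrival counts over one acquisition window.

    ``bin_edges`` is a strictly increasing uniform grid (ns) with
    ``len(counts) == len(bin_edges) - 1``.  ``background_per_bin`` holds the
    expected background counts per bin (0 when unknown).
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    background_per_bin: float = 0.0

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.bin_edges.ndim != 1:
            raise InvalidParameterError("bin_edges and counts must be 1-D")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise InvalidParameterError(
                f"len(counts)={len(self.counts)} must equal "
                f"len(bin_edges)-1={len(self.bin_edges) - 1}"
            )
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise InvalidParameterError("bin_edges must be strictly increasing")
        if np.any(np.abs(widths - widths[0]) > 1e-9 * widths[0]):
            raise InvalidParameterError("bins must be uniform within 1e-9 rel. tol.")
        if np.any(self.counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if self.background_per_bin < 0:
            raise InvalidParameterError("background_per_bin must be >= 0")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class LifetimeSummary:
    """Center-of-mass and amplitude-weighted lifetime summaries."""

    tau_a: float  # amplitude-weighted lifetime (ns); NaN when not fitted
    tau_mean: float  # center-of-mass mean lifetime (ns)
    total_photons: int


@dataclass(frozen=True)
class FretResult:
    """FRET efficiency from donor lifetimes with/without acceptor."""

    efficiency: float
    tau_a_donor_only: float
    tau_a_with_acceptor: float


@dataclass
class FitDiagnostics:
    """Diagnostics attached to a bi-exponential fit."""

    redchi: float
    nll: float
    n_photons: int
    n_starts: int
    success: bool
    mono_exponential: bool  # tau2 - tau1 below the degeneracy gap
    stderr: dict = field(default_factory=dict)


def convolved_exponential(t, t0: float, tau: float, tauG: float):
    """Exponential decay convolved with a unit-area Gaussian IRF.

    Evaluates H(t) = 1/2 exp(tauG^2/(2 tau^2) - (t-t0)/tau)
    * erfc((tauG^2 - tau (t-t0)) / (sqrt(2) tau tauG)), the closed form of
    exp(-(t-t0)/tau)·theta(t-t0) convolved with N(0, tauG^2).  Computed via
    the scaled complementary error function erfcx so large exponent
    arguments (short lifetimes, wide IRFs, early times) do not overflow:

        H = 1/2 * erfcx(x) * exp(-(t-t0)^2 / (2 tauG^2)),
        x = (tauG^2 - tau (t-t0)) / (sqrt(2) tau tauG).

    Parameters are in ns; the result is dimensionless with peak ~1.
    """
    if tau <= 0:
        raise InvalidParameterError(f"tau must be positive, got {tau}")
    if tauG <= 0:
        raise InvalidParameterError(f"tauG must be positive, got {tauG}")
    dt = np.asarray(t, dtype=float) - t0
    x = (tauG * tauG - tau * dt) / (math.sqrt(2.0) * tau * tauG)
    out = np.empty_like(dt)
    # x >= 0 (early times): erfc(x)*exp(a) = erfcx(x)*exp(a - x^2),
    # with a - x^2 == -dt^2/(2 tauG^2); avoids overflow of exp(a).
    pos = x >= 0
    out[pos] = 0.5 * erfcx(x[pos]) * np.exp(
        -(dt[pos] ** 2) / (2.0 * tauG * tauG)
    )
    # x < 0 (decay tail): erfc(x) in (1, 2] and the plain exponent is small.
    neg = ~pos
    a = tauG * tauG / (2.0 * tau * tau) - dt[neg] / tau
    out[neg] = 0.5 * np.exp(a) * erfc(x[neg])
    return out if out.ndim else float(out)


def decay_model(times, params: DecayParams):
    """Bi-exponential decay F(t) evaluated on a time grid (photons per bin)."""
    h1 = convolved_exponential(times, params.t0, params.tau1, params.tauG)
    h2 = convolved_exponential(times, params.t0, params.tau2, params.tauG)
    return params.F0 * (params.P1 * h1 + (1.0 - params.P1) * h2)


def periodic_decay_model(times, params: DecayParams, window: float,
                         n_periods: int = 3):
    """Decay under periodic excitation: photons from the previous
    ``n_periods`` pulses fold into the observation window, so the expected
    intensity is sum_k F(t + k * window).  Two extra periods suffice for
    lifetimes below ~window/4 (residual < exp(-3 window / tau))."""
    if window <= 0:
        raise InvalidParameterError("window must be positive")
    t = np.asarray(times, dtype=float)
    out = np.zeros_like(t)
    for k in range(n_periods):
        out += decay_model(t + k * window, params)
    return out


def amplitude_weighted_lifetime(P1: float, tau1: float, tau2: float) -> float:
    """Amplitude-weighted lifetime tau_a = P1*tau1 + (1-P1)*tau2 (ns)."""
    if not (0.0 <= P1 <= 1.0):
        raise InvalidParameterError(f"P1 must be in [0, 1], got {P1}")
    if tau1 <= 0 or tau2 <= 0:
        raise InvalidParameterError("lifetimes must be positive")
    return P1 * tau1 + (1.0 - P1) * tau2


def fret_efficiency(tau_a_DA: float, tau_a_D: float) -> float:
    """FRET efficiency E = 1 - tau_a,DA / tau_a,D.

    Not clamped: photon noise can push E slightly negative.
    """
    if tau_a_D <= 0 or tau_a_DA <= 0:
        raise InvalidParameterError("lifetimes must be positive")
    return 1.0 - tau_a_DA / tau_a_D


def forster_efficiency(r, R0: float):
    """Pairwise Förster efficiency E = 1 / (1 + (r/R0)^6).

    ``R0`` is the Förster radius — the separation at 50% transfer
    efficiency (60 Å for the EGFP–ShadowY pair).
    """
    if R0 <= 0:
        raise InvalidParameterError(f"R0 must be positive, got {R0}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("separation r must be non-negative")
    out = 1.0 / (1.0 + (r / R0) ** 6)
    return out if out.ndim else float(out)


def mean_lifetime(hist: DecayHistogram, t_reference: float = 0.0) -> LifetimeSummary:
    """Center-of-mass mean lifetime of a decay histogram.

    tau_mean = sum(count_i * center_i) / sum(count_i) - t_reference, over the
    full window with no background subtraction.  ``t_reference`` should be a
    consistent per-cell time origin (typically the fitted t0); all downstream
    comparisons are differences, so only consistency matters.
    """
    total = hist.counts.sum()
    if total <= 0:
        raise InsufficientPhotonsError("empty histogram: no photons to average")
    com = float(np.dot(hist.counts, hist.centers) / total)
    return LifetimeSummary(
        tau_a=math.nan, tau_mean=com - t_reference, total_photons=int(total)
    )


def wrapped_exponential_mean(tau: float, t0: float, window: float) -> float:
    """Mean arrival time (ns) of t0 + Exp(tau) wrapped modulo the window.

    Under periodic excitation, photons emitted after the window end are
    recorded in the next period; the center of mass of the wrapped decay is
    lower than t0 + tau by window * q where
    q = exp(-(window - t0)/tau) / (1 - exp(-window/tau)).
    """
    q = math.exp(-(window - t0) / tau) / (1.0 - math.exp(-window / tau))
    return t0 + tau - window * q


# ---------------------------------------------------------------------------
# Poisson maximum-likelihood fitting
# ---------------------------------------------------------------------------

_LOGIT = lambda p: math.log(p / (1.0 - p))  # noqa: E731


def _theta_from_params(p: DecayParams, fit_tauG: bool, fit_t0: bool) -> np.ndarray:
    th = [math.log(p.F0), _LOGIT(min(max(p.P1, 1e-4), 1 - 1e-4)),
          math.log(p.tau1), math.log(p.tau2)]
    if fit_tauG:
        th.append(math.log(p.tauG))
    if fit_t0:
        th.append(p.t0)
    return np.array(th)


def _params_from_theta(th, tauG_fixed, t0_fixed) -> DecayParams:
    i = 4
    tauG = tauG_fixed
    if tauG is None:
        tauG = math.exp(th[i])
        i += 1
    t0 = t0_fixed if t0_fixed is not None else th[i]
    return DecayParams(
        F0=math.exp(th[0]),
        P1=1.0 / (1.0 + math.exp(-th[1])),
        tau1=math.exp(th[2]),
        tau2=math.exp(th[3]),
        tauG=tauG,
        t0=float(t0),
    )


def _initial_guesses(hist: DecayHistogram) -> tuple[float, float]:
    """Heuristic (t0, tauG) from the histogram peak position and rise width."""
    c = hist.counts.astype(float)
    centers = hist.centers
    ipk = int(np.argmax(c))
    t_peak = centers[ipk]
    # rise width: time from 10% of peak to peak on the leading edge
    thresh = 0.1 * c[ipk]
    i = ipk
    while i > 0 and c[i] > thresh:
        i -= 1
    rise = max(t_peak - centers[i], hist.bin_width)
    tauG0 = max(rise / 2.0, hist.bin_width / 2.0)
    t0_0 = max(t_peak - tauG0, hist.bin_edges[0])
    return float(t0_0), float(tauG0)


def fit_biexponential(
    hist: DecayHistogram,
    init: DecayParams | None = None,
    fix_tauG: float | None = None,
    fix_t0: float | None = None,
    min_photons: int = MIN_PHOTONS_BIEXP,
) -> tuple[DecayParams, FitDiagnostics]:
    """Fit the IRF-convolved bi-exponential by Poisson maximum likelihood.

    The expected counts per bin are ``decay_model(center) +
    background_per_bin``; the Poisson negative log-likelihood is minimised by
    L-BFGS-B in log/logit-transformed parameters from four starting points
    ((tau1, tau2) in {(0.5, 2.5), (1.0, 3.0)} x P1 in {0.3, 0.7}) because
    bi-exponential likelihoods are multimodal.  Pass ``fix_tauG`` / ``fix_t0``
    to pin the instrument parameters to per-cell values.

    Returns the canonical-order parameters and :class:`FitDiagnostics`
    (Pearson reduced chi-square, per-parameter standard errors from the
    observed information, and a flag marking effectively mono-exponential
    fits with ``tau2 - tau1 < 0.05`` ns where only tau_a is identifiable).

    Raises
    ------
    InsufficientPhotonsError
        Below ``min_photons`` total counts (default 10,000; the practical
        floor for resolving two components — fall back to `mean_lifetime`).
    ConvergenceError
        No start converged; the best candidate is attached.
    """
    total = hist.total_photons
    if total < min_photons:
        raise InsufficientPhotonsError(
            f"{total} photons < minimum {min_photons} for a bi-exponential fit; "
            "use mean_lifetime instead"
        )
    centers = hist.centers
    counts = hist.counts.astype(float)
    bg = float(hist.background_per_bin)
    fit_tauG = fix_tauG is None
    fit_t0 = fix_t0 is None

    t0_0, tauG0 = _initial_guesses(hist)
    if fix_t0 is not None:
        t0_0 = fix_t0
    if fix_tauG is not None:
        tauG0 = fix_tauG

    if init is not None:
        starts = [init]
    else:
        starts = []
        for tau1, tau2 in ((0.5, 2.5), (1.0, 3.0)):
            for p1 in (0.3, 0.7):
                ta = p1 * tau1 + (1 - p1) * tau2
                F0 = max((total - bg * len(counts)) * hist.bin_width / ta, 1e-3)
                starts.append(
                    DecayParams(F0=F0, P1=p1, tau1=tau1, tau2=tau2,
                                tauG=tauG0, t0=t0_0)
                )

    window = float(hist.bin_edges[-1] - hist.bin_edges[0])

    def nll(th):
        try:
            p = _params_from_theta(th, fix_tauG, fix_t0)
        except (InvalidParameterError, OverflowError):
            return 1e300
        mu = periodic_decay_model(centers, p, window) + bg
        mu = np.maximum(mu, 1e-12)
        return float(np.sum(mu - counts * np.log(mu)))

    best = None
    for start in starts:
        th0 = _theta_from_params(start, fit_tauG, fit_t0)
        res = optimize.minimize(nll, th0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res

    params = _params_from_theta(best.x, fix_tauG, fix_t0)
    mu = np.maximum(periodic_decay_model(centers, params, window) + bg, 1e-12)
    n_free = len(best.x)
    redchi = float(np.sum((counts - mu) ** 2 / mu) / max(len(counts) - n_free, 1))

    stderr = _observed_information_stderr(nll, best.x, fix_tauG, fix_t0, params)
    diag = FitDiagnostics(
        redchi=redchi,
        nll=float(best.fun),
        n_photons=total,
        n_starts=len(starts),
        success=bool(best.success),
        mono_exponential=(params.tau2 - params.tau1) < DEGENERATE_TAU_GAP_NS,
        stderr=stderr,
    )
    if not best.success and not np.isfinite(best.fun):
        raise ConvergenceError(
            "bi-exponential fit failed to converge", best_candidate=(params, diag)
        )
    return params, diag


def _observed_information_stderr(nll, theta, fix_tauG, fix_t0, params) -> dict:
    """Standard errors from a finite-difference Hessian of the NLL,
    propagated from transformed to natural parameters by the delta method."""
    n = len(theta)
    h = 1e-4
    H = np.zeros((n, n))
    f0 = nll(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h
            ej = np.eye(n)[j] * h
            if i == j:
                H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h**2
            else:
                fpp = nll(theta + ei + ej)
                fpm = nll(theta + ei - ej)
                fmp = nll(theta - ei + ej)
                fmm = nll(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
    try:
        cov = np.linalg.pinv(H)
        var = np.clip(np.diag(cov), 0, None)
    except np.linalg.LinAlgError:
        return {}
    sd = np.sqrt(var)
    names = ["F0", "P1", "tau1", "tau2"]
    # jacobian of natural w.r.t. transformed parameters
    jac = [params.F0, params.P1 * (1 - params.P1), params.tau1, params.tau2]
    if fix_tauG is None:
        names.append("tauG")
        jac.append(params.tauG)
    if fix_t0 is None:
        names.append("t0")
        jac.append(1.0)
    return {nm: float(s * j) for nm, s, j in zip(names, sd, jac)}
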