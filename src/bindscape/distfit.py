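"""Ensemble histograms and the Gaussian-center / exponential-tail model.

Across an ensemble of ligands the observables (affinity, log K, ISR,
log residence time) are Gaussian near the mean with exponential tails —
the composite shape the landscape theory predicts and the shape one fits
to a drawn histogram.  :func:`fit_composite` recovers the center
``(mu, sigma)`` and the tail rates ``lambda_L``, ``lambda_R`` with the
junctions placed where the pieces cross; :func:`fit_power_tail` estimates
the power-law exponent of a positive variable from the exponential slope
of its log-transform, with a Hill-type maximum-likelihood cross-check.

Fits minimize squared error on bin probability densities — the histogram
is the object being modelled — not likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import integrate, optimize

from .errors import FitError

__all__ = [
    "TailFit",
    "DistributionFit",
    "PowerTailFit",
    "histogram",
    "fit_composite",
    "fit_power_tail",
    "freedman_diaconis_bins",
]


def freedman_diaconis_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis bin count (>= 10)."""
    values = np.asarray(values, dtype=float)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr == 0:
        return 10
    width = 2.0 * iqr / values.size ** (1.0 / 3.0)
    span = values.max() - values.min()
    return max(10, int(np.ceil(span / width)))


def histogram(values, n_bins: int, log_space: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """Probability-normalized histogram (sum p_i * width_i = 1).

    With ``log_space`` the values are log-transformed first (for K and
    tau, whose natural axis is logarithmic); bin centers are then in log
    units.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise FitError("histogram of empty input")
    if n_bins < 2:
        raise FitError(f"n_bins must be >= 2, got {n_bins}")
    if log_space:
        if np.any(values <= 0):
            raise FitError("log_space histogram requires positive values")
        values = np.log(values)
    probs, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, probs


@dataclass(frozen=True)
class TailFit:
    """One exponential tail piece ``amplitude * exp(-rate * |x - junction|)``."""

    rate: float  # lambda, > 0 for a decaying tail
    junction: float  # x_L or x_R where the piece takes over from the Gaussian
    amplitude: float  # density at the junction
    reliable: bool  # False when too few informative bins supported the fit
    n_bins: int
    rms_residual: float


@dataclass(frozen=True)
class DistributionFit:
    """Fitted composite density: Gaussian center plus exponential tails.

    The composite is continuous at both junctions and integrates to 1;
    a missing (unreliable) tail piece extends the Gaussian on that side.
    """

    variable_name: str
    mu: float
    sigma: float
    center_amplitude: float
    left_tail: Optional[TailFit]
    right_tail: Optional[TailFit]
    normalization: float
    center_rms_residual: float
    n_values: int
    n_bins: int
    window: Tuple[float, float]
    bin_centers: np.ndarray = field(repr=False)
    bin_probs: np.ndarray = field(repr=False)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self.center_amplitude * np.exp(-((x - self.mu) ** 2) / (2 * self.sigma**2))
        if self.left_tail is not None:
            lt = self.left_tail
            left = lt.amplitude * np.exp(lt.rate * (x - lt.junction))
            out = np.where(x < lt.junction, left, out)
        if self.right_tail is not None:
            rt = self.right_tail
            right = rt.amplitude * np.exp(-rt.rate * (x - rt.junction))
            out = np.where(x > rt.junction, right, out)
        return out / self.normalization

    def summary(self) -> dict:
        def tail_dict(t: Optional[TailFit]) -> Optional[dict]:
            if t is None:
                return None
            return {
                "lambda": t.rate,
                "junction": t.junction,
                "amplitude": t.amplitude,
                "reliable": t.reliable,
                "n_bins": t.n_bins,
                "rms_residual": t.rms_residual,
            }

        return {
            "variable": self.variable_name,
            "center": {"mu": self.mu, "sigma": self.sigma},
            "left_tail": tail_dict(self.left_tail),
            "right_tail": tail_dict(self.right_tail),
            "center_rms_residual": self.center_rms_residual,
            "n_values": self.n_values,
            "n_bins": self.n_bins,
        }


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def _fit_tail(
    centers: np.ndarray,
    probs: np.ndarray,
    counts: np.ndarray,
    side: str,
    window_edge: float,
    gauss_par,
    min_bins: int = 3,
    min_count: int = 5,
    excess_factor: float = 1.5,
    curvature_limit: float = 0.25,
) -> Optional[TailFit]:
    """Log-linear LSQ on the bins the Gaussian center fails to explain.

    Bins qualify when they lie outside the center window on the given
    side, hold at least ``min_count`` observations, and their empirical
    density exceeds ``excess_factor`` times the fitted Gaussian there —
    i.e. where the data has genuinely departed from the center piece and
    the exponential should take over.  The tail is reported unreliable
    when fewer than ``min_bins`` bins qualify (the fit then falls back to
    the plain outside bins) or when the tail log-density is visibly
    curved — a Gaussian tail masquerading as exponential.
    """
    outside = centers < window_edge if side == "left" else centers > window_edge
    informative = outside & (probs > 0)
    solid = informative & (counts >= min_count)
    gpred = _gaussian(centers, *gauss_par)
    departed = solid & (probs > excess_factor * gpred)
    enough = departed.sum() >= min_bins
    use = departed if enough else (solid if solid.sum() >= 2 else informative)
    if use.sum() < 2:
        return None
    x = centers[use]
    logp = np.log(probs[use])
    # Poisson noise of log density scales as 1/sqrt(count)
    w = np.sqrt(np.maximum(counts[use], 1.0))
    slope, intercept = np.polyfit(x, logp, 1, w=w)
    rate = slope if side == "left" else -slope
    if rate <= 0:
        # tail not decaying away from the center: no meaningful piece
        return None
    curved = False
    if use.sum() >= 4:
        c2, c1, _ = np.polyfit(x, logp, 2, w=w)
        span = float(x.max() - x.min())
        mid_slope = 2.0 * c2 * float(x.mean()) + c1
        curved = abs(c2) * span / max(abs(mid_slope), 1e-12) > curvature_limit
    # provisional junction at the window edge; refined by the caller
    amp_edge = math.exp(intercept + slope * window_edge)
    fitted = np.exp(intercept + slope * x)
    rms = float(np.sqrt(np.mean((fitted - probs[use]) ** 2)))
    return TailFit(
        rate=float(rate),
        junction=float(window_edge),
        amplitude=float(amp_edge),
        reliable=bool(enough and not curved),
        n_bins=int(use.sum()),
        rms_residual=rms,
    )


def _cross_junction(gauss_par, tail: TailFit, side: str) -> TailFit:
    """Move the junction to where Gaussian and exponential cross.

    Solving ``log G(x) = log tail(x)`` is a quadratic in x; the root on
    the tail's side nearest the center is used.  If the pieces never
    cross, the junction stays at the window edge and the tail amplitude
    is matched to the Gaussian there (continuity by amplitude matching).
    """
    amp, mu, sigma = gauss_par
    s = 1.0 if side == "left" else -1.0
    # log amp - (x-mu)^2/(2 sigma^2) = log A + s * rate * (x - x0)
    a = -1.0 / (2.0 * sigma**2)
    b = mu / sigma**2 - s * tail.rate
    c = (
        math.log(amp)
        - mu**2 / (2.0 * sigma**2)
        - math.log(tail.amplitude)
        - s * tail.rate * (-tail.junction)
    )
    disc = b * b - 4.0 * a * c
    if disc >= 0:
        r1 = (-b + math.sqrt(disc)) / (2.0 * a)
        r2 = (-b - math.sqrt(disc)) / (2.0 * a)
        roots = [r for r in (r1, r2) if (r < mu if side == "left" else r > mu)]
        if roots:
            x_j = max(roots) if side == "left" else min(roots)
            amp_j = _gaussian(x_j, *gauss_par)
            return TailFit(
                rate=tail.rate,
                junction=float(x_j),
                amplitude=float(amp_j),
                reliable=tail.reliable,
                n_bins=tail.n_bins,
                rms_residual=tail.rms_residual,
            )
    # no crossing: clamp amplitude to the Gaussian at the window edge
    amp_j = _gaussian(tail.junction, *gauss_par)
    return TailFit(
        rate=tail.rate,
        junction=tail.junction,
        amplitude=float(amp_j),
        reliable=tail.reliable,
        n_bins=tail.n_bins,
        rms_residual=tail.rms_residual,
    )


def fit_composite(
    values,
    n_bins: Optional[int] = None,
    center_window_sigmas: float = 1.5,
    variable_name: str = "value",
) -> DistributionFit:
    """Fit the Gaussian-center / two-exponential-tail composite model.

    Procedure: (1) a robust center estimate (median, MAD-scaled sigma)
    defines the center window ``median +- center_window_sigmas * sigma``;
    (2) the Gaussian is least-squares fit to the bin densities inside the
    window; (3) each exponential tail is log-linear least-squares fit to
    the outside bins the Gaussian cannot explain; (4) the junctions move
    to the crossing points of the pieces, continuity being enforced by
    amplitude matching when no crossing exists; finally the composite is
    renormalized to integrate to 1.

    Requires at least 100 values; a constant sample raises
    :class:`FitError`.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise FitError(f"need >= 100 values to fit, got {values.size}")
    med = float(np.median(values))
    mad_sigma = 1.4826 * float(np.median(np.abs(values - med)))
    if mad_sigma == 0.0:
        raise FitError("degenerate sample: zero robust spread")
    if n_bins is None:
        n_bins = freedman_diaconis_bins(values)
    if n_bins < 10:
        raise FitError(f"n_bins must be >= 10, got {n_bins}")
    centers, probs = histogram(values, n_bins)
    window = (med - center_window_sigmas * mad_sigma, med + center_window_sigmas * mad_sigma)
    in_window = (centers >= window[0]) & (centers <= window[1]) & (probs > 0)
    if in_window.sum() < 4:
        raise FitError("too few populated bins inside the center window")
    p0 = (probs[in_window].max(), med, mad_sigma)
    par, _ = optimize.curve_fit(
        _gaussian,
        centers[in_window],
        probs[in_window],
        p0=p0,
        bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    amp, mu, sigma = (float(v) for v in par)
    center_rms = float(
        np.sqrt(np.mean((_gaussian(centers[in_window], *par) - probs[in_window]) ** 2))
    )
    width = centers[1] - centers[0]
    counts = np.rint(probs * width * values.size)
    left = _fit_tail(centers, probs, counts, "left", window[0], par)
    right = _fit_tail(centers, probs, counts, "right", window[1], par)
    if left is not None:
        left = _cross_junction(par, left, "left")
    if right is not None:
        right = _cross_junction(par, right, "right")

    fit = DistributionFit(
        variable_name=variable_name,
        mu=mu,
        sigma=sigma,
        center_amplitude=amp,
        left_tail=left,
        right_tail=right,
        normalization=1.0,
        center_rms_residual=center_rms,
        n_values=int(values.size),
        n_bins=int(n_bins),
        window=window,
        bin_centers=centers,
        bin_probs=probs,
    )
    span = values.max() - values.min()
    lo = values.min() - 2 * span
    hi = values.max() + 2 * span
    mass, _ = integrate.quad(lambda x: float(fit.pdf(x)), lo, hi, limit=400)
    if not mass > 0:
        raise FitError("composite fit has zero mass")
    return DistributionFit(
        variable_name=variable_name,
        mu=mu,
        sigma=sigma,
        center_amplitude=amp,
        left_tail=left,
        right_tail=right,
        normalization=float(mass),
        center_rms_residual=center_rms,
        n_values=int(values.size),
        n_bins=int(n_bins),
        window=window,
        bin_centers=centers,
        bin_probs=probs,
    )


@dataclass(frozen=True)
class PowerTailFit:
    """Power-law tail exponent with a Hill-type ML cross-check."""

    exponent: float  # alpha = 1 + lambda from the log-space slope
    hill_exponent: float  # alpha from the Hill estimator over the same tail
    rate: float  # lambda: exponential rate of log(value) in the tail
    threshold: float  # tail start (original scale)
    n_tail: int
    curvature_ratio: float  # |c2| * span / |c1| of a quadratic log-density fit
    is_power_law: bool  # False when the log-density is visibly curved


def fit_power_tail(
    values,
    tail_fraction: float = 0.2,
    n_bins: Optional[int] = None,
    curvature_limit: float = 0.2,
) -> PowerTailFit:
    """Tail exponent of a positive heavy-tailed variable.

    A density ``f(x) ~ x**(-1 - lambda)`` maps to an exponential density
    ``exp(-lambda * y)`` of ``y = log x``, so the exponent is
    ``alpha = 1 + lambda`` with ``lambda`` the log-linear slope of the
    log-space histogram over the upper ``tail_fraction`` of the sample.
    The Hill maximum-likelihood estimate over the same tail is reported
    alongside.  A quadratic term in the log-density flags curvature
    (e.g. log-normal samples), marking the tail as not power-law.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise FitError("power tail requires strictly positive values")
    if not 0.0 < tail_fraction < 0.5:
        raise FitError(f"tail_fraction must be in (0, 0.5), got {tail_fraction}")
    y = np.log(values)
    thr = float(np.quantile(y, 1.0 - tail_fraction))
    tail = y[y > thr]
    if tail.size < 50:
        raise FitError(f"too few tail points ({tail.size}) for a slope fit")
    if n_bins is None:
        n_bins = max(10, freedman_diaconis_bins(tail))
    probs, edges = np.histogram(tail, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]
    # sparse far-tail bins are log-noisy; keep well-populated bins only
    keep = np.rint(probs * width * tail.size) >= 5
    if keep.sum() < 3:
        keep = probs > 0
    if keep.sum() < 3:
        raise FitError("too few populated tail bins")
    x = centers[keep]
    logp = np.log(probs[keep])
    w = np.sqrt(np.maximum(np.rint(probs[keep] * width * tail.size), 1.0))
    slope, _ = np.polyfit(x, logp, 1, w=w)
    lam = -float(slope)
    # curvature check on the same bins
    c2, c1, _ = np.polyfit(x, logp, 2, w=w)
    span = float(x.max() - x.min())
    mid_slope = 2.0 * c2 * float(x.mean()) + c1
    curvature = abs(c2) * span / max(abs(mid_slope), 1e-12)
    hill = 1.0 + 1.0 / float(np.mean(tail - thr))
    return PowerTailFit(
        exponent=1.0 + lam,
        hill_exponent=hill,
        rate=lam,
        threshold=math.exp(thr),
        n_tail=int(tail.size),
        curvature_ratio=float(curvature),
        is_power_law=bool(curvature < curvature_limit and lam > 0),
    )
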