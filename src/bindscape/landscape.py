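"""Closed-form random-energy-model (REM) statistics of ligand binding.

A receptor binding many different ligands (or, equivalently, one ligand
exploring many binding modes) is modelled as a random energy landscape:
the binding states of each ligand are i.i.d. Gaussian energies with mean
``mean_energy`` and roughness (standard deviation) ``roughness``.  Out of
that single assumption one obtains the ligand-to-ligand distributions of

* binding free energy: Gaussian near the mean, exponential below a cutoff
  free energy once the landscape becomes glassy (below the trapping
  temperature ``Tc``);
* equilibrium constant ``K``: log-normal near the mean, power law
  ``K**(-1 - T/Tc)`` in the strong-binding tail;
* intrinsic specificity ratio (ISR): the extreme-value density of the
  standardized minimum of ``N_t`` Gaussian states near the mean, a pure
  exponential far in the tail;
* binding/unbinding time: log-normal near the mean, power law
  ``tau**(-1 - T/Tc)`` in the slow tail.

All energies and temperatures are in kcal/mol with ``k_B = 1``; times are
in units of the prefactor ``time_prefactor``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate, special

from .errors import LandscapeError

__all__ = [
    "ROOM_TEMPERATURE",
    "LandscapeParams",
    "AnalyticDensity",
    "density",
    "trapping_temperature",
    "pdf_free_energy_center",
    "pdf_free_energy_tail",
    "pdf_logK_center",
    "pdf_K_tail",
    "pdf_isr_center",
    "cdf_isr_center",
    "pdf_isr_tail",
    "pdf_tau_center",
    "pdf_tau_tail",
]

#: kT at 298 K in kcal/mol; used whenever a temperature is left unstated.
ROOM_TEMPERATURE = 0.593

#: Default span of the bounded support used to normalize power-law tails.
POWER_TAIL_SPAN = 1.0e6


@dataclass(frozen=True)
class LandscapeParams:
    """Parameter set of the binding energy landscape.

    Parameters
    ----------
    mean_energy:
        Mean state energy ``E_bar`` (kcal/mol).
    roughness:
        Standard deviation ``dE`` of the state energies (kcal/mol, >= 0);
        the landscape roughness.
    temperature:
        Thermal energy ``T`` (kcal/mol, ``k_B = 1``).
    num_states:
        Number of configurational states ``N_t`` (>= 1).  When given, the
        configurational entropy is ``S = log(N_t)``.
    entropy:
        Configurational entropy ``S = log(Omega)`` (dimensionless).  May be
        passed directly instead of ``num_states``.
    cutoff_free_energy:
        Cutoff free energy ``Fc`` bounding the exponential low-free-energy
        tail.  Defaults to the freezing free energy
        ``E_bar - dE * sqrt(2 S)``, the level at which the density of
        states runs out.
    time_prefactor:
        Elementary time scale ``tau0`` (> 0) for kinetic quantities.
    """

    mean_energy: float = 0.0
    roughness: float = 1.0
    temperature: float = ROOM_TEMPERATURE
    num_states: Optional[int] = None
    entropy: Optional[float] = None
    cutoff_free_energy: Optional[float] = None
    time_prefactor: float = 1.0
    _entropy: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.roughness < 0:
            raise LandscapeError(f"roughness must be >= 0, got {self.roughness}")
        if self.temperature <= 0:
            raise LandscapeError(f"temperature must be > 0, got {self.temperature}")
        if self.time_prefactor <= 0:
            raise LandscapeError(
                f"time_prefactor must be > 0, got {self.time_prefactor}"
            )
        if self.num_states is not None:
            if self.num_states < 1:
                raise LandscapeError(f"num_states must be >= 1, got {self.num_states}")
            entropy = math.log(self.num_states)
            if self.entropy is not None and not math.isclose(
                self.entropy, entropy, rel_tol=1e-9, abs_tol=1e-12
            ):
                raise LandscapeError(
                    "entropy and num_states disagree: "
                    f"S={self.entropy} vs log(N_t)={entropy}"
                )
            object.__setattr__(self, "_entropy", entropy)
        elif self.entropy is not None:
            if self.entropy < 0:
                raise LandscapeError(f"entropy must be >= 0, got {self.entropy}")
            object.__setattr__(self, "_entropy", float(self.entropy))
        else:
            object.__setattr__(self, "_entropy", 0.0)

    @property
    def S(self) -> float:
        """Configurational entropy (k_B = 1)."""
        return self._entropy

    @property
    def Tc(self) -> float:
        """Trapping transition temperature ``dE / sqrt(2 S)``."""
        return trapping_temperature(self)

    @property
    def rho(self) -> float:
        """Reduced temperature ``T / Tc``."""
        return self.temperature / self.Tc

    @property
    def mean_free_energy(self) -> float:
        """Annealed REM free energy ``E_bar - dE^2/(2T) - T S``.

        This is the high-temperature (self-averaging) free energy of one
        landscape realization; it serves as the default location of the
        Gaussian free-energy distribution across ligands.
        """
        t = self.temperature
        return self.mean_energy - self.roughness**2 / (2.0 * t) - t * self.S

    @property
    def cutoff(self) -> float:
        """Cutoff free energy ``Fc`` (explicit or the freezing level)."""
        if self.cutoff_free_energy is not None:
            return self.cutoff_free_energy
        return self.mean_energy - self.roughness * math.sqrt(2.0 * self.S)


def trapping_temperature(params: LandscapeParams) -> float:
    """Trapping transition temperature ``Tc = dE / sqrt(2 S)``.

    ``Tc`` marks the onset of kinetic trapping: below it the thermal
    population condenses onto the few lowest states of the spectrum.  It
    follows from the Gaussian microcanonical entropy
    ``S(E) = S - E^2 / (2 dE^2)`` vanishing at the ground-state edge.

    Raises
    ------
    LandscapeError
        If roughness or entropy is not strictly positive (``Tc`` is then
        undefined).
    """
    if params.roughness <= 0:
        raise LandscapeError("Tc requires roughness > 0")
    if params.S <= 0:
        raise LandscapeError("Tc requires entropy > 0")
    return params.roughness / math.sqrt(2.0 * params.S)


# ---------------------------------------------------------------------------
# free energy
# ---------------------------------------------------------------------------

def pdf_free_energy_center(F, params: LandscapeParams, mean: Optional[float] = None):
    """Gaussian density of the binding free energy near its mean.

    Above the trapping temperature the ligand-to-ligand free energy is
    Gaussian around ``mean`` (default: the annealed mean free energy) with
    standard deviation equal to the landscape roughness ``dE``.
    """
    if params.roughness == 0:
        raise LandscapeError("degenerate free-energy distribution: roughness = 0")
    mu = params.mean_free_energy if mean is None else mean
    sd = params.roughness
    F = np.asarray(F, dtype=float)
    return np.exp(-((F - mu) ** 2) / (2.0 * sd**2)) / (sd * math.sqrt(2.0 * math.pi))


def pdf_free_energy_tail(F, params: LandscapeParams):
    """Exponential density of the free energy below the cutoff ``Fc``.

    Near or below ``Tc`` the free energy density is
    ``(1/Tc) exp((F - Fc)/Tc)`` for ``F <= Fc`` and exactly zero above the
    cutoff (hard step, no smoothing).  The mean sits at ``Fc - Tc`` and
    the width is of order ``Tc``.
    """
    rho = params.rho
    if rho <= 0:
        raise LandscapeError("free-energy tail requires rho = T/Tc > 0")
    rate = rho / params.temperature  # == 1 / Tc
    Fc = params.cutoff
    F = np.asarray(F, dtype=float)
    out = np.where(F <= Fc, rate * np.exp(rate * (F - Fc)), 0.0)
    return out


# ---------------------------------------------------------------------------
# equilibrium constant
# ---------------------------------------------------------------------------

def pdf_logK_center(logK, params: LandscapeParams, mean_logK: float = 0.0):
    """Normal density of ``log K`` near the mean (log-normal ``K``).

    ``log K = (F_n - F_un)/T`` inherits the Gaussian free-energy statistics,
    so ``log K`` is normal with standard deviation ``dE / T``.  The law
    fixes only the shape; the location ``mean_logK`` is a free parameter
    (default 0).
    """
    if params.roughness <= 0:
        raise LandscapeError("logK center requires roughness > 0")
    sd = params.roughness / params.temperature
    y = np.asarray(logK, dtype=float)
    return np.exp(-((y - mean_logK) ** 2) / (2.0 * sd**2)) / (sd * math.sqrt(2.0 * math.pi))


def pdf_K_tail(K, params: LandscapeParams, support: Optional[Tuple[float, float]] = None):
    """Power-law density ``K**(-1 - T/Tc)`` of the equilibrium constant tail.

    The pure power law is not normalizable on ``(0, inf)``, so the density
    lives on a bounded support ``[K_min, K_max]`` (default span 10**6).
    """
    lam = params.rho
    if lam <= 0:
        raise LandscapeError("K tail requires T/Tc > 0")
    kmin, kmax = support if support is not None else (1.0, POWER_TAIL_SPAN)
    if not (0 < kmin < kmax):
        raise LandscapeError(f"invalid power-tail support [{kmin}, {kmax}]")
    norm = lam / (kmin ** (-lam) - kmax ** (-lam))
    K = np.asarray(K, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(
            (K >= kmin) & (K <= kmax), norm * np.power(K, -1.0 - lam), 0.0
        )
    return out


# ---------------------------------------------------------------------------
# intrinsic specificity ratio
# ---------------------------------------------------------------------------

def _isr_center_norm(num_states: int) -> float:
    # P(|standardized minimum| >= 0) = 1 - Phi(0)^N = 1 - 2^-N
    return 1.0 - 0.5**num_states


def pdf_isr_center(isr, params: LandscapeParams, num_states: Optional[int] = None):
    """Extreme-value density of the ISR near the mean (above ``Tc``).

    With ``N_t`` i.i.d. Gaussian states, the native state is the minimum
    of the spectrum, and ISR = |F_min - F_bar| / dF is the magnitude of the
    standardized minimum.  Its density on ``[0, inf)`` is

        ``N_t phi(x) Phi(x)**(N_t - 1) / (1 - 2**-N_t)``

    which for ``N_t = 1`` reduces to a half-normal.  The mode shifts to
    larger ISR as ``N_t`` grows: richer spectra produce deeper minima.
    Negative arguments return 0.
    """
    n = _resolve_num_states(params, num_states)
    x = np.asarray(isr, dtype=float)
    phi = np.exp(-(x**2) / 2.0) / math.sqrt(2.0 * math.pi)
    Phi = 0.5 * (1.0 + special.erf(x / math.sqrt(2.0)))
    out = n * phi * Phi ** (n - 1) / _isr_center_norm(n)
    return np.where(x >= 0, out, 0.0)


def cdf_isr_center(isr, params: LandscapeParams, num_states: Optional[int] = None):
    """Closed-form CDF companion of :func:`pdf_isr_center`."""
    n = _resolve_num_states(params, num_states)
    x = np.asarray(isr, dtype=float)
    Phi = 0.5 * (1.0 + special.erf(x / math.sqrt(2.0)))
    out = (Phi**n - 0.5**n) / _isr_center_norm(n)
    return np.clip(np.where(x >= 0, out, 0.0), 0.0, 1.0)


def pdf_isr_tail(isr, params: LandscapeParams, num_states: Optional[int] = None):
    """Exponential-tail density of the ISR near or below ``Tc``.

    Implemented literally as ``exp(-(ISR + 1)) (1 - exp(-(ISR + 1)))**(N_t - 1)``
    on ``[0, inf)``; normalization is closed form.  Large specificities are
    exponentially rare: the log-density slope tends to -1 for any ``N_t``.
    """
    n = _resolve_num_states(params, num_states)
    x = np.asarray(isr, dtype=float)
    u = np.exp(-(x + 1.0))
    # integral_0^inf u (1-u)^(n-1) dx = (1 - (1 - e^-1)^n) / n
    norm = (1.0 - (1.0 - math.exp(-1.0)) ** n) / n
    out = u * (1.0 - u) ** (n - 1) / norm
    return np.where(x >= 0, out, 0.0)


def _resolve_num_states(params: LandscapeParams, num_states: Optional[int]) -> int:
    n = num_states if num_states is not None else params.num_states
    if n is None or n < 1:
        raise LandscapeError("ISR densities require num_states >= 1")
    return int(n)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def pdf_tau_center(tau, params: LandscapeParams, tau_median: Optional[float] = None):
    """Log-normal density of binding/residence times near the mean.

    ``log(tau/tau0)`` is normal with standard deviation ``dE / T`` around
    ``log(tau_median/tau0)`` (default median: ``tau0``), reflecting a
    normal distribution of activation barriers across parallel pathways.
    The median of the density is ``tau_median``; the mean exceeds it by
    ``exp((dE/T)^2 / 2)``.
    """
    if np.any(np.asarray(tau) <= 0):
        raise LandscapeError("tau must be > 0")
    if params.roughness <= 0:
        raise LandscapeError("tau center requires roughness > 0")
    med = params.time_prefactor if tau_median is None else tau_median
    if med <= 0:
        raise LandscapeError("tau_median must be > 0")
    sd = params.roughness / params.temperature
    t = np.asarray(tau, dtype=float)
    y = np.log(t / med)
    return np.exp(-(y**2) / (2.0 * sd**2)) / (t * sd * math.sqrt(2.0 * math.pi))


def pdf_tau_tail(tau, params: LandscapeParams, support: Optional[Tuple[float, float]] = None):
    """Power-law density ``tau**(-1 - T/Tc)`` of the slow-kinetics tail.

    Below ``Tc`` an exponential density of trap depths turns the residence
    times into a fat power-law tail; normalized on a bounded support like
    :func:`pdf_K_tail`.
    """
    if np.any(np.asarray(tau) <= 0):
        raise LandscapeError("tau must be > 0")
    lam = params.rho
    if lam <= 0:
        raise LandscapeError("tau tail requires T/Tc > 0")
    tmin, tmax = support if support is not None else (
        params.time_prefactor,
        params.time_prefactor * POWER_TAIL_SPAN,
    )
    if not (0 < tmin < tmax):
        raise LandscapeError(f"invalid power-tail support [{tmin}, {tmax}]")
    norm = lam / (tmin ** (-lam) - tmax ** (-lam))
    t = np.asarray(tau, dtype=float)
    return np.where((t >= tmin) & (t <= tmax), norm * np.power(t, -1.0 - lam), 0.0)


# ---------------------------------------------------------------------------
# evaluable density objects
# ---------------------------------------------------------------------------

_FAMILIES = {
    "free_energy_center": pdf_free_energy_center,
    "free_energy_tail": pdf_free_energy_tail,
    "logK_center": pdf_logK_center,
    "K_tail": pdf_K_tail,
    "isr_center": pdf_isr_center,
    "isr_tail": pdf_isr_tail,
    "tau_center": pdf_tau_center,
    "tau_tail": pdf_tau_tail,
}


class AnalyticDensity:
    """One analytic law as a normalized, evaluable probability density.

    Wraps a family name, a :class:`LandscapeParams` set, and an explicit
    support; exposes vectorized ``pdf``, grid-based ``cdf``/``ppf`` and
    inverse-CDF ``sample``.  The pdf is exactly zero outside the support.
    """

    def __init__(
        self,
        family: str,
        params: LandscapeParams,
        support: Optional[Tuple[float, float]] = None,
        grid_size: int = 4001,
        **kwargs,
    ):
        if family not in _FAMILIES:
            raise LandscapeError(
                f"unknown density family {family!r}; choose from {sorted(_FAMILIES)}"
            )
        self.family = family
        self.params = params
        self.kwargs = kwargs
        self._fn: Callable = _FAMILIES[family]
        self.support = tuple(support) if support is not None else self._default_support()
        if not self.support[0] < self.support[1]:
            raise LandscapeError(f"empty support {self.support}")
        # K and tau live on multiplicative scales: tabulate on a log grid
        self._log_scale = family in ("K_tail", "tau_center", "tau_tail")
        if self._log_scale:
            lo = max(self.support[0], 1e-300)
            self._grid = np.geomspace(lo, self.support[1], grid_size)
        else:
            self._grid = np.linspace(self.support[0], self.support[1], grid_size)
        pdf_grid = self.pdf(self._grid)
        cdf_grid = integrate.cumulative_trapezoid(pdf_grid, self._grid, initial=0.0)
        self._mass = float(cdf_grid[-1])
        self._cdf_grid = cdf_grid / self._mass if self._mass > 0 else cdf_grid

    def _default_support(self) -> Tuple[float, float]:
        p = self.params
        if self.family == "free_energy_center":
            mu = self.kwargs.get("mean", p.mean_free_energy)
            return (mu - 10 * p.roughness, mu + 10 * p.roughness)
        if self.family == "free_energy_tail":
            Fc = p.cutoff
            return (Fc - 40.0 * p.temperature / p.rho, Fc)
        if self.family == "logK_center":
            mu = self.kwargs.get("mean_logK", 0.0)
            sd = p.roughness / p.temperature
            return (mu - 10 * sd, mu + 10 * sd)
        if self.family == "K_tail":
            return self.kwargs.get("support", (1.0, POWER_TAIL_SPAN))
        if self.family in ("isr_center", "isr_tail"):
            return (0.0, 40.0)
        if self.family == "tau_center":
            med = self.kwargs.get("tau_median", p.time_prefactor)
            sd = p.roughness / p.temperature
            return (med * math.exp(-10 * sd), med * math.exp(10 * sd))
        if self.family == "tau_tail":
            return self.kwargs.get(
                "support", (p.time_prefactor, p.time_prefactor * POWER_TAIL_SPAN)
            )
        raise AssertionError(self.family)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        lo, hi = self.support
        inside = (x >= lo) & (x <= hi)
        vals = np.where(inside, self._fn(np.clip(x, lo, hi), self.params, **self.kwargs), 0.0)
        return vals

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.interp(x, self._grid, self._cdf_grid, left=0.0, right=1.0)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        return np.interp(q, self._cdf_grid, self._grid)

    def sample(self, n: int, rng: np.random.Generator):
        """Inverse-CDF sampling on the tabulated grid."""
        return self.ppf(rng.uniform(size=n))

    def normalization_error(self) -> float:
        """|1 - integral of pdf over support| by adaptive quadrature.

        Multiplicative-scale families are integrated after the substitution
        ``x = exp(y)`` so the quadrature resolves the many-decade support.
        """
        lo, hi = self.support
        if self._log_scale:
            val, _ = integrate.quad(
                lambda y: float(self._fn(math.exp(y), self.params, **self.kwargs))
                * math.exp(y),
                math.log(max(lo, 1e-300)),
                math.log(hi),
                limit=400,
            )
        else:
            val, _ = integrate.quad(
                lambda x: float(self._fn(x, self.params, **self.kwargs)),
                lo,
                hi,
                limit=400,
            )
        return abs(1.0 - val)

    def to_json(self) -> str:
        p = self.params
        payload = {
            "family": self.family,
            "mean_energy": p.mean_energy,
            "roughness": p.roughness,
            "temperature": p.temperature,
            "num_states": p.num_states,
            "entropy": p.entropy,
            "cutoff_free_energy": p.cutoff_free_energy,
            "time_prefactor": p.time_prefactor,
            "support": list(self.support),
            **{k: v for k, v in self.kwargs.items() if not isinstance(v, tuple)},
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_mapping(cls, payload: dict) -> "AnalyticDensity":
        payload = dict(payload)
        family = payload.pop("family")
        support = payload.pop("support", None)
        param_keys = {
            "mean_energy",
            "roughness",
            "temperature",
            "num_states",
            "entropy",
            "cutoff_free_energy",
            "time_prefactor",
        }
        pkw = {k: payload.pop(k) for k in list(payload) if k in param_keys}
        params = LandscapeParams(**{k: v for k, v in pkw.items() if v is not None})
        return cls(family, params, support=support, **payload)


def density(family: str, params: LandscapeParams, **kwargs) -> AnalyticDensity:
    """Factory shortcut for :class:`AnalyticDensity`."""
    return AnalyticDensity(family, params, **kwargs)
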