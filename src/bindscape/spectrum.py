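"""Per-ligand binding spectra and their thermodynamic metrics.

A binding spectrum is the set of pose energies one ligand exhibits
against a receptor (e.g. from exhaustive docking), each pose carrying an
RMSD to the strongest-binding (native) pose.  From a spectrum we compute

* affinity        ``F_n - F_bar``   (native vs mean non-native, <= 0),
* log K           ``(F_n - F_un)/T`` with ``F_un`` the Boltzmann free
  energy of the non-native ensemble,
* ISR             ``|F_n - F_bar| / dF``, the intrinsic specificity
  ratio: the native gap in units of the non-native spread,

and the RMSD-stratified free-energy profile that feeds the kinetics.
``k_B = R = 1``; energies and T in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DegenerateSpectrumError, ProfileError
from .kinetics import FreeEnergyProfile

__all__ = ["BindingSpectrum", "LigandMetrics", "compute_metrics", "stratify_profile"]


@dataclass(frozen=True)
class BindingSpectrum:
    """One ligand's docked poses: (energy, RMSD) states plus a native index.

    The native state must carry the minimum energy (ties broken by lowest
    RMSD); RMSDs are non-negative and measured relative to the native
    pose.
    """

    ligand_id: str
    energies: np.ndarray
    rmsds: np.ndarray
    native_index: int

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        r = np.asarray(self.rmsds, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "rmsds", r)
        if e.ndim != 1 or e.size < 2:
            raise DegenerateSpectrumError("spectrum needs at least 2 states")
        if e.shape != r.shape:
            raise DegenerateSpectrumError("energies and rmsds must align")
        if np.any(r < 0):
            raise DegenerateSpectrumError("RMSDs must be >= 0")
        if not 0 <= self.native_index < e.size:
            raise DegenerateSpectrumError(f"native_index {self.native_index} out of range")
        emin = e.min()
        if e[self.native_index] > emin + 1e-12:
            raise DegenerateSpectrumError("native state must have the minimum energy")
        ties = np.flatnonzero(np.isclose(e, e[self.native_index], atol=1e-12))
        if r[self.native_index] > r[ties].min() + 1e-12:
            raise DegenerateSpectrumError(
                "energy tie must be broken by the lowest-RMSD state"
            )

    @property
    def n_states(self) -> int:
        return int(self.energies.size)

    @property
    def native_energy(self) -> float:
        return float(self.energies[self.native_index])

    @property
    def native_rmsd(self) -> float:
        return float(self.rmsds[self.native_index])


@dataclass(frozen=True)
class LigandMetrics:
    """Thermodynamic summary of one spectrum (all energies in kcal/mol)."""

    ligand_id: str
    F_n: float
    F_mean: float
    dF: float
    F_un: float
    affinity: float
    logK: float
    isr: float
    n_non_native: int


def _non_native_mask(spectrum: BindingSpectrum, exclusion_radius: float) -> np.ndarray:
    mask = np.ones(spectrum.n_states, dtype=bool)
    mask[spectrum.native_index] = False
    if exclusion_radius > 0:
        # poses geometrically indistinguishable from the native one belong
        # to the native basin, not the non-native ensemble
        mask &= spectrum.rmsds > spectrum.native_rmsd + exclusion_radius
        mask[spectrum.native_index] = False
    return mask


def compute_metrics(
    spectrum: BindingSpectrum,
    T: float,
    exclusion_radius: float = 1.0,
    require_isr: bool = True,
) -> LigandMetrics:
    """Affinity, log K and ISR of one binding spectrum.

    Parameters
    ----------
    spectrum:
        The ligand's pose spectrum.
    T:
        Thermal energy (kcal/mol, > 0).
    exclusion_radius:
        Poses within this RMSD (A) of the native pose are treated as part
        of the native basin and excluded from the non-native ensemble.
        Set 0 to keep every non-native pose.
    require_isr:
        If True (default), a zero non-native spread raises
        :class:`DegenerateSpectrumError`; otherwise ISR is reported NaN.

    Notes
    -----
    ``F_bar`` and ``dF`` are the mean and *population* standard deviation
    of the non-native energies (the landscape roughness is a population
    parameter).  ``F_un = -T log sum exp(-E_i/T)`` over the non-native
    states, so ``log K = (F_n - F_un)/T`` is a genuine free-energy
    difference.  All three metrics are invariant under a constant energy
    shift; ISR is additionally invariant under energy scaling.
    """
    if T <= 0:
        raise DegenerateSpectrumError(f"temperature must be > 0, got {T}")
    mask = _non_native_mask(spectrum, exclusion_radius)
    non_native = spectrum.energies[mask]
    if non_native.size < 2:
        raise DegenerateSpectrumError(
            f"ligand {spectrum.ligand_id}: need >= 2 non-native states, "
            f"got {non_native.size}"
        )
    F_n = spectrum.native_energy
    F_mean = float(non_native.mean())
    dF = float(non_native.std())  # population (divide-by-N)
    F_un = float(-T * logsumexp(-non_native / T))
    affinity = F_n - F_mean
    logK = (F_n - F_un) / T
    if dF == 0.0:
        if require_isr:
            raise DegenerateSpectrumError(
                f"ligand {spectrum.ligand_id}: ISR undefined, zero non-native spread"
            )
        isr = float("nan")
    else:
        isr = abs(F_n - F_mean) / dF
    return LigandMetrics(
        ligand_id=spectrum.ligand_id,
        F_n=F_n,
        F_mean=F_mean,
        dF=dF,
        F_un=F_un,
        affinity=affinity,
        logK=logK,
        isr=isr,
        n_non_native=int(non_native.size),
    )


def stratify_profile(
    spectrum: BindingSpectrum,
    T: float,
    bin_width: float,
    D: float = 1.0,
) -> FreeEnergyProfile:
    """RMSD-stratified free-energy profile of one spectrum.

    States are binned by RMSD from the native pose outward; each bin
    carries the Boltzmann free energy ``F(b) = -T log sum exp(-E_i/T)``
    of its states (a single-state bin reproduces that state's energy, two
    degenerate states give ``E - T log 2``).  Empty interior bins are
    filled by linear interpolation between their occupied neighbours; the
    grid of bin centers is returned with the diffusion coefficient
    attached.
    """
    if T <= 0:
        raise ProfileError(f"temperature must be > 0, got {T}")
    if bin_width <= 0:
        raise ProfileError(f"bin_width must be > 0, got {bin_width}")
    r = spectrum.rmsds
    e = spectrum.energies
    lo = float(r.min())
    n_bins = int(np.floor((float(r.max()) - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    which = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    centers = edges[:-1] + bin_width / 2.0
    F = np.full(n_bins, np.nan)
    for b in range(n_bins):
        in_bin = which == b
        if in_bin.any():
            F[b] = -T * logsumexp(-e[in_bin] / T)
    occupied = ~np.isnan(F)
    if occupied.sum() < 2:
        raise ProfileError(
            f"ligand {spectrum.ligand_id}: all states fall in one RMSD bin; "
            "profile too short"
        )
    # interior gaps between occupied bins -> linear interpolation
    F = np.interp(centers, centers[occupied], F[occupied])
    return FreeEnergyProfile(rmsd_grid=centers, F_values=F, D=D)
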