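"""Synthetic ensembles with the statistical structure of docking data.

Three generators cover the three levels of the theory:

* a contact-Hamiltonian sampler (``E = sum J_ij sigma_ij`` with Gaussian
  couplings) demonstrating how landscape roughness ``dE**2 = N dJ**2``
  emerges from many random pairwise contacts;
* a microscopic spectrum generator emulating one ligand's docking run:
  many i.i.d. Gaussian non-native pose energies, one native pose a gap
  below the spectrum minimum, and RMSDs correlated with energy so that
  stratifying by RMSD yields a funneled profile;
* landscape-level samplers drawing per-ligand observables (free energy /
  affinity / log K, exponential-trap residence times) directly from the
  analytic laws, for parameter-recovery studies where the ligand-to-
  ligand spread must equal the nominal roughness.

All generators are reproducible from a root seed; per-ligand streams are
keyed by (seed, ligand_index) so ensembles are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import LandscapeError, ProfileError
from .kinetics import FreeEnergyProfile
from .landscape import LandscapeParams
from .spectrum import BindingSpectrum

__all__ = [
    "ContactModel",
    "EnsembleSpec",
    "sample_contact_energies",
    "generate_spectrum",
    "generate_ensemble",
    "ensemble_to_frame",
    "generate_profile",
    "sample_native_minima",
    "sample_rem_ensemble",
    "sample_exponential_dos_times",
]


# ---------------------------------------------------------------------------
# contact Hamiltonian
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactModel:
    """Pairwise-contact energy model with Gaussian couplings.

    ``contact_map`` flags which atom pairs are in contact (within the
    informational cutoff ``cutoff`` A); the energy of a configuration is
    the sum of the active couplings, each drawn fresh from
    ``Normal(coupling_mean, coupling_sd**2)``.
    """

    contact_map: np.ndarray
    coupling_mean: float = 0.0
    coupling_sd: float = 1.0
    cutoff: float = 4.5

    def __post_init__(self) -> None:
        cm = np.asarray(self.contact_map)
        if not np.isin(cm, (0, 1)).all():
            raise LandscapeError("contact_map entries must be 0 or 1")
        object.__setattr__(self, "contact_map", cm.astype(np.int8))
        if self.coupling_sd < 0:
            raise LandscapeError("coupling_sd must be >= 0")

    @classmethod
    def fully_connected(cls, n_contacts: int, **kwargs) -> "ContactModel":
        if n_contacts < 1:
            raise LandscapeError("n_contacts must be >= 1")
        return cls(contact_map=np.ones(n_contacts, dtype=np.int8), **kwargs)

    @property
    def n_active(self) -> int:
        return int(self.contact_map.sum())


def sample_contact_energies(model: ContactModel, n_samples: int, seed: int) -> np.ndarray:
    """Energies of fresh coupling realizations applied to the contact map.

    By the central limit theorem the energies are Gaussian with mean
    ``n_active * coupling_mean`` and variance ``n_active * coupling_sd**2``
    — the roughness of the landscape grows as the square root of the
    number of contacts.
    """
    if n_samples <= 0:
        raise LandscapeError(f"n_samples must be > 0, got {n_samples}")
    n_active = model.n_active
    if n_active == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    J = rng.normal(model.coupling_mean, model.coupling_sd, size=(n_samples, n_active))
    return J.sum(axis=1)


# ---------------------------------------------------------------------------
# per-ligand docking spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnsembleSpec:
    """Recipe for a synthetic ensemble of per-ligand binding spectra.

    Per ligand: ``states_per_ligand`` non-native pose energies i.i.d.
    ``Normal(mean_energy, roughness**2)``; one native pose at
    ``rmsd_native`` whose energy is the spectrum minimum minus a
    non-negative gap ``|Normal(gap_mean, gap_sd**2)|``; non-native RMSDs
    rise linearly with energy above the minimum (funnel) plus Gaussian
    noise, clipped to (rmsd_native, rmsd_max].
    """

    num_ligands: int = 720
    states_per_ligand: int = 100
    landscape: LandscapeParams = field(
        default_factory=lambda: LandscapeParams(mean_energy=-6.0, roughness=2.0, num_states=100)
    )
    gap_mean: float = 2.0
    gap_sd: float = 0.5
    rmsd_native: float = 1.0
    rmsd_max: float = 10.0
    energy_rmsd_slope: float = 0.8
    rmsd_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_ligands < 1:
            raise LandscapeError("num_ligands must be >= 1")
        if self.states_per_ligand < 2:
            raise LandscapeError("states_per_ligand must be >= 2")
        if self.gap_sd < 0 or self.rmsd_noise_sd < 0:
            raise LandscapeError("standard deviations must be >= 0")
        if not 0 <= self.rmsd_native < self.rmsd_max:
            raise LandscapeError("need 0 <= rmsd_native < rmsd_max")
        if self.energy_rmsd_slope < 0:
            raise LandscapeError("energy_rmsd_slope must be >= 0")


def _ligand_rng(seed: int, ligand_index: int) -> np.random.Generator:
    # counter-keyed stream: independent of generation order
    return np.random.default_rng(np.random.SeedSequence([seed, ligand_index]))


def generate_spectrum(spec: EnsembleSpec, ligand_index: int) -> BindingSpectrum:
    """One ligand's synthetic binding spectrum, deterministic per (seed, index)."""
    if spec.states_per_ligand < 2:
        raise LandscapeError("states_per_ligand must be >= 2")
    rng = _ligand_rng(spec.seed, ligand_index)
    p = spec.landscape
    e_non = rng.normal(p.mean_energy, p.roughness, size=spec.states_per_ligand)
    gap = abs(rng.normal(spec.gap_mean, spec.gap_sd)) if spec.gap_sd > 0 else max(spec.gap_mean, 0.0)
    e_native = e_non.min() - gap
    noise = (
        rng.normal(0.0, spec.rmsd_noise_sd, size=spec.states_per_ligand)
        if spec.rmsd_noise_sd > 0
        else np.zeros(spec.states_per_ligand)
    )
    r_non = spec.rmsd_native + spec.energy_rmsd_slope * (e_non - e_non.min()) + noise
    eps = 1e-9 * max(spec.rmsd_max, 1.0)
    r_non = np.clip(r_non, spec.rmsd_native + eps, spec.rmsd_max)
    energies = np.concatenate(([e_native], e_non))
    rmsds = np.concatenate(([spec.rmsd_native], r_non))
    return BindingSpectrum(
        ligand_id=f"L{ligand_index:05d}",
        energies=energies,
        rmsds=rmsds,
        native_index=0,
    )


def generate_ensemble(spec: EnsembleSpec):
    """All spectra of the ensemble as a list."""
    return [generate_spectrum(spec, i) for i in range(spec.num_ligands)]


def ensemble_to_frame(spectra) -> pd.DataFrame:
    """Long-format table: ligand_id, state_id, energy_kcal_mol, rmsd_A, is_native."""
    rows = []
    for sp in spectra:
        for j in range(sp.n_states):
            rows.append(
                (sp.ligand_id, j, sp.energies[j], sp.rmsds[j], int(j == sp.native_index))
            )
    return pd.DataFrame(
        rows, columns=["ligand_id", "state_id", "energy_kcal_mol", "rmsd_A", "is_native"]
    )


def sample_native_minima(
    params: LandscapeParams,
    n_ligands: int,
    n_states: int,
    seed: int,
    chunk: int = 2_000_000,
) -> np.ndarray:
    """Vectorized per-ligand spectrum minima (no RMSD bookkeeping).

    Equivalent to the native energy of :func:`generate_spectrum` with zero
    gap; used for extreme-value (order-statistics) checks at large
    ensemble sizes.
    """
    if n_ligands < 1 or n_states < 1:
        raise LandscapeError("n_ligands and n_states must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_ligands)
    rows_per_chunk = max(1, chunk // n_states)
    start = 0
    while start < n_ligands:
        stop = min(start + rows_per_chunk, n_ligands)
        block = rng.normal(
            params.mean_energy, params.roughness, size=(stop - start, n_states)
        )
        out[start:stop] = block.min(axis=1)
        start = stop
    return out


# ---------------------------------------------------------------------------
# landscape-level (analytic-law) samplers
# ---------------------------------------------------------------------------

def sample_rem_ensemble(
    params: LandscapeParams,
    n_ligands: int,
    seed: int,
    affinity_mean: Optional[float] = None,
) -> pd.DataFrame:
    """Per-ligand affinity and log K drawn from the Gaussian center laws.

    Each ligand's native free energy carries the full landscape roughness,
    so affinities are ``Normal(affinity_mean, roughness**2)`` (default
    mean: three roughness units below zero) and ``log K = affinity / T``
    has standard deviation ``roughness / T``.  This is the ligand-to-
    ligand variability asserted by the analytic theory; contrast with the
    narrower order-statistics spread of min-of-spectrum affinities from
    :func:`generate_spectrum`.
    """
    if n_ligands < 1:
        raise LandscapeError("n_ligands must be >= 1")
    if params.roughness <= 0:
        raise LandscapeError("sample_rem_ensemble requires roughness > 0")
    mu = -3.0 * params.roughness if affinity_mean is None else affinity_mean
    rng = np.random.default_rng(seed)
    affinity = rng.normal(mu, params.roughness, size=n_ligands)
    logK = affinity / params.temperature
    return pd.DataFrame(
        {
            "ligand_id": [f"L{i:05d}" for i in range(n_ligands)],
            "affinity": affinity,
            "logK": logK,
        }
    )


def sample_exponential_dos_times(
    params: LandscapeParams, n_samples: int, seed: int
) -> np.ndarray:
    """Residence times under an exponential density of trap depths.

    Below the trapping temperature the relevant states are traps with
    depths exponentially distributed on the scale ``Tc``; Arrhenius escape
    ``tau = tau0 exp(depth / T)`` then makes ``log(tau/tau0)`` exponential
    with rate ``T/Tc``, i.e. a power-law time density with exponent
    ``1 + T/Tc``.
    """
    if n_samples < 1:
        raise LandscapeError("n_samples must be >= 1")
    Tc = params.Tc
    rng = np.random.default_rng(seed)
    depths = rng.exponential(scale=Tc, size=n_samples)
    return params.time_prefactor * np.exp(depths / params.temperature)


# ---------------------------------------------------------------------------
# free-energy profiles
# ---------------------------------------------------------------------------

def generate_profile(
    kind: str,
    rmsd_i: float = 1.0,
    rmsd_f: float = 10.0,
    n_points: int = 500,
    slope: float = 0.5,
    roughness_amplitude: float = 1.0,
    roughness_scale: float = 0.5,
    D: float = 1.0,
    seed: int = 0,
) -> FreeEnergyProfile:
    """Synthetic F(RMSD) profiles: flat, linear funnel, or rough funnel.

    ``linear_funnel`` rises with ``slope`` (kcal/mol per A) away from the
    native end; ``rough_funnel`` superimposes seeded Gaussian bumps of
    standard deviation ``roughness_amplitude`` (kcal/mol) and correlation
    length ``roughness_scale`` (A).  Zero amplitude reproduces the linear
    funnel pointwise.
    """
    if n_points < 2:
        raise ProfileError("n_points must be >= 2")
    if rmsd_i >= rmsd_f:
        raise ProfileError("need rmsd_i < rmsd_f")
    grid = np.linspace(rmsd_i, rmsd_f, n_points)
    if kind == "flat":
        F = np.zeros(n_points)
    elif kind in ("linear_funnel", "rough_funnel"):
        F = slope * (grid - rmsd_i)
        if kind == "rough_funnel" and roughness_amplitude > 0:
            rng = np.random.default_rng(seed)
            raw = rng.normal(size=n_points)
            sigma_pts = roughness_scale / (grid[1] - grid[0])
            smooth = ndimage.gaussian_filter1d(raw, sigma=max(sigma_pts, 1e-9), mode="nearest")
            sd = smooth.std()
            if sd > 0:
                F = F + roughness_amplitude * smooth / sd
    else:
        raise ProfileError(
            f"unknown profile kind {kind!r}; choose flat, linear_funnel, rough_funnel"
        )
    return FreeEnergyProfile(rmsd_grid=grid, F_values=F, D=D)
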