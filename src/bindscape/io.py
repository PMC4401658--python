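"""Tabular I/O: every table is TSV with a one-line header."""

from __future__ import annotations

from pathlib import Path
from typing import List

import pandas as pd

from .errors import ConfigError
from .spectrum import BindingSpectrum

ENSEMBLE_COLUMNS = ["ligand_id", "state_id", "energy_kcal_mol", "rmsd_A", "is_native"]


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_ensemble(path) -> List[BindingSpectrum]:
    """Load per-ligand spectra from an ensemble TSV."""
    frame = read_tsv(path)
    missing = [c for c in ENSEMBLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"ensemble table {path} missing columns: {missing}")
    spectra = []
    for ligand_id, grp in frame.groupby("ligand_id", sort=True):
        grp = grp.sort_values("state_id")
        native = grp.index[grp["is_native"] == 1]
        if len(native) != 1:
            raise ConfigError(f"ligand {ligand_id}: exactly one native state required")
        native_pos = int(grp.index.get_indexer(native)[0])
        spectra.append(
            BindingSpectrum(
                ligand_id=str(ligand_id),
                energies=grp["energy_kcal_mol"].to_numpy(),
                rmsds=grp["rmsd_A"].to_numpy(),
                native_index=native_pos,
            )
        )
    return spectra


def read_profile(path):
    """Read a free-energy profile TSV (rmsd_A, F_kcal_mol[, D])."""
    from .kinetics import FreeEnergyProfile

    frame = read_tsv(path)
    for col in ("rmsd_A", "F_kcal_mol"):
        if col not in frame.columns:
            raise ConfigError(f"profile table {path} missing column {col}")
    D = float(frame["D"].iloc[0]) if "D" in frame.columns else 1.0
    return FreeEnergyProfile(
        rmsd_grid=frame["rmsd_A"].to_numpy(),
        F_values=frame["F_kcal_mol"].to_numpy(),
        D=D,
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
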