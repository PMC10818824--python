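"""Titration series: one ligand's concentration ladder with fluorescence readouts.

A fluorescence quenching titration holds the protein concentration fixed
and steps up the ligand (quencher) concentration; the C = 0 point defines
the unquenched intensity F0.  Readouts are either a scalar intensity at
the emission maximum or a full emission scan per point.

CSV layouts
-----------
Scalar mode: columns ``ligand_id,conc_mol_per_L,intensity``.
Scan mode (long format): ``ligand_id,conc_mol_per_L,wavelength_nm,intensity``.
Both require a header; ``#`` lines are comments (the simulator records its
seed there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .spectra import EmissionScan

__all__ = ["TitrationSeries", "read_titration_csv", "write_titration_csv"]


@dataclass(frozen=True)
class TitrationSeries:
    """Concentration ladder with fluorescence intensities for one ligand.

    Parameters
    ----------
    ligand_id : str
        Compound label (e.g. ``"PFOS"``).
    concentrations : array-like
        Ligand concentrations in mol/L.  Exactly one entry must be 0 (the
        blank that defines F0); the rest must be strictly positive and
        strictly increasing.
    intensities : array-like
        Fluorescence intensities, one per concentration, all > 0.
    scans : list of EmissionScan or None, optional
        Full emission scan per point (scan mode); ``None`` entries allowed.
    protein_conc : float, optional
        Protein concentration in mol/L (constant across the ladder).
    """

    ligand_id: str
    concentrations: np.ndarray
    intensities: np.ndarray
    scans: tuple[EmissionScan | None, ...] | None = None
    protein_conc: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        f = np.asarray(self.intensities, dtype=float)
        if c.shape != f.shape or c.ndim != 1:
            raise ValidationError("concentrations and intensities must be equal-length 1-D")
        n_zero = int(np.sum(c == 0))
        if n_zero != 1:
            raise ValidationError(
                f"series {self.ligand_id!r}: exactly one C=0 point required, got {n_zero}"
            )
        if c[0] != 0:
            order = np.argsort(c, kind="stable")
            c, f = c[order], f[order]
            if self.scans is not None:
                object.__setattr__(
                    self, "scans", tuple(self.scans[i] for i in order)
                )
        nonzero = c[1:]
        if np.any(nonzero <= 0) or np.any(np.diff(nonzero) <= 0):
            raise ValidationError(
                f"series {self.ligand_id!r}: nonzero concentrations must be "
                "strictly positive and strictly increasing"
            )
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            raise ValidationError(
                f"series {self.ligand_id!r}: all intensities must be finite and > 0"
            )
        if self.scans is not None and len(self.scans) != c.size:
            raise ValidationError("one scan slot per titration point required")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "intensities", f)

    @property
    def f0(self) -> float:
        """Unquenched intensity (the C = 0 reading)."""
        return float(self.intensities[0])

    def __len__(self) -> int:
        return self.concentrations.size

    @property
    def has_scans(self) -> bool:
        return self.scans is not None and all(s is not None for s in self.scans)

    def scan_at(self, conc: float) -> EmissionScan | None:
        """The emission scan recorded at concentration ``conc`` (exact match)."""
        if self.scans is None:
            return None
        idx = np.flatnonzero(self.concentrations == conc)
        return self.scans[int(idx[0])] if idx.size else None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ligand_id: str | None = None,
                       protein_conc: float | None = None) -> "TitrationSeries":
        """Build a series from a scalar- or scan-mode dataframe."""
        if ligand_id is not None:
            df = df[df["ligand_id"] == ligand_id]
        elif df["ligand_id"].nunique() != 1:
            raise ValidationError("dataframe holds multiple ligands; pass ligand_id")
        lig = str(df["ligand_id"].iloc[0])
        if "wavelength_nm" in df.columns:
            concs, intens, scans = [], [], []
            for conc, grp in df.groupby("conc_mol_per_L", sort=True):
                grp = grp.sort_values("wavelength_nm")
                scan = EmissionScan(grp["wavelength_nm"].to_numpy(float),
                                    grp["intensity"].to_numpy(float))
                concs.append(float(conc))
                intens.append(float(scan.intensities.max()))
                scans.append(scan)
            return cls(lig, np.array(concs), np.array(intens), tuple(scans),
                       protein_conc)
        df = df.sort_values("conc_mol_per_L")
        return cls(lig, df["conc_mol_per_L"].to_numpy(float),
                   df["intensity"].to_numpy(float), None, protein_conc)


def read_titration_csv(path: str | Path) -> dict[str, TitrationSeries]:
    """Read a titration CSV (scalar or scan mode) into per-ligand series."""
    df = pd.read_csv(path, comment="#")
    scalar_cols = {"ligand_id", "conc_mol_per_L", "intensity"}
    if not scalar_cols.issubset(df.columns):
        raise FormatError(
            f"{path}: titration CSV must have columns {sorted(scalar_cols)} "
            "(plus wavelength_nm in scan mode)"
        )
    return {
        str(lig): TitrationSeries.from_dataframe(grp)
        for lig, grp in df.groupby("ligand_id", sort=True)
    }


def write_titration_csv(series: TitrationSeries, path: str | Path,
                        header_comment: str | None = None) -> None:
    """Write one series in the layout :func:`read_titration_csv` expects."""
    if series.has_scans:
        rows = []
        for conc, scan in zip(series.concentrations, series.scans):
            for wl, it in zip(scan.wavelengths, scan.intensities):
                rows.append((series.ligand_id, conc, wl, it))
        df = pd.DataFrame(rows, columns=["ligand_id", "conc_mol_per_L",
                                         "wavelength_nm", "intensity"])
    else:
        df = pd.DataFrame({
            "ligand_id": series.ligand_id,
            "conc_mol_per_L": series.concentrations,
            "intensity": series.intensities,
        })
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
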