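"""Reference data for ten PFASs binding to human serum albumin.

Published fitted coefficients from a fluorescence titration study of
three legacy long-chain PFASs (PFOA, PFOS, PFHxS), three short-chain
alternatives (PFPrS, PFBS, PFBA) and four novel alternatives
(9Cl-PF3ONS, 11Cl-PF3OUdS, HFPO-DA, NaDONA) against HSA, together with
compound metadata and an AutoDock-Vina docking summary for the same ten
compounds.  The raw instrument data behind the lines were not deposited;
the coefficients let noiseless titration series be reconstructed exactly
(see :func:`quenchfit.simulate.series_from_sv_line`), which is how the
package's worked examples and validation recompute every published
constant.

``SV_LINES`` maps ligand to (slope, intercept, reported R^2) of the
modified Stern-Volmer line y = F0/(F0-F) vs x = 1/C; ``LB_LINES`` maps
ligand to (n_sites, lg_ka, reported R^2) of the double-log binding line.
"""

from __future__ import annotations

from .pipeline import CompoundMeta, DockingRecord

__all__ = ["SV_LINES", "LB_LINES", "COMPOUNDS", "DOCKING_RECORDS", "LIGANDS"]

# slope (mol/L), intercept, reported R^2
SV_LINES: dict[str, tuple[float, float, float]] = {
    "PFOA": (0.0005035, 0.635, 0.9996),
    "PFOS": (0.0007969, 0.2456, 0.9977),
    "PFHxS": (0.0005641, 0.4741, 0.9946),
    "PFPrS": (0.0004813, 0.7054, 0.9977),
    "PFBS": (0.0005327, 0.6013, 0.9989),
    "PFBA": (0.0003302, 0.9979, 0.9985),
    "9Cl-PF3ONS": (0.0006538, 0.7081, 0.9948),
    "11Cl-PF3OUdS": (0.0005285, 0.6068, 0.9956),
    "HFPO-DA": (0.0005095, 0.8051, 0.9945),
    "NaDONA": (0.0005118, 0.6743, 0.9994),
}

# n_sites (slope), lg KA (intercept), reported R^2
LB_LINES: dict[str, tuple[float, float, float]] = {
    "PFOA": (0.6811, 2.0143, 0.9991),
    "PFOS": (0.8694, 2.5962, 0.9896),
    "PFHxS": (0.7328, 2.1985, 0.9754),
    "PFPrS": (0.6487, 1.9001, 0.9939),
    "PFBS": (0.6986, 2.0663, 0.9931),
    "PFBA": (0.4692, 1.3089, 0.9792),
    "9Cl-PF3ONS": (0.724, 2.0686, 0.9952),
    "11Cl-PF3OUdS": (0.7102, 2.1059, 0.9966),
    "HFPO-DA": (0.6214, 1.7708, 0.9794),
    "NaDONA": (0.6718, 1.9689, 0.9982),
}

COMPOUNDS: dict[str, CompoundMeta] = {
    "PFOA": CompoundMeta("PFOA", "PFCA", "legacy_long", 7),
    "PFOS": CompoundMeta("PFOS", "PFSA", "legacy_long", 8),
    "PFHxS": CompoundMeta("PFHxS", "PFSA", "legacy_long", 6),
    "PFPrS": CompoundMeta("PFPrS", "PFSA", "short_alternative", 3),
    "PFBS": CompoundMeta("PFBS", "PFSA", "short_alternative", 4),
    "PFBA": CompoundMeta("PFBA", "PFCA", "short_alternative", 3),
    "9Cl-PF3ONS": CompoundMeta("9Cl-PF3ONS", "Cl-PFESA", "novel_alternative", 8),
    "11Cl-PF3OUdS": CompoundMeta("11Cl-PF3OUdS", "Cl-PFESA", "novel_alternative", 10),
    "HFPO-DA": CompoundMeta("HFPO-DA", "ether-PFCA", "novel_alternative", 5),
    "NaDONA": CompoundMeta("NaDONA", "ether-PFCA", "novel_alternative", 6),
}

DOCKING_RECORDS: list[DockingRecord] = [
    DockingRecord("PFOA", -7.6, 1, ("MET548",)),
    DockingRecord("PFOS", -8.3, 1, ("ASN405",)),
    DockingRecord("PFHxS", -7.5, 2, ("ASN405", "TYR401")),
    DockingRecord("PFBA", -6.2, 4, ("ARG117",)),
    DockingRecord("PFBS", -6.4, 1, ("LYS137",)),
    DockingRecord("PFPrS", -6.2, 2, ("LEU14", "ASN18")),
    DockingRecord("NaDONA", -7.3, 1, ("LEU155",)),
    DockingRecord("HFPO-DA", -7.0, 1, ("SER287",)),
    DockingRecord("9Cl-PF3ONS", -7.8, 4, ("ARG410", "ALA406")),
    DockingRecord("11Cl-PF3OUdS", -7.9, 3, ("ARG410",)),
]

LIGANDS: tuple[str, ...] = tuple(SV_LINES)
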