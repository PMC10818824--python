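"""Per-compound analysis orchestration and cross-compound comparison.

One compound's titration series runs through the modified Stern-Volmer
fit, the quenching-mechanism call, and the double-log binding fit; rows
for several compounds are ranked by binding constant, summarised by
chemical family and chain class, checked against declared ordering
assertions and, optionally, joined with a molecular-docking summary to
report a rank concordance between the spectroscopic KA and the docking
binding energy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, QuenchFitError, ValidationError
from .models import (DEFAULT_TAU0_S, BindingResults, QuenchMechanism,
                     SternVolmerResults, fit_lineweaver_burk,
                     fit_modified_stern_volmer)
from .spectra import peak_shift
from .titration import TitrationSeries

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundMeta",
    "DockingRecord",
    "CompoundRow",
    "ComparisonReport",
    "run_compound_analysis",
    "compare_compounds",
    "merge_docking",
    "read_docking_csv",
]

FAMILIES = ("PFSA", "PFCA", "Cl-PFESA", "ether-PFCA")
CHAIN_CLASSES = ("legacy_long", "short_alternative", "novel_alternative")


@dataclass(frozen=True)
class CompoundMeta:
    """Chemical metadata for one PFAS."""

    ligand_id: str
    family: str
    chain_class: str
    perfluorinated_carbon_count: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"family must be one of {FAMILIES}")
        if self.chain_class not in CHAIN_CLASSES:
            raise ValidationError(f"chain_class must be one of {CHAIN_CLASSES}")
        if self.perfluorinated_carbon_count < 1:
            raise ValidationError("perfluorinated_carbon_count must be >= 1")


@dataclass(frozen=True)
class DockingRecord:
    """One row of an ingested docking summary (never computed here)."""

    ligand_id: str
    binding_energy: float  # kcal/mol; negative = favorable
    hydrogen_bonds: int
    residues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.hydrogen_bonds < 0:
            raise ValidationError("hydrogen_bonds must be >= 0")


@dataclass(frozen=True)
class CompoundRow:
    """Full analysis output for one compound."""

    meta: CompoundMeta
    sv: SternVolmerResults
    mechanism: QuenchMechanism
    binding: BindingResults
    emission_shift_nm: float | None = None
    docking: DockingRecord | None = None

    @property
    def ligand_id(self) -> str:
        return self.meta.ligand_id

    def to_dict(self) -> dict:
        d = {
            "ligand_id": self.ligand_id,
            "family": self.meta.family,
            "chain_class": self.meta.chain_class,
            "perfluorinated_carbons": self.meta.perfluorinated_carbon_count,
            "stern_volmer": self.sv.to_dict(),
            "mechanism": self.mechanism.label,
            "binding": self.binding.to_dict(),
        }
        if self.emission_shift_nm is not None:
            d["emission_shift_nm"] = self.emission_shift_nm
        if self.docking is not None:
            d["docking"] = {
                "binding_energy_kcal_mol": self.docking.binding_energy,
                "hydrogen_bonds": self.docking.hydrogen_bonds,
                "residues": list(self.docking.residues),
            }
        return d


def run_compound_analysis(series: TitrationSeries,
                          tau0: float = DEFAULT_TAU0_S,
                          meta: CompoundMeta | None = None) -> CompoundRow:
    """Run the full quenching/binding analysis for one compound.

    Fits the modified Stern-Volmer model, classifies the quenching
    mechanism from Kq, fits the double-log binding model, and records the
    emission-maximum shift when the series carries full scans.
    """
    if meta is None:
        meta = CompoundMeta(series.ligand_id, "PFCA", "legacy_long", 1)
    try:
        sv = fit_modified_stern_volmer(series, tau0=tau0)
        binding = fit_lineweaver_burk(series)
    except QuenchFitError as exc:
        raise type(exc)(f"[{series.ligand_id}] {exc}") from exc
    shift = peak_shift(series) if series.has_scans else None
    return CompoundRow(meta=meta, sv=sv, mechanism=sv.mechanism,
                       binding=binding, emission_shift_nm=shift)


@dataclass(frozen=True)
class ComparisonReport:
    """Cross-compound comparison: rankings, group means, assertions, concordance.

    ``ranking`` lists ligand ids by decreasing KA (ties broken
    lexicographically); ``group_mean_lg_ka_by_family`` and ``..._by_class``
    average lg KA (log domain, so one large binder does not dominate);
    ``assertion_results`` maps each declared ordering assertion to whether
    it held; ``docking_concordance`` is the Spearman rank correlation
    (midranks) between KA and the negated docking binding energy, or None
    when fewer than two compounds are matched.
    """

    rows: tuple[CompoundRow, ...]
    ranking: tuple[str, ...]
    group_mean_lg_ka_by_family: dict[str, float]
    group_mean_lg_ka_by_class: dict[str, float]
    assertion_results: dict[str, bool] = field(default_factory=dict)
    docking_concordance: float | None = None

    def row(self, ligand_id: str) -> CompoundRow:
        for r in self.rows:
            if r.ligand_id == ligand_id:
                return r
        raise KeyError(ligand_id)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "ligand_id": r.ligand_id,
                "family": r.meta.family,
                "chain_class": r.meta.chain_class,
                "sv_equation": r.sv.fitted_equation,
                "sv_r_squared": r.sv.r_squared,
                "kq_L_per_mol_s": r.sv.kq,
                "mechanism": r.mechanism.label,
                "lb_equation": r.binding.fitted_equation,
                "lb_r_squared": r.binding.r_squared,
                "ka_L_per_mol": r.binding.ka,
                "n_sites": r.binding.n_sites,
            }
            if r.docking is not None:
                rec["binding_energy_kcal_mol"] = r.docking.binding_energy
            recs.append(rec)
        df = pd.DataFrame(recs)
        order = {lig: i for i, lig in enumerate(self.ranking)}
        return df.sort_values("ligand_id", key=lambda s: s.map(order)).reset_index(drop=True)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "rows": [r.to_dict() for r in self.rows],
            "ranking_by_ka": list(self.ranking),
            "group_mean_lg_ka_by_family": self.group_mean_lg_ka_by_family,
            "group_mean_lg_ka_by_chain_class": self.group_mean_lg_ka_by_class,
            "assertions": self.assertion_results,
            "docking_concordance_spearman": self.docking_concordance,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def summary(self) -> str:
        lines = ["Cross-compound comparison", "=" * 52,
                 "ranking by KA (desc): " + " > ".join(self.ranking), ""]
        df = self.to_dataframe()
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.4g}"))
        if self.assertion_results:
            lines.append("")
            for expr, ok in self.assertion_results.items():
                lines.append(f"assertion {expr!r}: {'PASS' if ok else 'FAIL'}")
        if self.docking_concordance is not None:
            lines.append("")
            lines.append(
                f"Spearman concordance KA vs -binding_energy: "
                f"{self.docking_concordance:.3f}")
        return "\n".join(lines)


def _parse_assertion(expr: str) -> list[str]:
    """``"PFOS > PFHxS > PFOA"`` -> ["PFOS", "PFHxS", "PFOA"]."""
    parts = [p.strip() for p in expr.split(">")]
    if len(parts) < 2 or any(not p for p in parts):
        raise ValidationError(f"cannot parse ordering assertion {expr!r}")
    return parts


def compare_compounds(rows, expected_orderings=None) -> ComparisonReport:
    """Assemble a :class:`ComparisonReport` from per-compound rows.

    Parameters
    ----------
    rows : iterable of CompoundRow
        At least two, with unique ligand ids.
    expected_orderings : iterable of str, optional
        Chained ordering assertions on KA such as
        ``"PFOS > PFHxS > PFOA"``; each is evaluated strictly.
    """
    rows = tuple(rows)
    if len(rows) < 2:
        raise ValidationError("need >= 2 compounds to compare")
    ids = [r.ligand_id for r in rows]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ligand_id in comparison rows")

    ranked = sorted(rows, key=lambda r: (-r.binding.ka, r.ligand_id))
    ranking = tuple(r.ligand_id for r in ranked)

    by_family: dict[str, list[float]] = {}
    by_class: dict[str, list[float]] = {}
    for r in rows:
        by_family.setdefault(r.meta.family, []).append(r.binding.lg_ka)
        by_class.setdefault(r.meta.chain_class, []).append(r.binding.lg_ka)
    mean_family = {k: float(np.mean(v)) for k, v in by_family.items()}
    mean_class = {k: float(np.mean(v)) for k, v in by_class.items()}

    ka = {r.ligand_id: r.binding.ka for r in rows}
    assertion_results: dict[str, bool] = {}
    for expr in expected_orderings or ():
        chain = _parse_assertion(expr)
        missing = [p for p in chain if p not in ka]
        if missing:
            raise ValidationError(f"assertion {expr!r} names unknown ligand(s) {missing}")
        assertion_results[expr] = all(
            ka[a] > ka[b] for a, b in zip(chain, chain[1:]))

    return ComparisonReport(rows=rows, ranking=ranking,
                            group_mean_lg_ka_by_family=mean_family,
                            group_mean_lg_ka_by_class=mean_class,
                            assertion_results=assertion_results)


def merge_docking(report: ComparisonReport, docking) -> ComparisonReport:
    """Join docking records onto a report and compute rank concordance.

    Concordance is the Spearman correlation (midranks for ties) between
    KA and the negated binding energy over matched compounds; with fewer
    than two matches it is reported as absent (None).  Docking records
    naming unknown ligands are dropped with a warning.
    """
    by_id = {d.ligand_id: d for d in docking}
    known = {r.ligand_id for r in report.rows}
    for lig in sorted(set(by_id) - known):
        logger.warning("docking record for unknown ligand %s dropped", lig)
    new_rows = tuple(
        CompoundRow(meta=r.meta, sv=r.sv, mechanism=r.mechanism,
                    binding=r.binding, emission_shift_nm=r.emission_shift_nm,
                    docking=by_id.get(r.ligand_id))
        for r in report.rows)
    matched = [r for r in new_rows if r.docking is not None]
    concordance: float | None = None
    if len(matched) >= 2:
        ka = [r.binding.ka for r in matched]
        affinity = [-r.docking.binding_energy for r in matched]
        rho = stats.spearmanr(ka, affinity).statistic
        concordance = float(rho)
    return ComparisonReport(
        rows=new_rows, ranking=report.ranking,
        group_mean_lg_ka_by_family=report.group_mean_lg_ka_by_family,
        group_mean_lg_ka_by_class=report.group_mean_lg_ka_by_class,
        assertion_results=report.assertion_results,
        docking_concordance=concordance)


def read_docking_csv(path: str | Path) -> list[DockingRecord]:
    """Read ``ligand_id,binding_energy_kcal_mol,hydrogen_bonds,residues`` CSV.

    ``residues`` is a semicolon-separated list.
    """
    df = pd.read_csv(path, comment="#")
    required = {"ligand_id", "binding_energy_kcal_mol", "hydrogen_bonds"}
    if not required.issubset(df.columns):
        from .exceptions import FormatError
        raise FormatError(f"{path}: docking CSV must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        residues = ()
        if "residues" in df.columns and isinstance(row.get("residues"), str):
            residues = tuple(s.strip() for s in row["residues"].split(";") if s.strip())
        records.append(DockingRecord(str(row["ligand_id"]),
                                     float(row["binding_energy_kcal_mol"]),
                                     int(row["hydrogen_bonds"]), residues))
    return records
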