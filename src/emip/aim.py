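"""Bond-critical-point (QTAIM) tables: classification and Espinosa energies.

This module consumes *tabulated* bond-critical-point (BCP) properties —
electron density ρ, its Laplacian ∇²ρ, and the potential/kinetic/total
energy densities V, G, H, all in atomic units — and derives two things:

* an interaction classification: closed-shell (non-covalent) contacts
  show ∇²ρ > 0 with |H| close to zero; shared-shell (covalent) bonds
  show ∇²ρ < 0; everything else is flagged ambiguous;
* the Espinosa estimate of the interaction energy, BE = V/2, converted
  from hartree to kcal mol⁻¹ (negative = stabilizing).

Wavefunction analysis and BCP searching are out of scope; tables come
from external QTAIM software or from the synthetic generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .constants import HARTREE_TO_KCAL

#: default "close to zero" window on |H|, atomic units
DEFAULT_H_TOL = 0.005

CLASSIFICATIONS = ("non_covalent", "covalent", "ambiguous")

MANDATORY_COLUMNS = ("cavity_id", "atom_a", "atom_b", "rho", "laplacian", "V")


class BCPError(ValueError):
    pass


@dataclass
class BCPRecord:
    """Properties of one bond critical point (atomic units)."""

    cavity_id: str
    atom_a: str
    atom_b: str
    rho: float
    laplacian: float
    V: float
    G: float | None = None
    H: float | None = None
    classification: str | None = None
    BE: float | None = None           # kcal mol⁻¹

    def __post_init__(self) -> None:
        if not self.rho > 0:
            raise BCPError(
                f"BCP {self.atom_a}-{self.atom_b}: rho must be > 0, "
                f"got {self.rho}")
        if self.H is None and self.G is not None:
            self.H = self.V + self.G
        if self.H is not None and self.G is not None:
            if abs(self.H - (self.V + self.G)) > 1e-6:
                raise BCPError(
                    f"BCP {self.atom_a}-{self.atom_b}: H={self.H} "
                    f"inconsistent with V+G={self.V + self.G}")
        if self.H is None:
            raise BCPError(
                f"BCP {self.atom_a}-{self.atom_b}: need H or G to fix the "
                "total energy density")


def classify_interaction(record: BCPRecord,
                         h_tol: float = DEFAULT_H_TOL) -> str:
    """Classify a BCP from (∇²ρ, H): pure function of its arguments.

    ``non_covalent`` iff ∇²ρ > 0 and |H| ≤ h_tol; ``covalent`` iff
    ∇²ρ < 0; otherwise ``ambiguous``.
    """
    if record.laplacian > 0 and abs(record.H) <= h_tol:
        return "non_covalent"
    if record.laplacian < 0:
        return "covalent"
    return "ambiguous"


def espinosa_be(record: BCPRecord) -> float:
    """Espinosa binding energy BE = V/2, in kcal mol⁻¹, sign preserved."""
    return 0.5 * record.V * HARTREE_TO_KCAL


def annotate(records: Iterable[BCPRecord],
             h_tol: float = DEFAULT_H_TOL) -> list[BCPRecord]:
    """Fill classification and BE on every record, in place."""
    out = list(records)
    for r in out:
        r.classification = classify_interaction(r, h_tol)
        r.BE = espinosa_be(r)
    return out


def read_bcp_table(path, h_tol: float = DEFAULT_H_TOL) -> list[BCPRecord]:
    """Read a BCP property CSV (atomic units) into validated records.

    Mandatory columns: ``cavity_id, atom_a, atom_b, rho, laplacian, V``;
    optional: ``G, H`` (H is computed from V+G when absent).  Records are
    annotated with classification and Espinosa BE.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise BCPError(f"{path}: missing mandatory columns {missing}")
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in ("G", "H"):
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = float(row[col])
        try:
            rec = BCPRecord(
                cavity_id=str(row["cavity_id"]),
                atom_a=str(row["atom_a"]),
                atom_b=str(row["atom_b"]),
                rho=float(row["rho"]),
                laplacian=float(row["laplacian"]),
                V=float(row["V"]),
                **kwargs)
        except (TypeError, ValueError) as exc:
            raise BCPError(f"{path}: row {idx}: {exc}") from exc
        records.append(rec)
    return annotate(records, h_tol)


def write_bcp_table(records: Sequence[BCPRecord], path) -> None:
    pd.DataFrame([
        {"cavity_id": r.cavity_id, "atom_a": r.atom_a, "atom_b": r.atom_b,
         "rho": r.rho, "laplacian": r.laplacian, "V": r.V, "G": r.G,
         "H": r.H, "classification": r.classification, "BE": r.BE}
        for r in records]).to_csv(path, index=False)


def cavity_interaction_summary(records: Sequence[BCPRecord]) -> pd.DataFrame:
    """Per-cavity summary: non-covalent count, ΣBE and mean |BE|.

    A ``TOTAL`` row aggregates over all cavities.  Records must be
    annotated (see :func:`annotate` / :func:`read_bcp_table`).
    """
    if not records:
        raise BCPError("cavity_interaction_summary needs at least one record")
    if any(r.classification is None or r.BE is None for r in records):
        raise BCPError("records must be annotated before summarizing")
    df = pd.DataFrame([
        {"cavity_id": r.cavity_id, "classification": r.classification,
         "BE": r.BE} for r in records])
    rows = []
    for cavity_id, grp in df.groupby("cavity_id", sort=True):
        nc = grp[grp.classification == "non_covalent"]
        rows.append({
            "cavity_id": cavity_id,
            "n_noncovalent": len(nc),
            "sum_BE": float(nc.BE.sum()),
            "mean_abs_BE": float(nc.BE.abs().mean()) if len(nc) else math.nan,
        })
    nc_all = df[df.classification == "non_covalent"]
    rows.append({
        "cavity_id": "TOTAL",
        "n_noncovalent": len(nc_all),
        "sum_BE": float(nc_all.BE.sum()),
        "mean_abs_BE": (float(nc_all.BE.abs().mean())
                        if len(nc_all) else math.nan),
    })
    return pd.DataFrame(rows)
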