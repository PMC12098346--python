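"""ΔΔG significance classification and thermodynamic conversion.

Predicted stability / binding-affinity changes (ΔΔG, kcal/mol) are inputs;
this module classifies their magnitude against two thresholds and converts a
binding ΔΔG into the implied dissociation-constant fold change:

* ``|ΔΔG| > 1.0`` kcal/mol       -> ``significant`` (strict inequality)
* ``0.6 < |ΔΔG| <= 1.0``          -> ``above_noise``
* ``|ΔΔG| <= 0.6``                -> ``within_noise``

The 0.6 kcal/mol noise threshold is approximately RT at 25 °C
(R = 1.9872e-3 kcal/(mol·K), T = 298.15 K, RT ≈ 0.593), and
Kd fold change = exp(|ΔΔG| / RT) — about 5.4-fold per 1 kcal/mol.
Classification uses the magnitude; the sign (destabilising vs stabilising)
is carried separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ThermoConstants",
    "DdgThresholds",
    "rt",
    "kd_fold_change",
    "classify",
    "batch_report",
    "read_ddg_table",
    "CLASS_LABELS",
]

CLASS_LABELS = ("significant", "above_noise", "within_noise")

GAS_CONSTANT_KCAL = 1.9872042586e-3  # kcal / (mol K)


@dataclass(frozen=True)
class ThermoConstants:
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15  # 25 °C

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative (kelvin)")


@dataclass(frozen=True)
class DdgThresholds:
    significant: float = 1.0  # kcal/mol
    noise: float = 0.6  # kcal/mol, ~RT at 25 °C

    def __post_init__(self) -> None:
        if not self.significant >= self.noise > 0:
            raise ValueError("thresholds must satisfy significant >= noise > 0")


def rt(constants: ThermoConstants | None = None) -> float:
    """Thermal energy RT in kcal/mol (≈0.593 at 298.15 K, rounding to 0.6)."""
    c = constants or ThermoConstants()
    return c.gas_constant * c.temperature


def kd_fold_change(ddg: float, constants: ThermoConstants | None = None) -> float:
    """exp(|ΔΔG| / RT): multiplicative change in dissociation constant.

    Always >= 1; 1 kcal/mol at 25 °C gives ≈5.4 (the conventional "~5-fold").
    """
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    return math.exp(abs(ddg) / rt(constants))


def classify(ddg: float, thresholds: DdgThresholds | None = None) -> str:
    """Classify |ΔΔG| against the significance and noise thresholds.

    Both comparisons at the breakpoints are strict from above: exactly 1.0
    is *not* significant ("larger than 1 kcal/mol") and exactly 0.6 is
    within noise.
    """
    if not math.isfinite(ddg):
        raise ValueError("ddg must be finite")
    t = thresholds or DdgThresholds()
    mag = abs(ddg)
    if mag > t.significant:
        return "significant"
    if mag > t.noise:
        return "above_noise"
    return "within_noise"


DDG_COLUMNS = ["complex_id", "mutation", "ddg_stability", "ddg_affinity"]


def read_ddg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"complex_id": str, "mutation": str})
    missing = set(DDG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ddg table {path} missing columns: {sorted(missing)}")
    return df


def batch_report(
    records: pd.DataFrame,
    thresholds: DdgThresholds | None = None,
    constants: ThermoConstants | None = None,
) -> tuple[pd.DataFrame, str]:
    """Classify every row for stability and affinity and add Kd fold change.

    Non-numeric ΔΔG entries produce a row-level ``error`` note and leave the
    remaining rows intact.  Output rows are ordered by (complex_id,
    mutation) for reproducibility.  Returns (table, text summary).
    """
    thresholds = thresholds or DdgThresholds()
    constants = constants or ThermoConstants()
    rows = []
    for _, row in records.iterrows():
        out = {
            "complex_id": row.get("complex_id", ""),
            "mutation": row.get("mutation", ""),
        }
        try:
            stab = float(row["ddg_stability"])
            aff = float(row["ddg_affinity"])
            if not (math.isfinite(stab) and math.isfinite(aff)):
                raise ValueError("non-finite ddg")
        except (TypeError, ValueError, KeyError) as exc:
            out.update(
                ddg_stability=row.get("ddg_stability"),
                ddg_affinity=row.get("ddg_affinity"),
                class_stability="error",
                class_affinity="error",
                kd_fold_change=float("nan"),
                sign_stability="",
                sign_affinity="",
                error=str(exc),
            )
            rows.append(out)
            continue
        out.update(
            ddg_stability=stab,
            ddg_affinity=aff,
            class_stability=classify(stab, thresholds),
            class_affinity=classify(aff, thresholds),
            kd_fold_change=kd_fold_change(aff, constants),
            sign_stability="destabilizing" if stab > 0 else ("neutral" if stab == 0 else "stabilizing"),
            sign_affinity="destabilizing" if aff > 0 else ("neutral" if aff == 0 else "stabilizing"),
            error="",
        )
        rows.append(out)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["complex_id", "mutation"], kind="mergesort").reset_index(drop=True)
    summary = _summarise(table, thresholds, constants)
    return table, summary


def _summarise(table: pd.DataFrame, thresholds: DdgThresholds, constants: ThermoConstants) -> str:
    lines = [
        f"ddG classification (significant > {thresholds.significant} kcal/mol, "
        f"noise <= {thresholds.noise} kcal/mol; RT = {rt(constants):.4f} kcal/mol "
        f"at {constants.temperature} K)",
        f"rows: {len(table)}",
    ]
    if table.empty:
        return "\n".join(lines) + "\n"
    ok = table[table["class_stability"] != "error"]
    for col, label in (("class_stability", "stability"), ("class_affinity", "affinity")):
        counts = ok[col].value_counts().to_dict()
        parts = ", ".join(f"{counts.get(k, 0)} {k}" for k in CLASS_LABELS)
        lines.append(f"{label}: {parts}")
    n_err = int((table["class_stability"] == "error").sum())
    if n_err:
        lines.append(f"errors: {n_err} row(s) with non-numeric ddG")
    if not ok.empty and (ok["class_stability"] == "significant").all() and (
        ok["class_affinity"] != "significant"
    ).all():
        lines.append(
            "pattern: stability change significant in every complex while the "
            "affinity change stays at or near the thermal noise threshold"
        )
    return "\n".join(lines) + "\n"
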