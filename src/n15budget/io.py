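"""CSV serialization of plant records, truth tables and budgets.

The plant table is long-format: one row per organ per plant, with the
plant-level metadata and phenotypes repeated.  Enrichment is accepted as
either ``atom_percent_15N`` or ``delta15N_permil`` — exactly one of the
two must be present (non-null) on each enriched row; δ values are
converted on read with the configured standard.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .budget import NBudget, OrganSample, PlantRecord, MATURITY_ORGANS
from .isotopes import IsotopeConfig, delta_to_atom_percent

__all__ = [
    "records_to_frame",
    "frame_to_records",
    "write_plants_csv",
    "read_plants_csv",
    "budgets_to_frame",
]

PLANT_COLUMNS = [
    "plant_id",
    "block",
    "greenhouse",
    "veg_treatment",
    "rep_treatment",
    "label_phase",
    "stage",
    "organ",
    "dry_mass_g",
    "n_concentration",
    "atom_percent_15N",
    "spikelet_count",
    "kernel_number",
    "grain_mass_g",
]


def records_to_frame(records: Sequence[PlantRecord]) -> pd.DataFrame:
    """Long-format organ table from plant records."""
    rows = []
    for rec in records:
        for organ in rec.organs:
            rows.append(
                {
                    "plant_id": rec.plant_id,
                    "block": rec.block,
                    "greenhouse": rec.greenhouse,
                    "veg_treatment": rec.veg_treatment,
                    "rep_treatment": rec.rep_treatment,
                    "label_phase": rec.label_phase,
                    "stage": rec.stage,
                    "organ": organ.organ,
                    "dry_mass_g": organ.dry_mass,
                    "n_concentration": organ.n_concentration,
                    "atom_percent_15N": organ.enrichment,
                    "spikelet_count": rec.spikelet_count,
                    "kernel_number": rec.kernel_number,
                    "grain_mass_g": rec.grain_mass,
                }
            )
    return pd.DataFrame(rows, columns=PLANT_COLUMNS)


def _enrichment_from_row(row: pd.Series, config: IsotopeConfig) -> float | None:
    has_ap = "atom_percent_15N" in row.index and pd.notna(row["atom_percent_15N"])
    has_delta = "delta15N_permil" in row.index and pd.notna(row["delta15N_permil"])
    if has_ap and has_delta:
        raise ValueError(
            "row carries both atom_percent_15N and delta15N_permil; "
            "exactly one enrichment column may be populated"
        )
    if has_ap:
        return float(row["atom_percent_15N"])
    if has_delta:
        return delta_to_atom_percent(
            float(row["delta15N_permil"]), config.standard_atom_percent
        )
    return None


def frame_to_records(
    frame: pd.DataFrame, config: IsotopeConfig | None = None
) -> list[PlantRecord]:
    """Parse a long-format organ table back into plant records."""
    config = config or IsotopeConfig()
    if "atom_percent_15N" not in frame.columns and "delta15N_permil" not in frame.columns:
        raise ValueError(
            "plant table needs an enrichment column: atom_percent_15N or "
            "delta15N_permil"
        )
    records = []
    for plant_id, group in frame.groupby("plant_id", sort=False):
        first = group.iloc[0]
        organs = [
            OrganSample(
                organ=str(row["organ"]),
                dry_mass=float(row["dry_mass_g"]),
                n_concentration=float(row["n_concentration"]),
                enrichment=_enrichment_from_row(row, config),
            )
            for _, row in group.iterrows()
        ]
        records.append(
            PlantRecord(
                plant_id=str(plant_id),
                block=str(first["block"]),
                greenhouse=str(first["greenhouse"]),
                veg_treatment=str(first["veg_treatment"]),
                rep_treatment=str(first["rep_treatment"]),
                label_phase=str(first["label_phase"]),
                stage=str(first["stage"]),
                organs=organs,
                spikelet_count=(
                    float(first["spikelet_count"])
                    if pd.notna(first.get("spikelet_count"))
                    else None
                ),
                kernel_number=(
                    float(first["kernel_number"])
                    if pd.notna(first.get("kernel_number"))
                    else None
                ),
                grain_mass=(
                    float(first["grain_mass_g"])
                    if pd.notna(first.get("grain_mass_g"))
                    else None
                ),
            )
        )
    return records


def write_plants_csv(records: Sequence[PlantRecord], path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def read_plants_csv(
    path: str | Path, config: IsotopeConfig | None = None
) -> list[PlantRecord]:
    return frame_to_records(pd.read_csv(path), config)


def budgets_to_frame(
    budgets: dict[str, NBudget], records: Sequence[PlantRecord] | None = None
) -> pd.DataFrame:
    """One row per plant with the budget outputs and per-organ partition
    columns; raw (unrounded) values throughout."""
    meta = {r.plant_id: r for r in records} if records else {}
    rows = []
    for plant_id, b in budgets.items():
        rec = meta.get(plant_id)
        row: dict = {
            "plant_id": plant_id,
            "veg_treatment": rec.veg_treatment if rec else None,
            "rep_treatment": rec.rep_treatment if rec else None,
            "label_phase": b.label_phase,
            "q_wps_used": b.q_wps_used,
            "q_wpm_total_n": b.q_wpm_total_n,
            "q_grain_n": b.q_grain_n,
            "excess_wpm": b.excess_wpm,
            "rem_pct": b.rem_pct,
            "q_rem_grain": b.q_rem_grain,
            "grain_rem_pct": b.grain_rem_pct,
            "post_uptake": b.post_uptake,
            "flags": ";".join(b.flags),
        }
        for organ in MATURITY_ORGANS:
            row[f"post_pct_{organ}"] = (
                b.post_pct_by_organ.get(organ) if b.post_pct_by_organ else None
            )
            row[f"q_post_{organ}"] = (
                b.q_post_by_organ.get(organ) if b.q_post_by_organ else None
            )
        rows.append(row)
    return pd.DataFrame(rows)
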