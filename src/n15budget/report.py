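"""Treatment-cell aggregation and table rendering.

Every published summary in this design is a mean ± SE over a
(vegetative × reproductive) treatment cell, followed for some headline
numbers by an *unweighted average of cell means* over a named subset of
cells (the "stress" cells, the low-N cells, ...).  Both constructions are
provided; report rounding (1 d.p. for percentages, 2 d.p. for grams)
happens only in the rendered text output — machine-readable CSVs keep raw
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .budget import REP_TREATMENTS, VEG_TREATMENTS, PlantRecord
from .phenotypes import kernel_weight, round_half_away_from_zero

__all__ = [
    "TreatmentSummary",
    "treatment_summary",
    "stress_average",
    "render_tables",
    "phenotype_frame",
]

_VEG_ORDER = {v: i for i, v in enumerate(VEG_TREATMENTS)}
_REP_ORDER = {r: i for i, r in enumerate(REP_TREATMENTS + ("none",))}


@dataclass(frozen=True)
class TreatmentSummary:
    """Mean ± SE of one metric in one treatment cell."""

    metric: str
    veg_treatment: str
    rep_treatment: str
    n: int
    mean: float
    se: float | None  # None when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se is not None and self.se < 0:
            raise ValueError("SE must be >= 0")


def treatment_summary(
    frame: pd.DataFrame,
    value: str,
    by: Sequence[str] = ("veg_treatment", "rep_treatment"),
) -> list[TreatmentSummary]:
    """Group means and standard errors (sample SD / √n) of ``frame[value]``.

    Groups are ordered stably: high-N before low-N vegetative treatment,
    then NW → nW → Nw → nw.  NaN values are dropped within groups; empty
    groups are omitted with a warning.
    """
    if value not in frame.columns:
        raise ValueError(f"no column {value!r} in frame")
    out: list[TreatmentSummary] = []
    for keys, group in frame.groupby(list(by), sort=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        values = group[value].dropna().to_numpy(dtype=float)
        if values.size == 0:
            warnings.warn(
                f"group {keys} has no values for {value!r}; omitted", stacklevel=2
            )
            continue
        n = int(values.size)
        se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else None
        named = dict(zip(by, keys))
        out.append(
            TreatmentSummary(
                metric=value,
                veg_treatment=str(named.get("veg_treatment", "")),
                rep_treatment=str(named.get("rep_treatment", "")),
                n=n,
                mean=float(values.mean()),
                se=se,
            )
        )
    out.sort(
        key=lambda s: (
            _REP_ORDER.get(s.rep_treatment, 99),
            _VEG_ORDER.get(s.veg_treatment, 99),
        )
    )
    return out


def summaries_to_frame(summaries: Iterable[TreatmentSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": s.metric,
                "veg_treatment": s.veg_treatment,
                "rep_treatment": s.rep_treatment,
                "n": s.n,
                "mean": s.mean,
                "se": s.se,
            }
            for s in summaries
        ]
    )


def stress_average(
    cell_means: Mapping[str, float], cells: Sequence[str]
) -> float:
    """Unweighted mean of named cell means — the construction behind the
    cross-treatment headline numbers (e.g. averaging the three stress
    cells nW, Nw, nw of one vegetative treatment)."""
    if not cells:
        raise ValueError("need at least one cell")
    missing = [c for c in cells if c not in cell_means]
    if missing:
        raise ValueError(f"unknown cells: {missing}")
    return float(np.mean([cell_means[c] for c in cells]))


def phenotype_frame(records: Sequence[PlantRecord]) -> pd.DataFrame:
    """Per-plant phenotype table (maturity plants): yield, kernel number,
    kernel weight, total biomass."""
    rows = []
    for rec in records:
        if rec.stage != "maturity":
            continue
        kw = (
            kernel_weight(rec.grain_mass, rec.kernel_number)
            if rec.grain_mass is not None
            and rec.kernel_number
            else None
        )
        rows.append(
            {
                "plant_id": rec.plant_id,
                "veg_treatment": rec.veg_treatment,
                "rep_treatment": rec.rep_treatment,
                "grain_yield_g": rec.grain_mass,
                "kernel_number": rec.kernel_number,
                "kernel_weight_mg": kw,
                "spikelet_count": rec.spikelet_count,
                "total_biomass_g": sum(o.dry_mass for o in rec.organs),
            }
        )
    return pd.DataFrame(rows)


def _rounded(df: pd.DataFrame, pct_cols: Sequence[str], g_cols: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for c in pct_cols:
        if c in out.columns:
            out[c] = out[c].map(
                lambda x: round_half_away_from_zero(x, 1) if pd.notna(x) else x
            )
    for c in g_cols:
        if c in out.columns:
            out[c] = out[c].map(
                lambda x: round_half_away_from_zero(x, 2) if pd.notna(x) else x
            )
    return out


def render_tables(
    budget_frame: pd.DataFrame,
    phenotypes: pd.DataFrame,
    out_dir: str | Path,
) -> list[Path]:
    """Write the four summary tables (CSV plus plain text).

    ``silking``: Q(wps) reference and spikelets per vegetative treatment;
    ``grain_sources``: Grain_rem % and grams remobilized per cell
    (vegetative-labelled plants); ``post_partition``: post-silking uptake
    and its per-organ partition per cell (reproductive-labelled plants);
    ``yield``: yield components per cell.  CSVs carry raw values; the
    ``.txt`` companions apply report rounding (1 d.p. %, 2 d.p. g).
    """
    if budget_frame.empty:
        raise ValueError("budget frame is empty; nothing to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, pct_cols=(), g_cols=()) -> None:
        csv_path = out_dir / f"{name}.csv"
        df.to_csv(csv_path, index=False)
        txt_path = out_dir / f"{name}.txt"
        txt_path.write_text(
            _rounded(df, pct_cols, g_cols).to_string(index=False) + "\n"
        )
        written.extend([csv_path, txt_path])

    veg_ref = (
        budget_frame.groupby("veg_treatment", sort=False)["q_wps_used"]
        .first()
        .reset_index()
        .rename(columns={"q_wps_used": "q_wps_reference_g"})
    )
    emit("silking", veg_ref, g_cols=["q_wps_reference_g"])

    veg_labelled = budget_frame[budget_frame["label_phase"] == "vegetative"]
    grain_sources = summaries_to_frame(
        treatment_summary(veg_labelled, "grain_rem_pct")
    ).merge(
        summaries_to_frame(treatment_summary(veg_labelled, "q_rem_grain")),
        on=["veg_treatment", "rep_treatment"],
        suffixes=("_grain_rem_pct", "_q_rem_grain"),
    )
    emit(
        "grain_sources",
        grain_sources,
        pct_cols=["mean_grain_rem_pct", "se_grain_rem_pct"],
        g_cols=["mean_q_rem_grain", "se_q_rem_grain"],
    )

    rep_labelled = budget_frame[budget_frame["label_phase"] == "reproductive"]
    post_cols = ["post_uptake"] + [
        c for c in rep_labelled.columns if c.startswith("post_pct_")
    ]
    pieces = []
    for col in post_cols:
        piece = summaries_to_frame(treatment_summary(rep_labelled, col))
        piece = piece.rename(columns={"mean": f"mean_{col}", "se": f"se_{col}"})
        piece = piece.drop(columns=["metric", "n"])
        pieces.append(piece.set_index(["veg_treatment", "rep_treatment"]))
    post_table = pd.concat(pieces, axis=1).reset_index()
    emit(
        "post_partition",
        post_table,
        pct_cols=[c for c in post_table.columns if "post_pct" in c],
        g_cols=["mean_post_uptake", "se_post_uptake"],
    )

    pheno_cols = [
        "grain_yield_g",
        "kernel_number",
        "kernel_weight_mg",
        "total_biomass_g",
    ]
    pieces = []
    for col in pheno_cols:
        piece = summaries_to_frame(treatment_summary(phenotypes, col))
        piece = piece.rename(columns={"mean": f"mean_{col}", "se": f"se_{col}"})
        piece = piece.drop(columns=["metric", "n"])
        pieces.append(piece.set_index(["veg_treatment", "rep_treatment"]))
    yield_table = pd.concat(pieces, axis=1).reset_index()
    emit("yield", yield_table, g_cols=[c for c in yield_table.columns if "mean_" in c or "se_" in c])

    return written
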