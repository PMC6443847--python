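"""Synthetic dual-phase ¹⁵N labelling experiment.

Emulates a greenhouse maize experiment in an inert, leachable growing
medium: two vegetative N levels (high ``Nveg`` / low ``nveg``) crossed
after silking with four reproductive N×water treatments (``NW``, ``nW``,
``Nw``, ``nw``); each labelled plant receives ¹⁵N-enriched KNO₃ in exactly
one phase (vegetative or reproductive), and the medium is leached at
silking so vegetative label cannot be taken up later.  A silking-harvested
cohort provides the Q(wps) reference; maturity plants provide the organ
N pools and enrichments the budget pipeline consumes.

The label model is the minimal one consistent with the mass-balance
assumptions: within each phase the plant-incorporated N is a single
well-mixed pool, a fraction φ of which is fertilizer-derived, so every
organ built from that pool shares one enrichment (organ-specific mixing
exists only behind :func:`perturb_assumptions`, for bias studies).
Remobilization moves pre-silking N from vegetative organs into the grain
with fixed per-organ source weights; post-silking uptake is allocated by
per-treatment partition vectors.

Measurement noise: multiplicative lognormal (unit mean) on organ N
content via the N concentration, additive Gaussian on atom% ¹⁵N —
typical tissue-sampling and IRMS error scales.  Every generated plant is
exactly mass- and isotope-consistent before noise, and the ground truth
of each plant's fluxes is returned alongside the records, so parameter
recovery is testable at any noise level.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .budget import (
    MATURITY_ORGANS,
    REP_TREATMENTS,
    SILKING_ORGANS,
    VEG_TREATMENTS,
    OrganSample,
    PlantRecord,
)
from .isotopes import IsotopeConfig

__all__ = [
    "SimConfig",
    "SimConfigError",
    "ExperimentTruth",
    "generate_experiment",
    "leach_event",
    "perturb_assumptions",
]

CELLS = [(v, r) for r in REP_TREATMENTS for v in VEG_TREATMENTS]

TRUTH_COLUMNS = [
    "plant_id",
    "veg_treatment",
    "rep_treatment",
    "label_phase",
    "stage",
    "q_wps",
    "rem_pct",
    "q_rem_grain",
    "post_uptake",
    "q_grain",
    "q_post_grain",
    "grain_rem_pct",
    "q_wpm",
] + [f"post_pct_{o}" for o in MATURITY_ORGANS]


class SimConfigError(ValueError):
    """Infeasible or inconsistent simulation configuration."""


def _normalized(d: Mapping[str, float]) -> dict[str, float]:
    total = sum(d.values())
    if total <= 0:
        raise SimConfigError("partition vector has non-positive total")
    return {k: v / total for k, v in d.items()}


def _default_silking_partition() -> dict[str, dict[str, float]]:
    # stalk-heavy storage under luxury N: stalk N 1.0 vs 0.5 g of the
    # 2.76 / 1.61 g totals, remainder mostly in leaves
    return {
        "Nveg": _normalized(
            {"leaves": 1.30, "stalk": 1.00, "roots": 0.36, "reproductive": 0.10}
        ),
        "nveg": _normalized(
            {"leaves": 0.85, "stalk": 0.50, "roots": 0.21, "reproductive": 0.05}
        ),
    }


def _default_rem_fraction_mean() -> dict[tuple[str, str], float]:
    # grams remobilized per cell divided by the treatment Q(wps)
    rem_g = {
        ("Nveg", "NW"): 1.59,
        ("Nveg", "nW"): 1.67,
        ("Nveg", "Nw"): 1.63,
        ("Nveg", "nw"): 1.42,
        ("nveg", "NW"): 0.91,
        ("nveg", "nW"): 0.82,
        ("nveg", "Nw"): 0.77,
        ("nveg", "nw"): 0.59,
    }
    q_wps = {"Nveg": 2.76, "nveg": 1.61}
    return {cell: rem_g[cell] / q_wps[cell[0]] for cell in rem_g}


def _default_post_uptake_mean() -> dict[tuple[str, str], float]:
    return {
        ("Nveg", "NW"): 1.35,
        ("Nveg", "nW"): 0.58,
        ("Nveg", "Nw"): 0.61,
        ("Nveg", "nw"): 0.67,
        ("nveg", "NW"): 1.75,
        ("nveg", "nW"): 0.50,
        ("nveg", "Nw"): 0.69,
        ("nveg", "nw"): 0.58,
    }


def _default_post_uptake_sd() -> dict[tuple[str, str], float]:
    # SE x sqrt(n), n = 4 labelled plants per cell and phase
    se = {
        ("Nveg", "NW"): 0.23,
        ("Nveg", "nW"): 0.15,
        ("Nveg", "Nw"): 0.26,
        ("Nveg", "nw"): 0.12,
        ("nveg", "NW"): 0.31,
        ("nveg", "nW"): 0.15,
        ("nveg", "Nw"): 0.14,
        ("nveg", "nw"): 0.07,
    }
    return {cell: s * 2.0 for cell, s in se.items()}


def _default_post_partition() -> dict[tuple[str, str], dict[str, float]]:
    # (grain, cob/husk, stalk, roots, green leaves, senesced leaves), %
    rows = {
        ("Nveg", "NW"): (64.6, 1.7, 20.3, 11.5, 0.3, 2.1),
        ("nveg", "NW"): (32.7, 14.3, 30.9, 14.7, 5.1, 2.2),
        ("Nveg", "nW"): (69.0, 1.8, 19.1, 7.1, 1.5, 1.5),
        ("nveg", "nW"): (86.4, 3.0, 4.6, 4.0, 0.6, 1.5),
        ("Nveg", "Nw"): (25.6, 1.7, 35.7, 33.9, 1.9, 1.2),
        ("nveg", "Nw"): (30.4, 9.3, 19.8, 37.3, 2.5, 0.6),
        ("Nveg", "nw"): (17.0, 2.4, 20.3, 58.9, 0.7, 0.7),
        ("nveg", "nw"): (72.4, 2.6, 5.6, 16.1, 2.7, 0.9),
    }
    organs = (
        "grain",
        "repro_nongrain",
        "stalk",
        "roots",
        "green_leaves",
        "senesced_leaves",
    )
    return {
        cell: _normalized(dict(zip(organs, vals))) for cell, vals in rows.items()
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic experiment.

    Between-plant SDs are reconstructed from published standard errors
    (SD = SE·√n at the table's n); noise SDs are measurement-error
    conventions.  ``q_wps_*`` are g N plant⁻¹ at silking;
    ``rem_fraction_mean`` is the fraction of pre-silking N remobilized to
    the grain; ``post_uptake_*`` are g N taken up after silking; partition
    dictionaries are fractions summing to 1; ``phi_pre``/``phi_post`` are
    the fractions of phase-incorporated N that are fertilizer-derived.
    """

    # pre-silking N uptake (g) per vegetative treatment
    q_wps_mean: dict[str, float] = field(
        default_factory=lambda: {"Nveg": 2.76, "nveg": 1.61}
    )
    q_wps_sd: dict[str, float] = field(
        default_factory=lambda: {"Nveg": 1.04, "nveg": 0.66}
    )
    # allocation of pre-silking N over silking organ groups
    silking_partition: dict[str, dict[str, float]] = field(
        default_factory=_default_silking_partition
    )
    # true remobilized fraction of pre-silking N, per (veg, rep) cell
    rem_fraction_mean: dict[tuple[str, str], float] = field(
        default_factory=_default_rem_fraction_mean
    )
    rem_fraction_sd: float = 0.03
    # post-silking uptake (g), per cell
    post_uptake_mean: dict[tuple[str, str], float] = field(
        default_factory=_default_post_uptake_mean
    )
    post_uptake_sd: dict[tuple[str, str], float] = field(
        default_factory=_default_post_uptake_sd
    )
    # allocation of post-silking N over maturity organs, per cell
    post_partition: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_post_partition
    )
    # which organs supply the remobilized N (stalk and leaves dominate)
    remobilization_source_weights: dict[str, float] = field(
        default_factory=lambda: _normalized(
            {"leaves": 0.45, "stalk": 0.45, "roots": 0.08, "reproductive": 0.02}
        )
    )
    # fraction of residual (non-remobilized) leaf N that is senesced by
    # maturity, per reproductive treatment
    leaf_senesced_fraction: dict[str, float] = field(
        default_factory=lambda: {"NW": 0.40, "nW": 0.55, "Nw": 0.50, "nw": 0.60}
    )
    # labelled-fertilizer fraction of phase-incorporated N
    phi_pre: dict[str, float] = field(
        default_factory=lambda: {"Nveg": 0.10, "nveg": 0.17}
    )
    phi_post: dict[str, float] = field(
        default_factory=lambda: {"NW": 0.35, "nW": 0.65, "Nw": 0.45, "nw": 0.70}
    )
    # label doses: mg 15N applied per phase, at label_atom_percent
    label_atom_percent: float = 10.0
    dose_pre_n15_mg: float = 40.0
    dose_post_n15_mg: float = 90.0
    # leaching of residual vegetative label at silking
    leach_efficiency: float = 0.99
    residual_uptake_fraction: float = 0.5
    # measurement noise
    noise_sd_atom_percent: float = 0.002
    noise_cv_n_content: float = 0.05
    # assumption perturbations (off by default)
    n_loss_fraction: float = 0.0
    label_mixing_multipliers: dict[str, float] | None = None
    # N concentrations (fraction of dry mass) used to back out dry masses
    n_conc_maturity: dict[str, float] = field(
        default_factory=lambda: {
            "green_leaves": 0.015,
            "senesced_leaves": 0.007,
            "stalk": 0.006,
            "roots": 0.008,
            "repro_nongrain": 0.005,
        }
    )
    n_conc_silking: dict[str, float] = field(
        default_factory=lambda: {
            "leaves": 0.025,
            "stalk": 0.012,
            "roots": 0.012,
            "reproductive": 0.020,
        }
    )
    # yield phenotypes per cell (counts, g)
    spikelet_mean: dict[str, float] = field(
        default_factory=lambda: {"Nveg": 805.0, "nveg": 656.0}
    )
    spikelet_sd: dict[str, float] = field(
        default_factory=lambda: {"Nveg": 87.0, "nveg": 73.0}
    )
    kernel_mean: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Nveg", "NW"): 575.0,
            ("nveg", "NW"): 532.0,
            ("Nveg", "nW"): 615.0,
            ("nveg", "nW"): 512.0,
            ("Nveg", "Nw"): 548.0,
            ("nveg", "Nw"): 401.0,
            ("Nveg", "nw"): 500.0,
            ("nveg", "nw"): 371.0,
        }
    )
    kernel_sd: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Nveg", "NW"): 73.0,
            ("nveg", "NW"): 132.0,
            ("Nveg", "nW"): 42.0,
            ("nveg", "nW"): 120.0,
            ("Nveg", "Nw"): 44.0,
            ("nveg", "Nw"): 125.0,
            ("Nveg", "nw"): 105.0,
            ("nveg", "nw"): 73.0,
        }
    )
    grain_mass_mean: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Nveg", "NW"): 133.0,
            ("nveg", "NW"): 129.7,
            ("Nveg", "nW"): 139.2,
            ("nveg", "nW"): 107.4,
            ("Nveg", "Nw"): 107.5,
            ("nveg", "Nw"): 78.1,
            ("Nveg", "nw"): 91.3,
            ("nveg", "nw"): 66.6,
        }
    )
    grain_mass_sd: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("Nveg", "NW"): 21.8,
            ("nveg", "NW"): 31.6,
            ("Nveg", "nW"): 13.5,
            ("nveg", "nW"): 21.8,
            ("Nveg", "Nw"): 15.4,
            ("nveg", "Nw"): 22.5,
            ("Nveg", "nw"): 15.7,
            ("nveg", "nw"): 12.0,
        }
    )
    # design sizes
    blocks_labelled: int = 4
    blocks_unlabelled: int = 2
    maturity_replicates: int = 1  # labelled plants per (block, cell, phase)
    unlabelled_per_block_cell: int = 1
    silking_plants_per_block: int = 2  # per vegetative treatment
    isotope: IsotopeConfig = field(default_factory=IsotopeConfig)

    def validate(self) -> None:
        for veg in VEG_TREATMENTS:
            for mapping, name in (
                (self.q_wps_mean, "q_wps_mean"),
                (self.q_wps_sd, "q_wps_sd"),
                (self.phi_pre, "phi_pre"),
            ):
                if veg not in mapping:
                    raise SimConfigError(f"{name} missing entry for {veg!r}")
            part = self.silking_partition[veg]
            if set(part) != set(SILKING_ORGANS):
                raise SimConfigError(f"silking_partition[{veg!r}] organ mismatch")
            if abs(sum(part.values()) - 1.0) > 1e-8:
                raise SimConfigError(f"silking_partition[{veg!r}] must sum to 1")
        if abs(sum(self.remobilization_source_weights.values()) - 1.0) > 1e-8:
            raise SimConfigError("remobilization_source_weights must sum to 1")
        for cell in CELLS:
            part = self.post_partition[cell]
            if set(part) != set(MATURITY_ORGANS):
                raise SimConfigError(f"post_partition[{cell}] organ mismatch")
            if abs(sum(part.values()) - 1.0) > 1e-8:
                raise SimConfigError(f"post_partition[{cell}] must sum to 1")
            if not 0.0 <= self.rem_fraction_mean[cell] <= 1.0:
                raise SimConfigError(f"rem_fraction_mean[{cell}] not in [0,1]")
            cap = self.rem_cap(cell[0])
            if self.rem_fraction_mean[cell] > cap:
                raise SimConfigError(
                    f"rem_fraction_mean[{cell}]={self.rem_fraction_mean[cell]:.3f} "
                    f"would remobilize more N than a source pool holds "
                    f"(cap {cap:.3f})"
                )
        mult = self.label_mixing_multipliers or {}
        for veg in VEG_TREATMENTS:
            worst = self.phi_pre[veg] * max([1.0, *mult.values()])
            if not 0.0 <= worst <= 1.0:
                raise SimConfigError(
                    "phi_pre x label_mixing_multipliers must stay within [0,1]"
                )
        for rep in REP_TREATMENTS:
            if not 0.0 <= self.phi_post[rep] <= 1.0:
                raise SimConfigError(f"phi_post[{rep!r}] not in [0,1]")
            if not 0.0 <= self.leaf_senesced_fraction[rep] <= 1.0:
                raise SimConfigError(f"leaf_senesced_fraction[{rep!r}] not in [0,1]")
        for name in (
            "leach_efficiency",
            "residual_uptake_fraction",
            "n_loss_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimConfigError(f"{name} must lie in [0,1]")
        for name in ("noise_sd_atom_percent", "noise_cv_n_content", "rem_fraction_sd"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")

    def rem_cap(self, veg: str) -> float:
        """Largest remobilizable fraction of pre-silking N that leaves every
        source pool non-negative given the source weights."""
        caps = [
            self.silking_partition[veg][o] / w
            for o, w in self.remobilization_source_weights.items()
            if w > 0
        ]
        return min(1.0, *caps)

    def noiseless(self) -> "SimConfig":
        """An idealized copy: no measurement noise, no between-plant
        variation, perfect leaching — every mass-balance assumption holds
        exactly, so the budget must recover the truth to round-off."""
        return dataclasses.replace(
            self,
            q_wps_sd={v: 0.0 for v in self.q_wps_sd},
            rem_fraction_sd=0.0,
            post_uptake_sd={c: 0.0 for c in self.post_uptake_sd},
            spikelet_sd={v: 0.0 for v in self.spikelet_sd},
            kernel_sd={c: 0.0 for c in self.kernel_sd},
            grain_mass_sd={c: 0.0 for c in self.grain_mass_sd},
            noise_sd_atom_percent=0.0,
            noise_cv_n_content=0.0,
            leach_efficiency=1.0,
        )


@dataclass
class ExperimentTruth:
    """Ground-truth fluxes of every generated plant (one row each)."""

    frame: pd.DataFrame

    def for_plant(self, plant_id: str) -> pd.Series:
        rows = self.frame[self.frame["plant_id"] == plant_id]
        if rows.empty:
            raise KeyError(plant_id)
        return rows.iloc[0]

    def validate_mass_consistency(self, atol: float = 1e-9) -> None:
        """Assert grain N = remobilized N + post-silking grain N on every
        maturity plant."""
        m = self.frame[self.frame["stage"] == "maturity"]
        resid = m["q_grain"] - (m["q_rem_grain"] + m["q_post_grain"])
        if not np.all(np.abs(resid.to_numpy()) <= atol):
            raise AssertionError("truth table is not mass-consistent")


def leach_event(residual_label_n: float, efficiency: float = 0.99) -> float:
    """Leaching of residual labelled fertilizer from the growing medium at
    silking: returns (1 − efficiency) × residual.

    The inert calcined-clay medium holds no N of its own, so a 30-min
    flush removes nearly all unabsorbed label (efficiency ≈ 0.99 measured
    by medium N content); without it, vegetative label remaining in the
    medium would be taken up after silking and bias the remobilization
    estimate."""
    if residual_label_n < 0:
        raise SimConfigError("residual label mass must be >= 0")
    if not 0.0 <= efficiency <= 1.0:
        raise SimConfigError("leach efficiency must lie in [0,1]")
    return residual_label_n * (1.0 - efficiency)


def perturb_assumptions(
    config: SimConfig,
    which: str,
    *,
    n_loss: float = 0.05,
    multipliers: Mapping[str, float] | None = None,
) -> SimConfig:
    """Return a config that violates one stated mass-balance assumption.

    ``n_loss``: a fraction of whole-plant N is lost between silking and
    maturity (e.g. volatilization), biasing estimated post-silking uptake
    low by about the lost mass.  ``nonuniform_label``: the pre-silking
    label is not uniformly mixed across organs; per-silking-organ
    multipliers scale the labelled fraction, biasing the remobilization
    estimate with a sign set by which source organs are over-enriched.
    """
    if which == "n_loss":
        return dataclasses.replace(config, n_loss_fraction=n_loss)
    if which == "nonuniform_label":
        mult = dict(
            multipliers
            or {"leaves": 1.10, "stalk": 1.30, "roots": 0.50, "reproductive": 1.00}
        )
        unknown = set(mult) - set(SILKING_ORGANS)
        if unknown:
            raise SimConfigError(f"unknown silking organs in multipliers: {unknown}")
        return dataclasses.replace(config, label_mixing_multipliers=mult)
    raise SimConfigError(f"unknown perturbation {which!r}")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean multiplicative noise with the given coefficient of
    variation."""
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _clip_draw(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float | None = None) -> float:
    value = float(rng.normal(mean, sd)) if sd > 0 else mean
    if hi is None:
        return max(value, lo)
    return min(max(value, lo), hi)


def _blocks(config: SimConfig) -> list[tuple[str, str, bool]]:
    """(block id, greenhouse, labelled) triples; blocks are split evenly
    across two greenhouses as in the nested design."""
    out: list[tuple[str, str, bool]] = []
    for i in range(config.blocks_labelled):
        gh = "G1" if i < (config.blocks_labelled + 1) // 2 else "G2"
        out.append((f"L{i + 1}", gh, True))
    for i in range(config.blocks_unlabelled):
        gh = "G1" if i < (config.blocks_unlabelled + 1) // 2 else "G2"
        out.append((f"U{i + 1}", gh, False))
    return out


def _silking_plant(
    config: SimConfig, rng: np.random.Generator, plant_id: str, block: str,
    greenhouse: str, veg: str
) -> tuple[PlantRecord, dict]:
    base = config.isotope.baseline_atom_percent
    q_wps = _clip_draw(rng, config.q_wps_mean[veg], config.q_wps_sd[veg], 0.1)
    organs = []
    for organ in SILKING_ORGANS:
        q = q_wps * config.silking_partition[veg][organ]
        conc_true = config.n_conc_silking[organ]
        conc = min(conc_true * _lognormal_factor(rng, config.noise_cv_n_content), 0.1)
        enrich = base + (
            float(rng.normal(0.0, config.noise_sd_atom_percent))
            if config.noise_sd_atom_percent > 0
            else 0.0
        )
        organs.append(
            OrganSample(
                organ=organ,
                dry_mass=q / conc_true,
                n_concentration=conc,
                enrichment=enrich,
            )
        )
    spikelets = round(
        _clip_draw(rng, config.spikelet_mean[veg], config.spikelet_sd[veg], 1.0)
    )
    record = PlantRecord(
        plant_id=plant_id,
        block=block,
        greenhouse=greenhouse,
        veg_treatment=veg,
        rep_treatment="none",
        label_phase="unlabelled",
        stage="silking",
        organs=organs,
        spikelet_count=spikelets,
    )
    truth = {
        "plant_id": plant_id,
        "veg_treatment": veg,
        "rep_treatment": "none",
        "label_phase": "unlabelled",
        "stage": "silking",
        "q_wps": q_wps,
    }
    return record, truth


def _maturity_plant(
    config: SimConfig,
    rng: np.random.Generator,
    plant_id: str,
    block: str,
    greenhouse: str,
    veg: str,
    rep: str,
    label_phase: str,
) -> tuple[PlantRecord, dict]:
    base = config.isotope.baseline_atom_percent
    label_ap = config.label_atom_percent
    cell = (veg, rep)

    # -- true fluxes ------------------------------------------------------
    q_wps = _clip_draw(rng, config.q_wps_mean[veg], config.q_wps_sd[veg], 0.1)
    rem = _clip_draw(
        rng,
        config.rem_fraction_mean[cell],
        config.rem_fraction_sd,
        0.0,
        config.rem_cap(veg),
    )
    uptake = _clip_draw(
        rng, config.post_uptake_mean[cell], config.post_uptake_sd[cell], 0.01
    )

    pools_pre_silking = {
        o: q_wps * config.silking_partition[veg][o] for o in SILKING_ORGANS
    }
    contrib = {
        o: rem * q_wps * w
        for o, w in config.remobilization_source_weights.items()
    }
    for o, c in contrib.items():
        if c > pools_pre_silking[o] + 1e-12:
            raise SimConfigError(
                f"remobilization drains more N than the {o} pool holds"
            )
    post = {o: uptake * config.post_partition[cell][o] for o in MATURITY_ORGANS}

    sen = config.leaf_senesced_fraction[rep]
    leaves_left = pools_pre_silking["leaves"] - contrib["leaves"]
    pre = {
        "green_leaves": leaves_left * (1.0 - sen),
        "senesced_leaves": leaves_left * sen,
        "stalk": pools_pre_silking["stalk"] - contrib["stalk"],
        "roots": pools_pre_silking["roots"] - contrib["roots"],
        "repro_nongrain": pools_pre_silking["reproductive"]
        - contrib["reproductive"],
        "grain": rem * q_wps,
    }

    # -- enrichment of the two source pools -------------------------------
    mult = config.label_mixing_multipliers or {}
    if label_phase == "vegetative":
        a_pre = {
            o: base + config.phi_pre[veg] * mult.get(o, 1.0) * (label_ap - base)
            for o in SILKING_ORGANS
        }
    else:
        a_pre = {o: base for o in SILKING_ORGANS}

    if label_phase == "reproductive":
        a_post = base + config.phi_post[rep] * (label_ap - base)
    elif label_phase == "vegetative":
        # residual vegetative label surviving the silking leach may re-enter
        applied_label_n = config.dose_pre_n15_mg / 1000.0 / (label_ap / 100.0)
        absorbed = config.phi_pre[veg] * q_wps
        residual = leach_event(
            max(applied_label_n - absorbed, 0.0), config.leach_efficiency
        )
        label_in_post = min(residual * config.residual_uptake_fraction, uptake)
        a_post = base + (label_in_post / uptake) * (label_ap - base)
    else:
        a_post = base

    rem_total = sum(contrib.values())
    if rem_total > 0:
        a_grain_pre = sum(contrib[o] * a_pre[o] for o in SILKING_ORGANS) / rem_total
    else:
        a_grain_pre = base
    a_pre_maturity = {
        "green_leaves": a_pre["leaves"],
        "senesced_leaves": a_pre["leaves"],
        "stalk": a_pre["stalk"],
        "roots": a_pre["roots"],
        "repro_nongrain": a_pre["reproductive"],
        "grain": a_grain_pre,
    }

    # -- assemble observed organs -----------------------------------------
    loss = config.n_loss_fraction
    grain_mass = _clip_draw(
        rng, config.grain_mass_mean[cell], config.grain_mass_sd[cell], 1.0
    )
    organs = []
    for organ in MATURITY_ORGANS:
        q_total = (pre[organ] + post[organ]) * (1.0 - loss)
        if pre[organ] + post[organ] > 0:
            a_true = (
                pre[organ] * a_pre_maturity[organ] + post[organ] * a_post
            ) / (pre[organ] + post[organ])
        else:
            a_true = base
        conc_true = (
            q_total / grain_mass
            if organ == "grain"
            else config.n_conc_maturity[organ]
        )
        dry = grain_mass if organ == "grain" else q_total / conc_true
        conc = min(conc_true * _lognormal_factor(rng, config.noise_cv_n_content), 0.1)
        enrich = a_true + (
            float(rng.normal(0.0, config.noise_sd_atom_percent))
            if config.noise_sd_atom_percent > 0
            else 0.0
        )
        organs.append(
            OrganSample(
                organ=organ, dry_mass=dry, n_concentration=conc, enrichment=enrich
            )
        )

    spikelets = round(
        _clip_draw(rng, config.spikelet_mean[veg], config.spikelet_sd[veg], 1.0)
    )
    kernels = round(
        _clip_draw(
            rng, config.kernel_mean[cell], config.kernel_sd[cell], 1.0, float(spikelets)
        )
    )
    record = PlantRecord(
        plant_id=plant_id,
        block=block,
        greenhouse=greenhouse,
        veg_treatment=veg,
        rep_treatment=rep,
        label_phase=label_phase,
        stage="maturity",
        organs=organs,
        spikelet_count=spikelets,
        kernel_number=kernels,
        grain_mass=grain_mass,
    )

    q_grain = pre["grain"] + post["grain"]
    truth = {
        "plant_id": plant_id,
        "veg_treatment": veg,
        "rep_treatment": rep,
        "label_phase": label_phase,
        "stage": "maturity",
        "q_wps": q_wps,
        "rem_pct": 100.0 * rem,
        "q_rem_grain": rem * q_wps,
        "post_uptake": uptake,
        "q_grain": q_grain,
        "q_post_grain": post["grain"],
        "grain_rem_pct": 100.0 * pre["grain"] / q_grain if q_grain > 0 else np.nan,
        "q_wpm": (q_wps + uptake) * (1.0 - loss),
    }
    for o in MATURITY_ORGANS:
        truth[f"post_pct_{o}"] = 100.0 * config.post_partition[cell][o]
    return record, truth


def generate_experiment(
    config: SimConfig | None = None, seed: int = 0
) -> tuple[list[PlantRecord], ExperimentTruth]:
    """Generate the full experiment: a silking-harvested Q(wps) cohort plus
    maturity-harvested labelled and unlabelled plants, with ground truth.

    Deterministic given ``(config, seed)``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    records: list[PlantRecord] = []
    truths: list[dict] = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:04d}"

    for block, greenhouse, labelled in _blocks(config):
        for veg in VEG_TREATMENTS:
            for _ in range(config.silking_plants_per_block):
                rec, tr = _silking_plant(
                    config, rng, next_id("S"), block, greenhouse, veg
                )
                records.append(rec)
                truths.append(tr)
        for veg, rep in CELLS:
            if labelled:
                for phase in ("vegetative", "reproductive"):
                    for _ in range(config.maturity_replicates):
                        rec, tr = _maturity_plant(
                            config, rng, next_id("M"), block, greenhouse,
                            veg, rep, phase,
                        )
                        records.append(rec)
                        truths.append(tr)
            else:
                for _ in range(config.unlabelled_per_block_cell):
                    rec, tr = _maturity_plant(
                        config, rng, next_id("M"), block, greenhouse,
                        veg, rep, "unlabelled",
                    )
                    records.append(rec)
                    truths.append(tr)

    frame = pd.DataFrame(truths).reindex(columns=TRUTH_COLUMNS)
    return records, ExperimentTruth(frame)
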