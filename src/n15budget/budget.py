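"""Per-plant ¹⁵N mass-balance: remobilization, grain-N sources and
post-silking uptake partitioning.

The calculus assumes (i) no isotopic discrimination within the plant,
(ii) none in N metabolism, (iii) no N losses from the plant, and (iv)
uniform distribution of the label in the root medium.  Under these
assumptions the excess ¹⁵N in an organ, q(x) = (A(x) − A₀)/100 × Q_x,
is proportional to the N that organ received from the labelled phase.

For a plant labelled during *vegetative* growth:

    rem%          = 100 · q(grain)/q(wpm)                 (fraction of
                    pre-silking N remobilized to grain)
    Q_rem(grain)  = Q(wps) · rem%/100
    Grain_rem     = 100 · Q_rem(grain)/Q(grain)

For a plant labelled during *reproductive* growth (after silking):

    Post%(x)      = 100 · q(x)/q(wpm)     for every organ x
    Q_post(x)     = (Q(wpm) − Q(wps)) · Post%(x)/100
    Grain_rem     = 100 · (1 − Q_post(grain)/Q(grain))

Q(wps), whole-plant N at silking, is not observable on a maturity-harvested
plant; following the experimental design it is supplied as the mean over a
silking-harvested cohort of the same vegetative treatment (a per-plant
override is accepted for sensitivity analysis).  No correction factor for
residual label uptake is applied by default — the labelling design leaches
the medium at silking — but a correction hook is exposed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .isotopes import IsotopeConfig, excess_n15_mass

logger = logging.getLogger(__name__)

__all__ = [
    "MATURITY_ORGANS",
    "SILKING_ORGANS",
    "SILKING_GROUP_OF",
    "OrganSample",
    "PlantRecord",
    "NBudget",
    "BudgetError",
    "DegenerateLabelError",
    "whole_plant_n",
    "excess_by_organ",
    "remobilized_fraction",
    "remobilized_to_grain",
    "grain_fraction_from_remobilization",
    "postsilking_partition",
    "postsilking_uptake",
    "postsilking_to_organ",
    "grain_rem_from_reproductive_label",
    "budget_assemble",
]

#: organ taxonomy at the maturity harvest (six groups)
MATURITY_ORGANS = (
    "green_leaves",
    "senesced_leaves",
    "stalk",
    "roots",
    "grain",
    "repro_nongrain",
)
#: organ taxonomy at the silking harvest (four groups)
SILKING_ORGANS = ("leaves", "stalk", "roots", "reproductive")
#: fixed mapping from maturity organs to their silking-stage group
SILKING_GROUP_OF = {
    "green_leaves": "leaves",
    "senesced_leaves": "leaves",
    "stalk": "stalk",
    "roots": "roots",
    "grain": "reproductive",
    "repro_nongrain": "reproductive",
}

VEG_TREATMENTS = ("Nveg", "nveg")
REP_TREATMENTS = ("NW", "nW", "Nw", "nw")
LABEL_PHASES = ("vegetative", "reproductive", "unlabelled")
STAGES = ("silking", "maturity")


class BudgetError(ValueError):
    """Invalid input to a budget operation."""


class DegenerateLabelError(BudgetError):
    """Whole-plant excess ¹⁵N is non-positive on a labelled plant, so
    label-based ratios are undefined."""


@dataclass
class OrganSample:
    """One organ of one plant at one harvest.

    ``n_concentration`` is a mass fraction of dry matter (0–1), and
    ``enrichment`` is atom% ¹⁵N (optional for unlabelled plants).
    """

    organ: str
    dry_mass: float
    n_concentration: float
    enrichment: float | None = None

    def __post_init__(self) -> None:
        if self.dry_mass < 0:
            raise BudgetError(f"dry_mass must be >= 0; got {self.dry_mass!r}")
        if not 0.0 <= self.n_concentration <= 0.1:
            raise BudgetError(
                "n_concentration must be a fraction in [0, 0.1]; "
                f"got {self.n_concentration!r}"
            )

    @property
    def n_content(self) -> float:
        """Organ N pool Q_x in grams (dry mass × N concentration)."""
        return self.dry_mass * self.n_concentration


@dataclass
class PlantRecord:
    """A plant's treatment assignment, labelling phase, harvest stage,
    organ samples and (optional) yield phenotypes."""

    plant_id: str
    block: str
    greenhouse: str
    veg_treatment: str
    rep_treatment: str  # "none" for silking-harvested plants
    label_phase: str
    stage: str
    organs: list[OrganSample] = field(default_factory=list)
    spikelet_count: float | None = None
    kernel_number: float | None = None
    grain_mass: float | None = None

    def __post_init__(self) -> None:
        if self.veg_treatment not in VEG_TREATMENTS:
            raise BudgetError(f"unknown veg_treatment {self.veg_treatment!r}")
        if self.rep_treatment not in REP_TREATMENTS + ("none",):
            raise BudgetError(f"unknown rep_treatment {self.rep_treatment!r}")
        if self.label_phase not in LABEL_PHASES:
            raise BudgetError(f"unknown label_phase {self.label_phase!r}")
        if self.stage not in STAGES:
            raise BudgetError(f"unknown stage {self.stage!r}")
        allowed = SILKING_ORGANS if self.stage == "silking" else MATURITY_ORGANS
        names = [o.organ for o in self.organs]
        for name in names:
            if name not in allowed:
                raise BudgetError(
                    f"unknown organ {name!r} for stage {self.stage!r}; "
                    f"allowed: {allowed}"
                )
        if len(set(names)) != len(names):
            raise BudgetError(f"duplicate organ labels in plant {self.plant_id!r}")
        if self.stage == "silking" and self.rep_treatment != "none":
            raise BudgetError("silking-harvested plants have rep_treatment='none'")
        if self.label_phase != "unlabelled":
            missing = [o.organ for o in self.organs if o.enrichment is None]
            if missing:
                raise BudgetError(
                    f"labelled plant {self.plant_id!r} missing enrichment on "
                    f"organs {missing}"
                )

    def organ(self, name: str) -> OrganSample:
        for o in self.organs:
            if o.organ == name:
                return o
        raise BudgetError(f"plant {self.plant_id!r} has no organ {name!r}")

    @property
    def has_grain(self) -> bool:
        return any(o.organ == "grain" for o in self.organs)


@dataclass
class NBudget:
    """Per-plant outputs of the ¹⁵N mass balance.

    Percentages are on the 0–100 scale; N masses in grams.  Fields that a
    labelling phase cannot determine are left ``None``.  ``flags`` records
    quality issues (assumption violations, out-of-range ratios) without
    altering the raw values.
    """

    plant_id: str
    label_phase: str
    q_wpm_total_n: float  # Q(wpm), g N
    q_grain_n: float | None  # Q(grain), g N
    q_wps_used: float | None  # reference Q(wps), g N
    excess_by_organ: dict[str, float] | None = None  # q(x), g 15N
    excess_wpm: float | None = None  # q(wpm), g 15N
    rem_pct: float | None = None
    q_rem_grain: float | None = None
    grain_rem_pct: float | None = None
    post_uptake: float | None = None
    post_pct_by_organ: dict[str, float] | None = None
    q_post_by_organ: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)


def whole_plant_n(record: PlantRecord) -> float:
    """Whole-plant N content (g): Σ Q_x over organs.  For a silking-stage
    plant this is its Q(wps)."""
    if not record.organs:
        raise BudgetError(f"plant {record.plant_id!r} has no organ samples")
    return sum(o.n_content for o in record.organs)


def excess_by_organ(
    record: PlantRecord, config: IsotopeConfig | None = None
) -> dict[str, float]:
    """Excess ¹⁵N per organ, q(x) in g ¹⁵N.

    Small negative excess (within ``config.negative_excess_tolerance``) is
    clamped to zero with a logged warning — unlabelled tissue routinely
    sits slightly below the empirical baseline.  Larger negative excess
    indicates an inconsistent baseline or corrupted data and raises.
    """
    config = config or IsotopeConfig()
    out: dict[str, float] = {}
    for organ in record.organs:
        if organ.enrichment is None:
            raise BudgetError(
                f"organ {organ.organ!r} of plant {record.plant_id!r} has no "
                "enrichment measurement"
            )
        q = excess_n15_mass(organ.enrichment, config, organ.n_content)
        if q < 0:
            if -q <= config.negative_excess_tolerance:
                logger.warning(
                    "plant %s organ %s: clamping negative excess %.3g g to 0",
                    record.plant_id,
                    organ.organ,
                    q,
                )
                q = 0.0
            else:
                raise BudgetError(
                    f"plant {record.plant_id!r} organ {organ.organ!r}: excess "
                    f"15N {q:.4g} g is below -tolerance "
                    f"({config.negative_excess_tolerance:g} g); check baseline"
                )
        out[organ.organ] = q
    return out


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise BudgetError(msg)


def remobilized_fraction(
    record: PlantRecord, config: IsotopeConfig | None = None
) -> float:
    """rem% — percent of pre-silking N remobilized to the grain, from a
    vegetative-labelled maturity plant: 100·q(grain)/q(wpm)."""
    _require(record.label_phase == "vegetative", "plant must be vegetative-labelled")
    _require(record.stage == "maturity", "plant must be harvested at maturity")
    _require(record.has_grain, f"plant {record.plant_id!r} has no grain organ")
    q = excess_by_organ(record, config)
    q_wpm = sum(q.values())
    if q_wpm <= 0:
        raise DegenerateLabelError(
            f"plant {record.plant_id!r}: whole-plant excess 15N is {q_wpm:.4g} g"
        )
    return 100.0 * q["grain"] / q_wpm


def remobilized_to_grain(q_wps: float, rem_pct: float) -> float:
    """Q_rem(grain) (g N) — pre-silking N remobilized to the grain:
    Q(wps) × rem%/100."""
    _require(q_wps >= 0, f"Q_wps must be >= 0; got {q_wps!r}")
    _require(0.0 <= rem_pct <= 100.0, f"rem_pct must lie in [0,100]; got {rem_pct!r}")
    return q_wps * rem_pct / 100.0


def grain_fraction_from_remobilization(q_rem_grain: float, q_grain: float) -> float:
    """Grain_rem (%) from the vegetative label: 100·Q_rem(grain)/Q(grain).

    Values above 100 (possible with noisy data or a mis-specified Q_wps
    reference) are returned raw; callers attach a quality flag."""
    if q_grain <= 0:
        raise BudgetError(f"grain N content must be > 0; got {q_grain!r}")
    return 100.0 * q_rem_grain / q_grain


def postsilking_partition(
    record: PlantRecord, config: IsotopeConfig | None = None
) -> dict[str, float]:
    """Post%(x) for every organ of a reproductive-labelled maturity plant:
    100·q(x)/q(wpm).  Sums to 100 over organs by construction."""
    _require(
        record.label_phase == "reproductive", "plant must be reproductive-labelled"
    )
    _require(record.stage == "maturity", "plant must be harvested at maturity")
    q = excess_by_organ(record, config)
    q_wpm = sum(q.values())
    if q_wpm <= 0:
        raise DegenerateLabelError(
            f"plant {record.plant_id!r}: whole-plant excess 15N is {q_wpm:.4g} g"
        )
    return {organ: 100.0 * qx / q_wpm for organ, qx in q.items()}


def postsilking_uptake(q_wpm: float, q_wps: float) -> float:
    """Post-silking N uptake (g): Q(wpm) − Q(wps).

    A negative result means net N loss between silking and maturity,
    violating the no-loss assumption; it is returned as-is with a warning
    so that downstream summaries remain auditable."""
    _require(q_wpm >= 0 and q_wps >= 0, "N contents must be >= 0")
    uptake = q_wpm - q_wps
    if uptake < 0:
        warnings.warn(
            f"negative post-silking uptake ({uptake:.3g} g): Q(wpm) < Q(wps) "
            "implies net N loss, violating the mass-balance assumption",
            stacklevel=2,
        )
    return uptake


def postsilking_to_organ(q_wpm: float, q_wps: float, post_pct_organ: float) -> float:
    """Q_post(x) (g N): (Q(wpm) − Q(wps)) × Post%(x)/100."""
    _require(
        0.0 <= post_pct_organ <= 100.0,
        f"post_pct must lie in [0,100]; got {post_pct_organ!r}",
    )
    return postsilking_uptake(q_wpm, q_wps) * post_pct_organ / 100.0


def grain_rem_from_reproductive_label(q_post_grain: float, q_grain: float) -> float:
    """Grain_rem (%) from the reproductive label:
    100·(1 − Q_post(grain)/Q(grain))."""
    if q_grain <= 0:
        raise BudgetError(f"grain N content must be > 0; got {q_grain!r}")
    return 100.0 * (1.0 - q_post_grain / q_grain)


CorrectionHook = Callable[[Mapping[str, float], PlantRecord], Mapping[str, float]]


def budget_assemble(
    record: PlantRecord,
    q_wps_reference: float,
    config: IsotopeConfig | None = None,
    correction: CorrectionHook | None = None,
) -> NBudget:
    """Assemble the full per-plant N budget, dispatching on label phase.

    Parameters
    ----------
    record
        a maturity-harvested plant.
    q_wps_reference
        Q(wps) for this plant — normally the silking-cohort mean of its
        vegetative treatment, optionally a per-plant override.
    correction
        optional hook mapping the raw per-organ excess dict to a corrected
        one (e.g. a residual-uptake correction); default is identity, as
        the leaching design makes no correction necessary.

    Vegetative-labelled plants get rem%, Q_rem(grain) and Grain_rem; the
    per-organ post-silking fields stay ``None``.  Reproductive-labelled
    plants get the Post% vector, Q_post per organ and Grain_rem; rem%
    stays ``None``.  Unlabelled plants get N totals only.
    """
    config = config or IsotopeConfig()
    _require(record.stage == "maturity", "budgets are assembled at maturity")
    q_wpm_total = whole_plant_n(record)
    q_grain = record.organ("grain").n_content if record.has_grain else None

    flags: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        uptake = postsilking_uptake(q_wpm_total, q_wps_reference)
    if caught:
        flags.append("negative_post_uptake")

    budget = NBudget(
        plant_id=record.plant_id,
        label_phase=record.label_phase,
        q_wpm_total_n=q_wpm_total,
        q_grain_n=q_grain,
        q_wps_used=q_wps_reference,
        post_uptake=uptake,
        flags=flags,
    )
    if record.label_phase == "unlabelled":
        return budget

    q = excess_by_organ(record, config)
    if correction is not None:
        q = dict(correction(q, record))
    budget.excess_by_organ = q
    budget.excess_wpm = sum(q.values())
    if budget.excess_wpm <= 0:
        raise DegenerateLabelError(
            f"plant {record.plant_id!r}: whole-plant excess 15N is non-positive"
        )

    if record.label_phase == "vegetative":
        _require(record.has_grain, f"plant {record.plant_id!r} has no grain organ")
        budget.rem_pct = 100.0 * q["grain"] / budget.excess_wpm
        budget.q_rem_grain = remobilized_to_grain(q_wps_reference, budget.rem_pct)
        budget.grain_rem_pct = grain_fraction_from_remobilization(
            budget.q_rem_grain, q_grain
        )
    else:  # reproductive
        post_pct = {o: 100.0 * qx / budget.excess_wpm for o, qx in q.items()}
        budget.post_pct_by_organ = post_pct
        budget.q_post_by_organ = {
            o: uptake * pct / 100.0 for o, pct in post_pct.items()
        }
        if record.has_grain:
            budget.grain_rem_pct = grain_rem_from_reproductive_label(
                budget.q_post_by_organ["grain"], q_grain
            )

    if budget.grain_rem_pct is not None and not (
        0.0 <= budget.grain_rem_pct <= 100.0
    ):
        budget.flags.append("grain_rem_out_of_range")
    return budget


def q_wps_reference_means(records: Sequence[PlantRecord]) -> dict[str, float]:
    """Treatment-mean Q(wps) from the silking-harvested cohort, keyed by
    vegetative treatment."""
    totals: dict[str, list[float]] = {}
    for rec in records:
        if rec.stage == "silking":
            totals.setdefault(rec.veg_treatment, []).append(whole_plant_n(rec))
    if not totals:
        raise BudgetError("no silking-stage plants to estimate Q(wps) from")
    return {veg: sum(v) / len(v) for veg, v in totals.items()}


def compute_budgets(
    records: Sequence[PlantRecord],
    config: IsotopeConfig | None = None,
    q_wps_reference: Mapping[str, float] | None = None,
    correction: CorrectionHook | None = None,
) -> dict[str, NBudget]:
    """Budget every maturity plant in ``records``.

    ``q_wps_reference`` maps vegetative treatment to the Q(wps) to use; if
    omitted it is estimated as the silking-cohort mean per treatment from
    the same record set."""
    refs = dict(q_wps_reference) if q_wps_reference else q_wps_reference_means(records)
    out: dict[str, NBudget] = {}
    for rec in records:
        if rec.stage != "maturity":
            continue
        if rec.veg_treatment not in refs:
            raise BudgetError(
                f"no Q(wps) reference for veg treatment {rec.veg_treatment!r}"
            )
        out[rec.plant_id] = budget_assemble(
            rec, refs[rec.veg_treatment], config=config, correction=correction
        )
    return out
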