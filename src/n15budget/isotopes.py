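"""Isotope-ratio arithmetic for ¹⁵N tracer studies.

Conversions between δ¹⁵N (per-mil deviation from the atmospheric-N₂
standard) and atom% ¹⁵N use exact isotope-ratio algebra — atom% is first
converted to the ¹⁵N/¹⁴N ratio, the δ scaling is applied to the ratio, and
the result is mapped back to atom%.  The common linear approximation
(δ ≈ 1000·ΔA/A) is deliberately not used: at natural-abundance precision
the two differ in the fourth decimal of atom%, which matters when
validating leaching experiments against δ values of a few per mil.

Two reference constants are kept distinct and never conflated:

``standard_atom_percent``
    atom% ¹⁵N of the international standard, atmospheric N₂ (0.3663%).
    δ¹⁵N is defined against this.
``baseline_atom_percent``
    the empirical natural-abundance baseline of the plant material,
    used as A₀ in the excess-¹⁵N mass balance.  For greenhouse-grown,
    unlabelled maize this sits slightly above the standard (0.3733%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IsotopeConfig",
    "TracerDose",
    "IsotopeError",
    "delta_to_atom_percent",
    "atom_percent_to_delta",
    "excess_n15_mass",
    "tracer_n15_mass",
]

#: atom% 15N of atmospheric N2, the delta-scale reference.
STANDARD_ATOM_PERCENT = 0.3663
#: empirical natural abundance of unlabelled greenhouse maize tissue, A0.
BASELINE_ATOM_PERCENT = 0.3733

# atomic masses (g/mol)
_MASS_K = 39.098
_MASS_O = 15.999
_MASS_N15 = 15.000
_MASS_N14 = 14.003


class IsotopeError(ValueError):
    """Invalid isotope-arithmetic input (out-of-range atom% or δ)."""


@dataclass(frozen=True)
class IsotopeConfig:
    """Reference constants for the ¹⁵N mass balance.

    Parameters
    ----------
    standard_atom_percent
        atom% ¹⁵N of the international standard (atmospheric N₂).
    baseline_atom_percent
        atom% ¹⁵N used as natural abundance A₀ in the excess calculation.
    negative_excess_tolerance
        magnitude of negative per-organ excess ¹⁵N (g) that the budget
        layer clamps to zero with a warning; anything more negative is an
        error.  Unlabelled tissue can sit slightly below the empirical
        baseline, so small negative excess is expected measurement scatter.
    """

    standard_atom_percent: float = STANDARD_ATOM_PERCENT
    baseline_atom_percent: float = BASELINE_ATOM_PERCENT
    negative_excess_tolerance: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("standard_atom_percent", "baseline_atom_percent"):
            value = getattr(self, name)
            if not 0.0 < value < 100.0:
                raise IsotopeError(f"{name} must lie in (0, 100); got {value!r}")
        if self.negative_excess_tolerance < 0:
            raise IsotopeError("negative_excess_tolerance must be >= 0")


def _atom_percent_to_ratio(atom_percent: float) -> float:
    if not 0.0 < atom_percent < 100.0:
        raise IsotopeError(f"atom percent must lie in (0, 100); got {atom_percent!r}")
    return atom_percent / (100.0 - atom_percent)


def _ratio_to_atom_percent(ratio: float) -> float:
    return 100.0 * ratio / (1.0 + ratio)


def delta_to_atom_percent(
    delta_permil: float, standard_atom_percent: float = STANDARD_ATOM_PERCENT
) -> float:
    """Convert δ¹⁵N (‰ vs the standard) to atom% ¹⁵N.

    Uses exact ratio algebra: R = R_std·(1 + δ/1000), atom% = 100·R/(1+R).
    δ ≤ −1000‰ would imply a non-positive isotope ratio and is rejected.
    """
    if not math.isfinite(delta_permil) or delta_permil <= -1000.0:
        raise IsotopeError(
            f"delta must be finite and > -1000 permil; got {delta_permil!r}"
        )
    r_std = _atom_percent_to_ratio(standard_atom_percent)
    r_sample = r_std * (1.0 + delta_permil / 1000.0)
    return _ratio_to_atom_percent(r_sample)


def atom_percent_to_delta(
    atom_percent: float, standard_atom_percent: float = STANDARD_ATOM_PERCENT
) -> float:
    """Convert atom% ¹⁵N to δ¹⁵N (‰ vs the standard); exact inverse of
    :func:`delta_to_atom_percent`."""
    r_sample = _atom_percent_to_ratio(atom_percent)
    r_std = _atom_percent_to_ratio(standard_atom_percent)
    return 1000.0 * (r_sample / r_std - 1.0)


def excess_n15_mass(
    atom_percent_sample: float,
    config: IsotopeConfig,
    organ_n_content: float,
) -> float:
    """Mass of ¹⁵N in excess of natural abundance, q(x) (g ¹⁵N).

    q(x) = (A(x) − A₀)/100 × Q_x, where Q_x is the organ N content in
    grams.  The result is the tracer-derived ¹⁵N and may be *negative*
    when the sample sits below the empirical baseline; callers decide
    whether to clamp (see :class:`IsotopeConfig.negative_excess_tolerance`).
    """
    if organ_n_content < 0:
        raise IsotopeError(f"organ N content must be >= 0; got {organ_n_content!r}")
    excess_points = atom_percent_sample - config.baseline_atom_percent
    return excess_points / 100.0 * organ_n_content


def tracer_n15_mass(salt_mass_mg: float, atom_percent_label: float) -> float:
    """mg of ¹⁵N delivered by dissolving ``salt_mass_mg`` of K¹⁵NO₃.

    The molar mass of the nitrogen atom in the salt is the label-weighted
    mean of ¹⁴N and ¹⁵N masses (at 10 atom% label: 0.9·14.003 + 0.1·15.000),
    so 680 mg of salt at 10 atom% yields 10 mg ¹⁵N to the nearest mg.
    """
    if salt_mass_mg < 0:
        raise IsotopeError(f"salt mass must be >= 0; got {salt_mass_mg!r}")
    if not 0.0 < atom_percent_label <= 100.0:
        raise IsotopeError(
            f"label atom percent must lie in (0, 100]; got {atom_percent_label!r}"
        )
    frac15 = atom_percent_label / 100.0
    mass_n = frac15 * _MASS_N15 + (1.0 - frac15) * _MASS_N14
    molar_mass_salt = _MASS_K + mass_n + 3.0 * _MASS_O
    moles = salt_mass_mg / molar_mass_salt  # mmol
    return moles * frac15 * _MASS_N15


@dataclass(frozen=True)
class TracerDose:
    """A ¹⁵N label application, entered either as salt mass or directly
    as mg ¹⁵N (the two are not always mutually consistent in published
    protocols, so both entry modes are provided).

    Parameters
    ----------
    salt_mass_mg
        mg of K¹⁵NO₃ dissolved.
    atom_percent_label
        atom% ¹⁵N of the salt.
    stated_n15_mg
        optional protocol-stated mg ¹⁵N; when given it overrides the
        stoichiometric value in :attr:`n15_mass_mg`.
    """

    salt_mass_mg: float
    atom_percent_label: float
    stated_n15_mg: float | None = None

    def __post_init__(self) -> None:
        if self.salt_mass_mg < 0:
            raise IsotopeError("salt_mass_mg must be >= 0")
        if not 0.0 < self.atom_percent_label <= 100.0:
            raise IsotopeError("atom_percent_label must lie in (0, 100]")

    @property
    def stoichiometric_n15_mg(self) -> float:
        """mg ¹⁵N implied by the salt mass and label enrichment."""
        return tracer_n15_mass(self.salt_mass_mg, self.atom_percent_label)

    @property
    def n15_mass_mg(self) -> float:
        """mg ¹⁵N of the dose: the stated value if provided, else the
        stoichiometric one."""
        if self.stated_n15_mg is not None:
            return self.stated_n15_mg
        return self.stoichiometric_n15_mg

    @property
    def labelled_n_mg(self) -> float:
        """Total N (mg, both isotopes) carried by the labelled salt."""
        return self.n15_mass_mg / (self.atom_percent_label / 100.0)
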