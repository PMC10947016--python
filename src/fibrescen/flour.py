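"""Quantitative model of white-flour dietary-fibre composition.

White flour (starchy endosperm, ~78-80% extraction) has a simple fibre
fraction of five components: arabinoxylan (AX, the major cell-wall
polysaccharide and about half of the total), beta-glucan, fructans
(fructo-oligosaccharides of 3-5 sugars), cellulose and arabinogalactan
peptide (AGP).  Each component has a content (% dry weight) and a
water-soluble fraction.  Contents reported in the literature are often
ranges (varietal variation for AX, assay spread for fructans), so the
model stores every quantity as an interval with a selectable evaluation
point (lo | mid | hi).

The default profile: AX 1.9% dw (varietal range 1.35-2.75, 25-50% soluble),
beta-glucan 0.2% (30% soluble), fructans 1.5-1.7% (fully soluble),
cellulose <0.1% (insoluble), AGP 0.3% (fully soluble).  Resistant starch
(~1% DM in white bread) is deliberately excluded; it is not part of these
component totals.

The module also covers the breeding scenario of raising AX — e.g. from
below 2% to about 4% dw, which lifts total fibre from about 4% to about
6% — and the water uptake of AX, which absorbs roughly 10x its dry weight
for the insoluble and 11x for the soluble fraction, a quantity bakers
track via flour water absorption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Mapping

import yaml

__all__ = [
    "Interval",
    "FlourFibreProfile",
    "AxScenario",
    "COMPONENTS",
    "default_profile",
    "total_fibre",
    "soluble_fraction",
    "apply_ax_scenario",
    "water_absorption",
    "load_profile",
]

Point = Literal["lo", "mid", "hi"]

COMPONENTS = ("arabinoxylan", "beta_glucan", "fructans", "cellulose", "agp")

#: Water absorbed per gram of arabinoxylan dry weight.
WATER_PER_G_INSOLUBLE_AX = 10.0
WATER_PER_G_SOLUBLE_AX = 11.0


@dataclass(frozen=True)
class Interval:
    """A range-valued quantity with an optional central (reported) value.

    ``at("mid")`` returns the central value when one is reported and the
    arithmetic midpoint otherwise; point-valued quantities use lo == hi.
    """

    lo: float
    hi: float
    central: float | None = None

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError(f"interval hi {self.hi} < lo {self.lo}")
        if self.central is not None and not (self.lo <= self.central <= self.hi):
            raise ValueError(f"central {self.central} outside [{self.lo}, {self.hi}]")

    @classmethod
    def point(cls, value: float) -> "Interval":
        return cls(value, value)

    def at(self, point: Point = "mid") -> float:
        if point == "lo":
            return self.lo
        if point == "hi":
            return self.hi
        if point == "mid":
            return self.central if self.central is not None else (self.lo + self.hi) / 2.0
        raise ValueError(f"evaluation point must be lo|mid|hi, got {point!r}")


@dataclass(frozen=True)
class FlourFibreProfile:
    """Component contents (% dry weight) and soluble fractions (0-1)."""

    content: Mapping[str, Interval]
    soluble: Mapping[str, Interval]

    def __post_init__(self) -> None:
        for comp in COMPONENTS:
            if comp not in self.content or comp not in self.soluble:
                raise ValueError(f"profile missing component {comp!r}")
        for comp, iv in self.content.items():
            if iv.lo < 0:
                raise ValueError(f"{comp}: content must be >= 0")
        for comp, iv in self.soluble.items():
            if not (0.0 <= iv.lo and iv.hi <= 1.0):
                raise ValueError(f"{comp}: soluble fraction must lie in [0, 1]")


def default_profile() -> FlourFibreProfile:
    """The literature-consensus white-flour profile described in the module docstring."""
    return FlourFibreProfile(
        content={
            "arabinoxylan": Interval(1.35, 2.75, central=1.9),
            "beta_glucan": Interval.point(0.2),
            "fructans": Interval(1.5, 1.7),
            "cellulose": Interval(0.0, 0.1),  # reported as "<0.1"
            "agp": Interval.point(0.3),
        },
        soluble={
            "arabinoxylan": Interval(0.25, 0.50),
            "beta_glucan": Interval.point(0.30),
            "fructans": Interval.point(1.0),
            "cellulose": Interval.point(0.0),
            "agp": Interval.point(1.0),
        },
    )


def total_fibre(profile: FlourFibreProfile, point: Point = "mid") -> float:
    """Total dietary fibre, % dry weight: the sum of the five component contents."""
    return sum(profile.content[c].at(point) for c in COMPONENTS)


def soluble_fraction(
    profile: FlourFibreProfile,
    content_point: Point = "mid",
    solubility_point: Point = "mid",
) -> float:
    """Soluble share of total fibre, in percent.

    100 * sum_i content_i * soluble_i / total.  Evaluating at the
    arabinoxylan-solubility bounds (solubility_point = "lo" / "hi") brackets
    the soluble share, since AX is the only component whose solubility is
    range-valued.
    """
    total = total_fibre(profile, content_point)
    if total <= 0:
        raise ValueError("total fibre is zero; soluble fraction undefined")
    soluble = sum(
        profile.content[c].at(content_point) * profile.soluble[c].at(solubility_point)
        for c in COMPONENTS
    )
    return 100.0 * soluble / total


@dataclass(frozen=True)
class AxScenario:
    """Substitute the arabinoxylan content: current -> target, % dry weight."""

    ax_current: float
    ax_target: float

    def __post_init__(self) -> None:
        if self.ax_current < 0 or self.ax_target < 0:
            raise ValueError("arabinoxylan contents must be >= 0")


def apply_ax_scenario(
    profile: FlourFibreProfile,
    scenario: AxScenario,
    point: Point = "mid",
    tol: float = 1e-9,
) -> tuple[FlourFibreProfile, float]:
    """Replace the AX content by the target; other components are unchanged.

    Returns the new profile and its new total at the same evaluation point,
    which exceeds the old total by exactly (ax_target - ax_current).  The
    profile's AX content at ``point`` must match ``ax_current``.
    """
    have = profile.content["arabinoxylan"].at(point)
    if abs(have - scenario.ax_current) > tol:
        raise ValueError(
            f"profile arabinoxylan {have} (at point {point!r}) does not match "
            f"scenario ax_current {scenario.ax_current}"
        )
    new_content = dict(profile.content)
    new_content["arabinoxylan"] = Interval.point(scenario.ax_target)
    new_profile = replace(profile, content=new_content)
    return new_profile, total_fibre(new_profile, point)


def water_absorption(ax_insoluble_g: float, ax_soluble_g: float) -> float:
    """Grams of water absorbed by the given masses of AX dry matter."""
    if ax_insoluble_g < 0 or ax_soluble_g < 0:
        raise ValueError("arabinoxylan masses must be >= 0")
    return WATER_PER_G_INSOLUBLE_AX * ax_insoluble_g + WATER_PER_G_SOLUBLE_AX * ax_soluble_g


def load_profile(path: str | Path) -> FlourFibreProfile:
    """Read a profile from YAML: per component, content and soluble_fraction as
    scalars or {lo, hi[, central]} mappings."""

    def as_interval(raw) -> Interval:
        if isinstance(raw, (int, float)):
            return Interval.point(float(raw))
        return Interval(float(raw["lo"]), float(raw["hi"]), raw.get("central"))

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return FlourFibreProfile(
        content={c: as_interval(raw[c]["content"]) for c in COMPONENTS},
        soluble={c: as_interval(raw[c]["soluble_fraction"]) for c in COMPONENTS},
    )
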