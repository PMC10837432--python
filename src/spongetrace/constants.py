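"""Isotope reference standards and elemental constants.

Bulk isotope measurements are reported in delta notation against the
international standards — VPDB for carbon and atmospheric N2 (AIR) for
nitrogen.  The registry below holds the heavy/light abundance ratios of
those standards together with the atomic masses needed to turn mass
percent + dry mass into moles of element.  All values are conventions,
not measurements, and can be overridden via a YAML/JSON mapping so that
an alternative calibration is a configuration change, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import yaml

ELEMENTS = ("C", "N")


@dataclass(frozen=True)
class IsotopeStandard:
    """International reference standard for one element.

    ``ratio`` is the heavy/light isotope abundance ratio of the standard
    (13C/12C for VPDB, 15N/14N for AIR).
    """

    element: str
    name: str
    ratio: float

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if not self.ratio > 0:
            raise ValueError("standard ratio must be > 0")


@dataclass(frozen=True)
class ElementConstants:
    """Atomic mass (g/mol) and heavy-isotope label for one element."""

    element: str
    atomic_mass: float
    heavy_isotope_label: str

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if not self.atomic_mass > 0:
            raise ValueError("atomic mass must be > 0")


@dataclass(frozen=True)
class ConstantsRegistry:
    """One standard and one set of element constants per element."""

    standards: Mapping[str, IsotopeStandard]
    elements: Mapping[str, ElementConstants]

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            if el not in self.standards or el not in self.elements:
                raise ValueError(f"registry incomplete: missing element {el}")
        for el, std in self.standards.items():
            if std.element != el:
                raise ValueError("standard keyed under wrong element")

    def standard(self, element: str) -> IsotopeStandard:
        return self.standards[element]

    def element(self, element: str) -> ElementConstants:
        return self.elements[element]

    def to_dict(self) -> dict:
        return {
            "standards": {
                el: {"name": s.name, "ratio": s.ratio}
                for el, s in self.standards.items()
            },
            "elements": {
                el: {
                    "atomic_mass": e.atomic_mass,
                    "heavy_isotope_label": e.heavy_isotope_label,
                }
                for el, e in self.elements.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConstantsRegistry":
        base = default_registry().to_dict()
        for section in ("standards", "elements"):
            for el, override in d.get(section, {}).items():
                base[section][el].update(override)
        return cls(
            standards={
                el: IsotopeStandard(element=el, **v)
                for el, v in base["standards"].items()
            },
            elements={
                el: ElementConstants(element=el, **v)
                for el, v in base["elements"].items()
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "ConstantsRegistry":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_registry() -> ConstantsRegistry:
    # Community-standard values: VPDB 13C/12C and atmospheric-N2 15N/14N.
    return ConstantsRegistry(
        standards={
            "C": IsotopeStandard("C", "VPDB", 0.011180),
            "N": IsotopeStandard("N", "AIR", 0.0036765),
        },
        elements={
            "C": ElementConstants("C", 12.011, "13C"),
            "N": ElementConstants("N", 14.007, "15N"),
        },
    )


DEFAULT_REGISTRY = default_registry()
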