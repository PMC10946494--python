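"""Spin-system registry: identities of the modelled 1H NMR signals.

A :class:`SpinSystem` names one proton group of one metabolite (e.g. the valine
methyl doublet) together with its nominal chemical shift and chemical class.
A :class:`Registry` is an ordered, id-unique collection of spin systems; the
packaged default registry covers the 16 serum/plasma systems this package
ships models for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import yaml

MULTIPLICITIES = frozenset({"singlet", "doublet", "triplet", "multiplet"})
CHEMICAL_CLASSES = frozenset(
    {"amino_acid", "carboxylic_acid", "sugar", "alcohol", "ketone", "other"}
)

#: Chemical classes that behave as one group under shared matrix effects.
#: Sugars co-vary with the carboxylic acids (glucose joins the lactate
#: sub-map) and alcohols with ketones (ethanol predicts acetone).
CLASS_GROUPS = {
    "amino_acid": "amino_acid",
    "carboxylic_acid": "acid_sugar",
    "sugar": "acid_sugar",
    "alcohol": "alcohol_ketone",
    "ketone": "alcohol_ketone",
    "other": "other",
}


class RegistryError(ValueError):
    """Malformed registry definition (duplicate ids, bad enum values...)."""


@dataclass(frozen=True)
class SpinSystem:
    """One modelled 1H signal: metabolite + proton group.

    Parameters
    ----------
    id : str
        Short unique token, e.g. ``"valine_CH3"``.
    metabolite : str
        Metabolite name.
    group : str
        Proton-group label, e.g. ``"-CH3"`` or ``"anomeric CH"``.
    multiplicity : str
        One of singlet / doublet / triplet / multiplet. A singlet's recorded
        position is the peak maximum itself (multiplet centering is the
        identity).
    nominal_delta : float
        Reference chemical shift in ppm; must lie in (0, 12).
    chemical_class : str
        One of amino_acid / carboxylic_acid / sugar / alcohol / ketone / other.
    """

    id: str
    metabolite: str
    group: str
    multiplicity: str
    nominal_delta: float
    chemical_class: str = "other"

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise RegistryError(
                f"{self.id}: unknown multiplicity {self.multiplicity!r}"
            )
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise RegistryError(
                f"{self.id}: unknown chemical_class {self.chemical_class!r}"
            )
        if not 0.0 < self.nominal_delta < 12.0:
            raise RegistryError(
                f"{self.id}: nominal_delta {self.nominal_delta} outside (0, 12) ppm"
            )

    @property
    def class_group(self) -> str:
        """Matrix-effect group this system belongs to (see CLASS_GROUPS)."""
        return CLASS_GROUPS[self.chemical_class]


class Registry:
    """Ordered collection of :class:`SpinSystem` with unique ids."""

    def __init__(self, systems: Iterable[SpinSystem]):
        self._systems: dict[str, SpinSystem] = {}
        for s in systems:
            if s.id in self._systems:
                raise RegistryError(f"duplicate spin-system id {s.id!r}")
            self._systems[s.id] = s

    def __len__(self) -> int:
        return len(self._systems)

    def __iter__(self) -> Iterator[SpinSystem]:
        return iter(self._systems.values())

    def __contains__(self, system_id: str) -> bool:
        return system_id in self._systems

    def __getitem__(self, system_id: str) -> SpinSystem:
        try:
            return self._systems[system_id]
        except KeyError:
            raise KeyError(f"unknown spin system {system_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return list(self._systems)

    def class_of(self, system_id: str) -> str:
        return self[system_id].chemical_class

    def group_of(self, system_id: str) -> str:
        return self[system_id].class_group

    # ---- serialization -------------------------------------------------

    @classmethod
    def from_mapping(cls, payload: dict) -> "Registry":
        return cls(SpinSystem(**entry) for entry in payload["systems"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Registry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def from_json(cls, path: str | Path) -> "Registry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_mapping(json.load(fh))

    def to_mapping(self) -> dict:
        return {"systems": [asdict(s) for s in self]}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)


def default_registry() -> Registry:
    """The packaged 16-system serum/plasma registry."""
    with resources.files("shiftmap.data").joinpath("registry.yaml").open(
        encoding="utf-8"
    ) as fh:
        return Registry.from_mapping(yaml.safe_load(fh))
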