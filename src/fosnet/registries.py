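"""Region and condition registries for the CTA c-Fos coactivation pipeline.

The study design samples Fos-positive cell counts in 11 brain regions under
six conditions: three acute stimuli (AN = acute NaCl, AB = acute Boost,
AL = acute LiCl) and three task-day conditions (COT = context-only task,
BOT = Boost-only task, BLT = Boost-LiCl task, i.e. CTA expression).

Every table and graph the pipeline emits orders regions and conditions by
these registries, so outputs are deterministic and comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "DEFAULT_REGIONS",
    "DEFAULT_REGION_ALIASES",
    "DEFAULT_CONDITION_ARMS",
    "RegionRegistry",
    "ConditionRegistry",
    "UnknownCodeError",
]

#: Canonical region codes, in reporting order: ventromedial prefrontal
#: cortex, agranular insula, granular insula layers 5/6 and layer 4,
#: accumbens core and shell, supraoptic and paraventricular hypothalamic
#: nuclei, basolateral and central amygdala, ventral tegmental area.
DEFAULT_REGIONS: tuple[str, ...] = (
    "vmPFC",
    "aIC",
    "gIC5/6",
    "gIC4",
    "NAcC",
    "NAcS",
    "SON",
    "BLA",
    "CeA",
    "PVN",
    "VTA",
)

#: Input synonyms -> canonical code. The granular-insula layer-4 region
#: appears in the literature both as "gICL4" and "gIC4"; slashes in
#: "gIC5/6" are awkward in file names so underscore/dash variants are
#: accepted too.
DEFAULT_REGION_ALIASES: Mapping[str, str] = {
    "gICL4": "gIC4",
    "gICL5/6": "gIC5/6",
    "gIC5_6": "gIC5/6",
    "gIC5-6": "gIC5/6",
    "gIC56": "gIC5/6",
}

#: Condition code -> experimental arm.
DEFAULT_CONDITION_ARMS: Mapping[str, str] = {
    "AN": "acute",
    "AB": "acute",
    "AL": "acute",
    "COT": "task",
    "BOT": "task",
    "BLT": "task",
}

SEXES: tuple[str, str] = ("F", "M")


class UnknownCodeError(ValueError):
    """An input used a region/condition code not present in the registry."""


@dataclass(frozen=True)
class RegionRegistry:
    """Ordered registry of brain-region codes with an alias map."""

    regions: tuple[str, ...] = DEFAULT_REGIONS
    aliases: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REGION_ALIASES))

    def __post_init__(self) -> None:
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region codes must be unique")
        for alias, target in self.aliases.items():
            if target not in self.regions:
                raise ValueError(f"alias {alias!r} maps to unknown region {target!r}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __contains__(self, code: object) -> bool:
        return code in self.regions or code in self.aliases

    def canonical(self, code: str) -> str:
        """Resolve ``code`` (possibly an alias) to its canonical region code."""
        if code in self.regions:
            return code
        if code in self.aliases:
            return self.aliases[code]
        raise UnknownCodeError(f"unknown region code {code!r}; known: {list(self.regions)}")

    def index(self, code: str) -> int:
        return self.regions.index(self.canonical(code))

    def sort_key(self, code: str) -> int:
        return self.index(code)


@dataclass(frozen=True)
class ConditionRegistry:
    """Ordered registry of condition codes, each tagged with its arm."""

    arms: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_CONDITION_ARMS))

    def __post_init__(self) -> None:
        bad = {arm for arm in self.arms.values()} - {"acute", "task"}
        if bad:
            raise ValueError(f"unknown arm tag(s): {sorted(bad)}")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.arms.keys())

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self):
        return iter(self.arms)

    def __contains__(self, code: object) -> bool:
        return code in self.arms

    def arm(self, code: str) -> str:
        try:
            return self.arms[code]
        except KeyError:
            raise UnknownCodeError(
                f"unknown condition code {code!r}; known: {list(self.arms)}"
            ) from None

    def canonical(self, code: str) -> str:
        if code not in self.arms:
            raise UnknownCodeError(
                f"unknown condition code {code!r}; known: {list(self.arms)}"
            )
        return code

    def index(self, code: str) -> int:
        return self.conditions.index(self.canonical(code))

    def subset(self, codes: Iterable[str]) -> tuple[str, ...]:
        """Return ``codes`` deduplicated and sorted into registry order."""
        wanted = {self.canonical(c) for c in codes}
        return tuple(c for c in self.conditions if c in wanted)
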