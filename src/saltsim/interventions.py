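"""Salt-restriction interventions as transformations of the sodium source mix.

Two China-specific strategies are modelled:

* **salt-restriction spoon** — a measuring spoon caps the sodium added as
  cooking salt at the spoon's sodium content (a full 2-g spoon holds
  788 mg sodium; quarter/half/three-quarter spoons 197/394/591 mg);
* **salt substitute** — a fraction of each of the five high-sodium food
  categories (added salt, soy sauce, MSG, fermented, pickled) is replaced
  by a blend of 65 % NaCl, 25 % KCl and 10 % MgSO4, multiplying the
  replaced portion's sodium by the NaCl share.

Both act on a person's sodium decomposition by source category (g/day) and
never increase any category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from ._demography import SOURCE_CATEGORIES, SUBSTITUTABLE_CATEGORIES

__all__ = [
    "ScenarioSpec",
    "apply_spoon",
    "apply_substitute",
    "apply_scenario",
    "spoon_cap_matrix",
    "substitute_matrix",
]

SPOON_SIZES_MG = (197.0, 394.0, 591.0, 788.0)
SUBSTITUTE_FRACTIONS = (0.65, 0.75, 0.85, 0.95)

_ADDED_SALT_IDX = SOURCE_CATEGORIES.index("added_salt")
_SUB_IDX = [SOURCE_CATEGORIES.index(c) for c in SUBSTITUTABLE_CATEGORIES]


@dataclass(frozen=True)
class ScenarioSpec:
    """Kind-discriminated intervention definition.

    kind "none" needs no further fields; "spoon" needs ``spoon_sodium_mg``;
    "substitute" needs ``substitute_fraction`` (share of high-sodium foods
    replaced) and ``substitute_nacl_share`` (default 0.65).  ``uptake`` is
    the adopting share of the population, default full compliance.
    """

    kind: str = "none"
    spoon_sodium_mg: float | None = None
    substitute_fraction: float | None = None
    substitute_nacl_share: float = 0.65
    start_year: int = 2010
    uptake: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "spoon", "substitute"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "spoon":
            if self.spoon_sodium_mg is None or self.spoon_sodium_mg < 0:
                raise ValueError("spoon scenario needs nonnegative spoon_sodium_mg")
            if self.substitute_fraction is not None:
                raise ValueError("spoon scenario must not set substitute_fraction")
        elif self.kind == "substitute":
            if self.substitute_fraction is None or not 0 <= self.substitute_fraction <= 1:
                raise ValueError("substitute scenario needs substitute_fraction in [0, 1]")
            if self.spoon_sodium_mg is not None:
                raise ValueError("substitute scenario must not set spoon_sodium_mg")
            if not 0 <= self.substitute_nacl_share <= 1:
                raise ValueError("substitute_nacl_share must lie in [0, 1]")
        elif self.spoon_sodium_mg is not None or self.substitute_fraction is not None:
            raise ValueError("scenario kind 'none' takes no intervention fields")
        if not 0 <= self.uptake <= 1:
            raise ValueError("uptake must lie in [0, 1]")

    @property
    def scenario_id(self) -> str:
        if self.kind == "spoon":
            return f"spoon-{self.spoon_sodium_mg:g}mg"
        if self.kind == "substitute":
            return f"substitute-{self.substitute_fraction:g}"
        return "none"

    def to_yaml(self, path) -> None:
        import dataclasses
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _check_map(sodium_by_source: Mapping[str, float]) -> None:
    unknown = set(sodium_by_source) - set(SOURCE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown source categories: {sorted(unknown)}")
    if any(v < 0 for v in sodium_by_source.values()):
        raise ValueError("sodium by source must be nonnegative")


def apply_spoon(sodium_by_source: Mapping[str, float],
                spoon_sodium_mg: float) -> dict[str, float]:
    """Cap added-salt sodium at the spoon's content; other sources unchanged."""
    if spoon_sodium_mg < 0:
        raise ValueError("spoon sodium content must be nonnegative")
    _check_map(sodium_by_source)
    out = dict(sodium_by_source)
    if "added_salt" in out:
        out["added_salt"] = min(out["added_salt"], spoon_sodium_mg / 1000.0)
    return out


def apply_substitute(sodium_by_source: Mapping[str, float], fraction: float,
                     nacl_share: float = 0.65) -> dict[str, float]:
    """Replace ``fraction`` of each high-sodium category by the low-sodium
    blend: new = old * ((1 - fraction) + fraction * nacl_share); the
    "other" category is untouched."""
    if not 0 <= fraction <= 1 or not 0 <= nacl_share <= 1:
        raise ValueError("fraction and nacl_share must lie in [0, 1]")
    _check_map(sodium_by_source)
    factor = (1.0 - fraction) + fraction * nacl_share
    return {c: (v * factor if c in SUBSTITUTABLE_CATEGORIES else v)
            for c, v in sodium_by_source.items()}


def apply_scenario(person_sources: Mapping[str, float], scenario: ScenarioSpec,
                   year: int, rng: np.random.Generator) -> dict[str, float]:
    """Dispatch one person's source mix through the scenario's transformation.

    Identity before ``start_year``, for kind "none", or when the person is
    not drawn into the adopting share."""
    if scenario.kind == "none" or year < scenario.start_year:
        return dict(person_sources)
    if rng.random() >= scenario.uptake:
        return dict(person_sources)
    if scenario.kind == "spoon":
        return apply_spoon(person_sources, scenario.spoon_sodium_mg)
    return apply_substitute(person_sources, scenario.substitute_fraction,
                            scenario.substitute_nacl_share)


# -- vectorised forms used by the simulation loop --------------------------

def spoon_cap_matrix(sodium_matrix: np.ndarray, spoon_sodium_mg: float) -> np.ndarray:
    """Vectorised spoon cap on an (n, 6) sodium-by-category matrix."""
    if spoon_sodium_mg < 0:
        raise ValueError("spoon sodium content must be nonnegative")
    out = np.array(sodium_matrix, dtype=float)
    out[:, _ADDED_SALT_IDX] = np.minimum(out[:, _ADDED_SALT_IDX],
                                         spoon_sodium_mg / 1000.0)
    return out


def substitute_matrix(sodium_matrix: np.ndarray, fraction: float,
                      nacl_share: float = 0.65) -> np.ndarray:
    """Vectorised substitution on an (n, 6) sodium-by-category matrix."""
    if not 0 <= fraction <= 1 or not 0 <= nacl_share <= 1:
        raise ValueError("fraction and nacl_share must lie in [0, 1]")
    out = np.array(sodium_matrix, dtype=float)
    out[:, _SUB_IDX] *= (1.0 - fraction) + fraction * nacl_share
    return out
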