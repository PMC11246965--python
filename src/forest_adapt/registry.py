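"""Registry of the stand-forming tree species and their model parameters.

Fifteen taxa are evaluated as main stand-forming species: six natives
(with the two white oaks *Quercus petraea* and *Q. robur* merged into a
single *Quercus* spp. entry, because national forest-inventory data does
not separate them) and nine non-native tree species (NNT).

Each species carries

* a mean model cut-off (percent): the occurrence-probability threshold
  below which a site is considered climatically unsuitable,
* a mean annual volume increment (m³ over bark ha⁻¹ yr⁻¹), and
* the standardized increment (increment relative to the all-species mean
  of about 12.6 m³), the dimensionless productivity score used downstream,

plus trait flags (native, conifer, evergreen).  The evergreen flag marks
"wintergreen" canopy for the avalanche-protection rules; the only
deciduous conifer among the defaults is *Larix decidua*.

The built-in standardized values are canonical for scoring and are used
verbatim rather than recomputed; :func:`standardize_increments` exists
for user-supplied increment sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SpeciesProfile",
    "SpeciesRegistry",
    "load_registry",
    "standardize_increments",
    "DEFAULT_SPECIES",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Parameters and traits of one stand-forming taxon."""

    code: str
    scientific_name: str
    native: bool
    conifer: bool
    evergreen: bool
    cutoff: float        # percent in (0, 100]
    increment: float     # m3 over bark / ha / yr
    increment_std: float # dimensionless, ~increment / mean increment

    def __post_init__(self) -> None:
        if not (0 < self.cutoff <= 100):
            raise ValueError(f"{self.code}: cutoff must be in (0, 100], got {self.cutoff}")
        if self.increment <= 0:
            raise ValueError(f"{self.code}: increment must be positive, got {self.increment}")
        if self.increment_std <= 0:
            raise ValueError(f"{self.code}: increment_std must be positive, got {self.increment_std}")

    @property
    def traits(self) -> tuple[bool, bool, bool]:
        return (self.native, self.conifer, self.evergreen)


# Default parameter set: cut-off [%], increment [m3/ha/yr], standardized
# increment.  Trait flags for the nine NNT follow standard botany: all
# NNT conifers are evergreen, all NNT broadleaves deciduous.
DEFAULT_SPECIES: tuple[SpeciesProfile, ...] = (
    SpeciesProfile("aal", "Abies alba", True, True, True, 46.4, 15.59, 1.26),
    SpeciesProfile("fsy", "Fagus sylvatica", True, False, False, 50.2, 8.17, 0.66),
    SpeciesProfile("lde", "Larix decidua", True, True, False, 52.1, 7.76, 0.62),
    SpeciesProfile("pab", "Picea abies", True, True, True, 56.5, 11.77, 0.95),
    SpeciesProfile("psy", "Pinus sylvestris", True, True, True, 63.1, 7.47, 0.60),
    SpeciesProfile("que", "Quercus spp.", True, False, False, 48.3, 9.64, 0.78),
    SpeciesProfile("agr", "Abies grandis", False, True, True, 65.0, 31.85, 2.56),
    SpeciesProfile("fpe", "Fraxinus pennsylvanica", False, False, False, 56.7, 3.65, 0.29),
    SpeciesProfile("jni", "Juglans nigra", False, False, False, 62.8, 9.57, 0.77),
    SpeciesProfile("pco", "Pinus contorta", False, True, True, 69.1, 3.85, 0.31),
    SpeciesProfile("pra", "Pinus radiata", False, True, True, 53.2, 22.50, 1.81),
    SpeciesProfile("pme", "Pseudotsuga menziesii", False, True, True, 46.4, 19.08, 1.54),
    SpeciesProfile("qru", "Quercus rubra", False, False, False, 59.2, 11.15, 0.90),
    SpeciesProfile("rps", "Robinia pseudoacacia", False, False, False, 66.9, 10.68, 0.86),
    SpeciesProfile("tpl", "Thuja plicata", False, True, True, 55.5, 16.38, 1.32),
)

_REQUIRED_COLUMNS = (
    "code",
    "scientific_name",
    "native",
    "conifer",
    "evergreen",
    "cutoff",
    "increment",
    "increment_std",
)


class SpeciesRegistry:
    """Immutable lookup of :class:`SpeciesProfile` by species code."""

    def __init__(self, profiles: Iterable[SpeciesProfile]):
        profiles = tuple(profiles)
        codes = [p.code for p in profiles]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise ValueError(f"duplicate code: {sorted(dupes)}")
        self._profiles: dict[str, SpeciesProfile] = {p.code: p for p in profiles}

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self):
        return iter(self._profiles.values())

    def __contains__(self, code: str) -> bool:
        return code in self._profiles

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._profiles)

    def get(self, code: str) -> SpeciesProfile:
        try:
            return self._profiles[code]
        except KeyError:
            raise KeyError(f"unknown species code: {code!r}") from None

    def traits(self, code: str) -> tuple[bool, bool, bool]:
        """(native, conifer, evergreen) for a registered species."""
        return self.get(code).traits

    def cutoff(self, code: str) -> float:
        return self.get(code).cutoff

    @property
    def native_codes(self) -> tuple[str, ...]:
        return tuple(c for c, p in self._profiles.items() if p.native)

    @property
    def nonnative_codes(self) -> tuple[str, ...]:
        return tuple(c for c, p in self._profiles.items() if not p.native)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(p) for p in self]).set_index("code")


def load_registry(override_source: str | Path | None = None) -> SpeciesRegistry:
    """Return the built-in default registry, or one read from a file.

    An override file is delimited text with a header naming every
    :class:`SpeciesProfile` field, one row per species.  Boolean columns
    accept true/false, yes/no, 1/0 (case-insensitive).
    """
    if override_source is None:
        return SpeciesRegistry(DEFAULT_SPECIES)

    df = pd.read_csv(override_source)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required field: {missing}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            SpeciesProfile(
                code=str(row["code"]),
                scientific_name=str(row["scientific_name"]),
                native=_as_bool(row["native"]),
                conifer=_as_bool(row["conifer"]),
                evergreen=_as_bool(row["evergreen"]),
                cutoff=float(row["cutoff"]),
                increment=float(row["increment"]),
                increment_std=float(row["increment_std"]),
            )
        )
    return SpeciesRegistry(profiles)


def _as_bool(value) -> bool:
    if isinstance(value, (bool,)):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "yes", "1", "t", "y"}:
        return True
    if s in {"false", "no", "0", "f", "n"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def standardize_increments(increments: Mapping[str, float]) -> dict[str, float]:
    """Divide each increment by the arithmetic mean over the supplied set.

    The result is dimensionless with mean 1; multiplying every input by
    the same positive constant leaves the output unchanged.
    """
    if not increments:
        raise ValueError("empty increment map")
    bad = {k: v for k, v in increments.items() if not (v > 0) or not math.isfinite(v)}
    if bad:
        raise ValueError(f"non-positive value: {bad}")
    mean = sum(increments.values()) / len(increments)
    return {k: v / mean for k, v in increments.items()}
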