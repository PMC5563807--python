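"""Husbandry reference profiles.

Four named models are conventionally used: two post-lactation slaughter
profiles (dairy-compatible, calf cull after weaning at 6-15 months),
an intensive-milk profile (cull before 6 months) and a meat profile
(slaughter peak at prime weight, 3-6 years).

The shipped defaults are SCHEMATIC: they satisfy the qualitative shape of
each strategy (peak class, secondary adult slaughter) but are not digitized
from any published assemblage.  Supply your own CSV of (model, class,
proportion) to reproduce a specific study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .io_model import AgeClassScheme, ReferenceProfile, default_scheme


@dataclass(frozen=True)
class ReferenceSet:
    """Named reference profiles, all defined on the same scheme."""

    profiles: dict[str, ReferenceProfile]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("reference set is empty")

    @property
    def names(self) -> list[str]:
        return list(self.profiles)

    def __getitem__(self, name: str) -> ReferenceProfile:
        return self.profiles[name]


def load_reference_set(
    path: str | Path, scheme: AgeClassScheme, provenance: dict[str, str] | None = None
) -> ReferenceSet:
    """Load references from a CSV of (model, class, proportion).

    Every model must define a proportion for every class of ``scheme`` and
    sum to 1 within 1e-9.
    """
    df = pd.read_csv(path, dtype={"model": str, "class": str})
    missing = {"model", "class", "proportion"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles: dict[str, ReferenceProfile] = {}
    for model, grp in df.groupby("model", sort=False):
        by_class = dict(zip(grp["class"], grp["proportion"].astype(float)))
        absent = [lbl for lbl in scheme.labels if lbl not in by_class]
        if absent:
            raise ValueError(f"model {model!r}: no proportion for classes {absent}")
        props = tuple(by_class[lbl] for lbl in scheme.labels)
        profiles[str(model)] = ReferenceProfile(name=str(model), proportions=props)
    return ReferenceSet(profiles=profiles, provenance=provenance or {})


def schematic_reference_set(scheme: AgeClassScheme | None = None) -> ReferenceSet:
    """The shipped schematic defaults (testing / simulation only)."""
    scheme = scheme or default_scheme()
    with resources.as_file(
        resources.files("mortprof.data").joinpath("schematic_references.csv")
    ) as p:
        rs = load_reference_set(p, scheme)
    prov = {name: "schematic default (not digitized from any assemblage)"
            for name in rs.names}
    return ReferenceSet(profiles=rs.profiles, provenance=prov)
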