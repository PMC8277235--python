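"""Expressive-power comparison of information models.

An information-model profile is an attribute subset of the schema. A gold
instance is precisely representable under a profile iff its annotation
captured the full original semantics (equal_to_original = full) AND every
non-default attribute it uses belongs to the profile. Percentages are
therefore monotone in the subset ordering: a richer model never represents
fewer descriptions precisely. The shipped profiles approximate the full
12-attribute model, the clinical element model (assertion + severity +
laterality), the FHIR condition model (severity + laterality) and the bare
concept-only baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml

from .model import AttributeSchema, PhenoSSUError, PhenoSSUInstance


@dataclass(frozen=True)
class InformationModelProfile:
    name: str
    attribute_names: frozenset[str]

    def validate(self, schema: AttributeSchema) -> None:
        unknown = self.attribute_names - set(schema.names)
        if unknown:
            raise PhenoSSUError(
                f"profile {self.name!r} names unknown attributes: {sorted(unknown)}"
            )


def load_profiles(path: str | Path) -> list[InformationModelProfile]:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "profiles" not in raw:
        raise PhenoSSUError("profiles config must be a mapping with a 'profiles' list")
    return [
        InformationModelProfile(
            name=str(p["name"]), attribute_names=frozenset(p.get("attributes", ()))
        )
        for p in raw["profiles"]
    ]


def default_profiles() -> list[InformationModelProfile]:
    with resources.as_file(
        resources.files("phenossu.data").joinpath("profiles.yaml")
    ) as p:
        return load_profiles(p)


def representable(
    instance: PhenoSSUInstance,
    profile: InformationModelProfile,
    schema: AttributeSchema,
) -> bool:
    """True iff the instance's full semantics survive projection onto the
    profile's attribute subset."""
    if instance.equal_to_original != "full":
        return False
    nondefault = instance.nondefault_values(schema)
    return set(nondefault) <= profile.attribute_names


@dataclass(frozen=True)
class ProfileRow:
    profile: str
    count_precise: int
    total: int

    @property
    def percentage(self) -> float:
        return round(100.0 * self.count_precise / self.total, 1)


def compare_profiles(
    corpus_instances: Sequence[PhenoSSUInstance],
    profiles: Sequence[InformationModelProfile],
    schema: AttributeSchema,
) -> list[ProfileRow]:
    """One row per profile: how many gold instances it represents precisely,
    out of the total, with the percentage to 1 decimal."""
    if not corpus_instances:
        raise PhenoSSUError("profile comparison undefined on empty corpus")
    total = len(corpus_instances)
    rows = []
    for profile in profiles:
        profile.validate(schema)
        count = sum(
            1 for inst in corpus_instances if representable(inst, profile, schema)
        )
        rows.append(ProfileRow(profile=profile.name, count_precise=count, total=total))
    return rows


def comparison_report(rows: Sequence[ProfileRow]) -> str:
    lines = ["profile\tprecise\ttotal\tpercentage"]
    for row in rows:
        lines.append(f"{row.profile}\t{row.count_precise}\t{row.total}\t{row.percentage}")
    return "\n".join(lines) + "\n"
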