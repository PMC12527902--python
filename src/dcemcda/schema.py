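"""Attribute/level data model and design-vector encoding for the orphan-drug DCE.

The default schema packages the seven value attributes used in the
orphan-drug reimbursement choice experiment: three disease/treatment
domains (disease severity, unmet needs, drug efficacy, improvement in
health-related quality of life, drug safety, quality of drug evidence)
plus the annual treatment cost reimbursed by basic medical insurance.
Each attribute carries three levels ordered worst-to-best, with the worst
level as the dummy-coding reference, so a profile encodes into a
13-entry design vector: 6 categorical attributes x 2 non-reference
dummies + 1 continuous cost entry (units of 10,000 RMB/year).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AttributeLevel",
    "Attribute",
    "AttributeSchema",
    "Profile",
    "SchemaMismatchError",
    "default_orphan_drug_schema",
    "encode_profile",
    "enumerate_full_factorial",
]

#: A profile maps attribute name -> chosen level ordinal.
Profile = Mapping[str, int]


class SchemaMismatchError(ValueError):
    """A profile or coefficient set does not match the attribute schema."""


@dataclass(frozen=True)
class AttributeLevel:
    """One level of an attribute.

    ``ordinal`` is the 0-based position within the attribute; ordinal 0 is
    the reference by default.  ``numeric_value`` is set only for continuous
    attributes (for cost: units of 10,000 RMB/year).
    """

    label: str
    ordinal: int
    numeric_value: float | None = None


@dataclass(frozen=True)
class Attribute:
    name: str
    domain_tag: str  # disease-related | drug/treatment-related | cost-related
    kind: str  # "categorical" | "continuous"
    levels: tuple[AttributeLevel, ...]
    reference_ordinal: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown attribute kind {self.kind!r}")
        ordinals = [lv.ordinal for lv in self.levels]
        if sorted(ordinals) != list(range(len(self.levels))):
            raise ValueError(f"{self.name}: level ordinals must be 0..n-1 and unique")
        if not 0 <= self.reference_ordinal < len(self.levels):
            raise ValueError(f"{self.name}: reference_ordinal out of range")
        if self.kind == "continuous":
            values = [lv.numeric_value for lv in self.levels]
            if any(v is None for v in values):
                raise ValueError(f"{self.name}: continuous levels need numeric_value")
            diffs = np.diff(np.asarray(values, dtype=float))
            if not (np.all(diffs > 0) or np.all(diffs < 0)):
                raise ValueError(f"{self.name}: numeric values must be strictly monotone")
        else:
            if any(lv.numeric_value is not None for lv in self.levels):
                raise ValueError(f"{self.name}: categorical levels must not carry numeric_value")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level(self, ordinal: int) -> AttributeLevel:
        for lv in self.levels:
            if lv.ordinal == ordinal:
                return lv
        raise SchemaMismatchError(f"{self.name}: no level with ordinal {ordinal}")

    @property
    def numeric_span(self) -> float:
        """max - min of numeric level values (continuous attributes only)."""
        if self.kind != "continuous":
            raise ValueError(f"{self.name} is not continuous")
        values = [float(lv.numeric_value) for lv in self.levels]  # type: ignore[arg-type]
        return max(values) - min(values)


@dataclass(frozen=True)
class AttributeSchema:
    """Ordered collection of attributes plus the coding convention.

    Dummy coding against each attribute's reference level is the default;
    the design vector stacks, in attribute order, one indicator per
    non-reference level of each categorical attribute followed by (for
    continuous attributes) the chosen level's numeric value.
    """

    attributes: tuple[Attribute, ...]
    coding: str = "dummy"

    def __post_init__(self) -> None:
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")
        if self.coding not in ("dummy", "effects"):
            raise ValueError(f"unknown coding {self.coding!r}")

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def attribute(self, name: str) -> Attribute:
        for a in self.attributes:
            if a.name == name:
                return a
        raise SchemaMismatchError(f"unknown attribute {name!r}")

    @property
    def design_vector_length(self) -> int:
        k = 0
        for a in self.attributes:
            k += 1 if a.kind == "continuous" else a.n_levels - 1
        return k

    @property
    def design_columns(self) -> list[str]:
        """Column labels for the design vector, in encoding order."""
        cols: list[str] = []
        for a in self.attributes:
            if a.kind == "continuous":
                cols.append(f"{a.short_name}")
            else:
                for lv in a.levels:
                    if lv.ordinal != a.reference_ordinal:
                        cols.append(f"{a.short_name}_{lv.ordinal}")
        return cols

    def column_attribute(self, column: str) -> Attribute:
        """The attribute a design column belongs to."""
        for a in self.attributes:
            if a.kind == "continuous" and column == a.short_name:
                return a
            if column.startswith(a.short_name + "_"):
                return a
        raise SchemaMismatchError(f"unknown design column {column!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "coding": self.coding,
            "attributes": [
                {
                    "name": a.name,
                    "domain_tag": a.domain_tag,
                    "kind": a.kind,
                    "reference_ordinal": a.reference_ordinal,
                    "levels": [
                        {"label": lv.label, "ordinal": lv.ordinal, "numeric_value": lv.numeric_value}
                        for lv in a.levels
                    ],
                }
                for a in self.attributes
            ],
        }
        text = json.dumps(payload, indent=2, ensure_ascii=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AttributeSchema":
        if isinstance(source, Path):
            text = source.read_text()
        elif source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        payload = json.loads(text)
        attrs = tuple(
            Attribute(
                name=a["name"],
                domain_tag=a["domain_tag"],
                kind=a["kind"],
                reference_ordinal=a["reference_ordinal"],
                levels=tuple(
                    AttributeLevel(
                        label=lv["label"],
                        ordinal=lv["ordinal"],
                        numeric_value=lv["numeric_value"],
                    )
                    for lv in a["levels"]
                ),
            )
            for a in payload["attributes"]
        )
        return cls(attributes=attrs, coding=payload.get("coding", "dummy"))


# Short machine-friendly names for design columns; attached here rather than
# stored so that user-built attributes get one automatically.
def _short_name(self: Attribute) -> str:
    mapping = {
        "Disease severity": "severity",
        "Unmet needs": "unmet",
        "Drug efficacy": "efficacy",
        "Improvement in health-related quality of life": "hrqol",
        "Drug safety": "safety",
        "Quality of drug evidence": "evidence",
        "Annual treatment cost per patient reimbursed by basic medical insurance": "cost_10k",
    }
    if self.name in mapping:
        return mapping[self.name]
    return self.name.lower().replace(" ", "_")


Attribute.short_name = property(_short_name)  # type: ignore[attr-defined]


def default_orphan_drug_schema() -> AttributeSchema:
    """The packaged seven-attribute, three-level orphan-drug value schema.

    Levels are listed worst-to-best so ordinal 0 is both the reference and
    the least attractive setting; cost is continuous with annual levels of
    500,000 / 200,000 / 80,000 RMB expressed as 50 / 20 / 8 (10,000 RMB).
    """

    def cat(name: str, domain: str, labels: list[str]) -> Attribute:
        return Attribute(
            name=name,
            domain_tag=domain,
            kind="categorical",
            levels=tuple(AttributeLevel(lbl, i) for i, lbl in enumerate(labels)),
        )

    attributes = (
        cat("Disease severity", "disease-related", ["Low", "Moderate", "High"]),
        cat(
            "Unmet needs",
            "drug/treatment-related",
            [
                "Mature treatments available with good clinical outcomes",
                "Controllable treatments available to manage disease progression",
                "No specific treatment available, only symptomatic/supportive treatment",
            ],
        ),
        cat(
            "Drug efficacy",
            "drug/treatment-related",
            ["Stabilizes disease", "Partially improves or alleviates", "Significantly improves or alleviates"],
        ),
        cat(
            "Improvement in health-related quality of life",
            "drug/treatment-related",
            [
                "No improvement in usual activity",
                "Partial improvement in usual activity",
                "Significant improvement in usual activity",
            ],
        ),
        cat(
            "Drug safety",
            "drug/treatment-related",
            [
                "May cause severe adverse reactions",
                "May cause moderate adverse reactions",
                "No or mild adverse reactions",
            ],
        ),
        cat("Quality of drug evidence", "drug/treatment-related", ["Low", "Moderate", "High"]),
        Attribute(
            name="Annual treatment cost per patient reimbursed by basic medical insurance",
            domain_tag="cost-related",
            kind="continuous",
            levels=(
                AttributeLevel("500,000 RMB", 0, 50.0),
                AttributeLevel("200,000 RMB", 1, 20.0),
                AttributeLevel("80,000 RMB", 2, 8.0),
            ),
        ),
    )
    return AttributeSchema(attributes=attributes)


def validate_profile(profile: Profile, schema: AttributeSchema) -> None:
    extra = set(profile) - set(schema.attribute_names)
    missing = set(schema.attribute_names) - set(profile)
    if extra or missing:
        raise SchemaMismatchError(f"profile attributes mismatch: extra={sorted(extra)}, missing={sorted(missing)}")
    for a in schema.attributes:
        ordinal = profile[a.name]
        if not 0 <= int(ordinal) < a.n_levels:
            raise SchemaMismatchError(f"{a.name}: ordinal {ordinal} out of range")


def encode_profile(profile: Profile, schema: AttributeSchema) -> np.ndarray:
    """Encode a profile into its design vector.

    Categorical attributes contribute one 0/1 indicator per non-reference
    level (all zero at the reference); continuous attributes contribute the
    chosen level's numeric value.  With ``coding="effects"`` the reference
    level contributes -1 on every indicator of its attribute instead.
    """
    validate_profile(profile, schema)
    out: list[float] = []
    for a in schema.attributes:
        ordinal = int(profile[a.name])
        if a.kind == "continuous":
            out.append(float(a.level(ordinal).numeric_value))  # type: ignore[arg-type]
            continue
        non_ref = [lv.ordinal for lv in a.levels if lv.ordinal != a.reference_ordinal]
        if ordinal == a.reference_ordinal and schema.coding == "effects":
            out.extend([-1.0] * len(non_ref))
        else:
            out.extend([1.0 if ordinal == o else 0.0 for o in non_ref])
    return np.asarray(out, dtype=float)


def enumerate_full_factorial(schema: AttributeSchema) -> list[dict[str, int]]:
    """All distinct profiles (every combination of level ordinals)."""
    if not schema.attributes:
        raise ValueError("schema has no attributes")
    names = schema.attribute_names
    ranges: Iterable[range] = (range(a.n_levels) for a in schema.attributes)
    return [dict(zip(names, combo)) for combo in itertools.product(*ranges)]
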