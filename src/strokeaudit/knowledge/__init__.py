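"""Shipped acute-stroke knowledge: schemas, terminology, guidelines.

``registry()`` and ``terminology_store()`` load the packaged schema
registry (16 archetypes) and code-system tables; ``load_guidelines()``
parses the three shipped guideline files.  The ``build_*`` functions
construct the same guidelines programmatically and are the source of
truth the shipped files are generated from.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from ..guideline import Guideline, parse_guideline, validate_guideline
from ..model import ArchetypeSchema, ElementDef, SchemaRegistry, SlotDef
from ..terminology import TerminologyStore, load_terminology_dir
from .content import (
    build_euro_criteria_guideline,
    build_nihss_guideline,
    build_thrombolysis_guideline,
)
from .criteria import (  # noqa: F401  (re-exported catalogue)
    CONTRAINDICATIONS, CRITERIA, EURO_CRITERIA, REPRESENTED, VERDICT_KEYS,
    CriterionSpec,
)

__all__ = [
    "data_dir", "registry", "terminology_store",
    "build_thrombolysis_guideline", "build_nihss_guideline",
    "build_euro_criteria_guideline",
    "load_guidelines", "load_guideline",
    "CONTRAINDICATIONS", "CRITERIA", "EURO_CRITERIA", "REPRESENTED",
    "VERDICT_KEYS", "CriterionSpec",
]

GUIDELINE_FILES = {
    "thrombolysis_contraindications": "thrombolysis_contraindications.gdl",
    "nihss_score": "nihss_score.gdl",
    "euro_stroke_criteria": "euro_stroke_criteria.gdl",
}


def data_dir() -> Path:
    return Path(str(resources.files(__package__) / "data"))


@lru_cache(maxsize=1)
def registry() -> SchemaRegistry:
    """The packaged 16-schema registry."""
    doc = yaml.safe_load((data_dir() / "schemas.yaml").read_text(encoding="utf-8"))
    reg = SchemaRegistry()
    for raw in doc["schemas"]:
        elements = tuple(
            ElementDef(
                path=e["path"],
                kind=e["kind"],
                name=e.get("name", ""),
                unit=e.get("unit"),
                codes=dict(e.get("codes", {})),
            )
            for e in raw.get("elements", [])
        )
        slots = tuple(
            SlotDef(s["item_tree_id"], s["prefix"]) for s in raw.get("slots", [])
        )
        reg.register_schema(
            ArchetypeSchema(raw["archetype_id"], raw["entry_type"], elements, slots)
        )
    return reg


@lru_cache(maxsize=1)
def terminology_store() -> TerminologyStore:
    """The packaged SNOMED CT / ICD-10 / ATC subset."""
    return load_terminology_dir(data_dir() / "terminology")


@lru_cache(maxsize=None)
def load_guideline(guideline_id: str) -> Guideline:
    """Parse one shipped guideline file (validated on load)."""
    filename = GUIDELINE_FILES[guideline_id]
    g = parse_guideline(
        (data_dir() / "guidelines" / filename).read_text(encoding="utf-8"))
    violations = validate_guideline(g, registry(), terminology_store())
    if violations:
        raise ValueError(
            f"shipped guideline {guideline_id} is invalid: "
            + "; ".join(map(str, violations))
        )
    return g


def load_guidelines() -> dict[str, Guideline]:
    """All three shipped guidelines keyed by id, in evaluation order."""
    return {gid: load_guideline(gid) for gid in GUIDELINE_FILES}
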