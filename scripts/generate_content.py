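"""Regenerate the shipped guideline files from their programmatic builders.

Run from the repository root after changing strokeaudit.knowledge.content:

    python scripts/generate_content.py
"""
from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from strokeaudit.guideline import serialize_guideline, validate_guideline  # noqa: E402
from strokeaudit import knowledge  # noqa: E402


def main() -> None:
    out_dir = Path(knowledge.data_dir()) / "guidelines"
    out_dir.mkdir(parents=True, exist_ok=True)
    builders = {
        "thrombolysis_contraindications.gdl": knowledge.build_thrombolysis_guideline,
        "nihss_score.gdl": knowledge.build_nihss_guideline,
        "euro_stroke_criteria.gdl": knowledge.build_euro_criteria_guideline,
    }
    registry = knowledge.registry()
    store = knowledge.terminology_store()
    for filename, build in builders.items():
        g = build()
        violations = validate_guideline(g, registry, store)
        if violations:
            raise SystemExit(
                f"{g.guideline_id}: " + "; ".join(str(v) for v in violations))
        (out_dir / filename).write_text(serialize_guideline(g), encoding="utf-8")
        print(f"wrote {out_dir / filename} ({len(g.rules)} rules)")


if __name__ == "__main__":
    main()
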