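"""The NIHSS instrument as shipped: 15 scored elements, maximum total 42.

Each element's recorded answer is a local level code ``at1<item><level>``;
the scoring rules translate the answer into its integer contribution and
a summation rule totals the contributions.
"""
from __future__ import annotations

from dataclasses import dataclass

_ITEMS: tuple[tuple[str, int], ...] = (
    ("Level of consciousness", 3),
    ("LOC questions", 2),
    ("LOC commands", 2),
    ("Best gaze", 2),
    ("Visual fields", 3),
    ("Facial palsy", 3),
    ("Motor arm left", 4),
    ("Motor arm right", 4),
    ("Motor leg left", 4),
    ("Motor leg right", 4),
    ("Limb ataxia", 2),
    ("Sensory", 2),
    ("Best language", 3),
    ("Dysarthria", 2),
    ("Extinction and inattention", 2),
)


@dataclass(frozen=True)
class NihssItem:
    index: int  # 1-based
    name: str
    max_score: int

    @property
    def answer_path(self) -> str:
        return f"/data[at0001]/items[at{100 + self.index:04d}]"

    @property
    def score_path(self) -> str:
        return f"/data[at0001]/items[at{200 + self.index:04d}]"

    def level_code(self, level: int) -> str:
        if not 0 <= level <= self.max_score:
            raise ValueError(f"item {self.index} has no level {level}")
        return f"at1{self.index:02d}{level}"

    @property
    def levels(self) -> tuple[tuple[str, int], ...]:
        return tuple((self.level_code(k), k) for k in range(self.max_score + 1))


NIHSS_ITEMS: tuple[NihssItem, ...] = tuple(
    NihssItem(i, name, mx) for i, (name, mx) in enumerate(_ITEMS, start=1)
)

MAX_TOTAL = sum(item.max_score for item in NIHSS_ITEMS)  # 42


def item_vector_for_total(total: int) -> dict[str, str]:
    """A deterministic answer vector (path -> level code) with a given sum.

    Fills items greedily in instrument order; used to construct probe cases
    with an exact target total.
    """
    if not 0 <= total <= MAX_TOTAL:
        raise ValueError(f"total must be within 0..{MAX_TOTAL}")
    remaining = total
    out: dict[str, str] = {}
    for item in NIHSS_ITEMS:
        take = min(item.max_score, remaining)
        out[item.answer_path] = item.level_code(take)
        remaining -= take
    assert remaining == 0
    return out
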