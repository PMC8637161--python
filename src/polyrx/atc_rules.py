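"""ATC exclusion rules and code utilities.

Decides which dispensations count toward the polypharmacy drug tally and
at which granularity distinct drugs are told apart. Distinct drugs are
counted at ATC level 5 (the full 7-character substance code), so a
fixed-dose combination product counts as one drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

from .config import DEFAULT_EXCLUDED_ATC_PREFIXES
from .records import ATC_LEVEL_LENGTH, DispensationRecord


@dataclass(frozen=True)
class AtcExclusionList:
    """Set of ATC prefixes; a code is excluded iff it starts with any of them."""

    prefixes: frozenset = frozenset(DEFAULT_EXCLUDED_ATC_PREFIXES)

    @classmethod
    def from_prefixes(cls, prefixes: Iterable[str]) -> "AtcExclusionList":
        return cls(frozenset(p.strip().upper() for p in prefixes))


DEFAULT_EXCLUSIONS = AtcExclusionList()


def is_excluded(atc_code: str, rules: AtcExclusionList = DEFAULT_EXCLUSIONS) -> bool:
    """True iff ``atc_code`` falls in an excluded ATC group (prefix match)."""
    if not atc_code or not atc_code.strip():
        raise ValueError("empty ATC code")
    code = atc_code.strip().upper()
    return any(code.startswith(p) for p in rules.prefixes)


def filter_claims(
    records: Iterable[DispensationRecord],
    rules: AtcExclusionList = DEFAULT_EXCLUSIONS,
) -> List[DispensationRecord]:
    """Drop excluded-ATC dispensations; order preserved."""
    return [r for r in records if not is_excluded(r.atc_code, rules)]


def drug_key(atc_code: str, level: int = 5) -> str:
    """Canonical prefix of an ATC code at the given classification level.

    Level 5 is the full 7-character substance code. Raises if the code is
    too short to carry the requested level.
    """
    if level not in ATC_LEVEL_LENGTH:
        raise ValueError(f"ATC level must be 1..5, got {level}")
    code = atc_code.strip().upper()
    length = ATC_LEVEL_LENGTH[level]
    if len(code) < length:
        raise ValueError(f"code {code!r} too short for ATC level {level}")
    return code[:length]


def concurrency_key(atc_code: str, level: int = 5) -> str:
    """Drug-distinction key used by the pipeline: the level-``level`` prefix,
    or the whole code when it is a legal truncation shorter than that level."""
    code = atc_code.strip().upper()
    length = ATC_LEVEL_LENGTH[level]
    return code if len(code) < length else code[:length]
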