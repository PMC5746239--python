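"""ATC (Anatomic Therapeutic Chemical) codes and their hierarchy dissimilarity.

The WHO ATC system encodes a medication at five nested levels:

====== ============================== ======= ==================
level  meaning                        chars   example (prefix)
====== ============================== ======= ==================
1      anatomical main group          1       ``N``
2      therapeutic subgroup           +2      ``N02``
3      pharmacological subgroup       +1      ``N02B``
4      chemical subgroup              +1      ``N02BE``
5      chemical substance             +2      ``N02BE01``
====== ============================== ======= ==================

so a valid code has length 1, 3, 4, 5, or 7 and follows the character
grammar ``L DD L L DD`` truncated at a level boundary (``L`` letter,
``D`` digit).

Two medications are compared by the deepest level at which their codes
agree, mapped to a small integer dissimilarity: 0 means the same
substance, 3 means no shared level of the hierarchy at all.  Under the
default map, paracetamol (``N02BE01``) is closer to an opioid such as
``N02AA05`` (shared therapeutic subgroup ``N02`` -> score 2) than to an
asthma medication such as ``R03AC02`` (nothing shared -> score 3).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Union

from .errors import ATCFormatError, ConfigError

__all__ = [
    "ATCCode",
    "DEFAULT_SCORE_MAP",
    "parse_atc",
    "shared_level",
    "atc_dissimilarity",
    "validate_score_map",
]

#: code length -> ATC level
_LENGTH_TO_LEVEL = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}
#: ATC level -> prefix length
LEVEL_PREFIX_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}
#: expected character class per position: 'L' letter, 'D' digit
_POSITION_CLASS = "LDDLLDD"

_LETTERS = frozenset(string.ascii_uppercase)
_DIGITS = frozenset(string.digits)

#: Default map from the deepest shared ATC level to the dissimilarity
#: score: identical substances score 0, agreement only at the chemical or
#: pharmacological subgroup scores 1, agreement only at the therapeutic
#: or anatomical group scores 2, and no agreement scores 3.
DEFAULT_SCORE_MAP: Mapping[int, int] = {5: 0, 4: 1, 3: 1, 2: 2, 1: 2, 0: 3}


def _validate_code(code: str) -> None:
    if not code:
        raise ATCFormatError("empty ATC code")
    if len(code) not in _LENGTH_TO_LEVEL:
        raise ATCFormatError(
            f"ATC code {code!r} has invalid length {len(code)}: "
            "valid lengths are 1 (level 1), 3 (level 2), 4 (level 3), "
            "5 (level 4) or 7 (level 5)"
        )
    for pos, (ch, cls) in enumerate(zip(code, _POSITION_CLASS), start=1):
        if cls == "L" and ch not in _LETTERS:
            raise ATCFormatError(
                f"ATC code {code!r}: position {pos} must be an uppercase "
                f"letter, found {ch!r}"
            )
        if cls == "D" and ch not in _DIGITS:
            raise ATCFormatError(
                f"ATC code {code!r}: position {pos} must be a digit, "
                f"found {ch!r}"
            )


@dataclass(frozen=True, order=True)
class ATCCode:
    """A validated ATC code at any of the five levels.

    Construct via :func:`parse_atc` to get whitespace/case
    canonicalization; direct construction requires the canonical
    (uppercase, stripped) form.
    """

    code: str

    def __post_init__(self) -> None:
        _validate_code(self.code)

    @property
    def level(self) -> int:
        """Hierarchy level (1-5), uniquely determined by code length."""
        return _LENGTH_TO_LEVEL[len(self.code)]

    def prefix(self, level: int) -> str:
        """The code truncated to ``level`` (requires level <= self.level)."""
        if not 1 <= level <= self.level:
            raise ConfigError(
                f"level {level} out of range 1..{self.level} for {self.code}"
            )
        return self.code[: LEVEL_PREFIX_LENGTH[level]]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.code


def parse_atc(raw: Union[str, ATCCode]) -> ATCCode:
    """Parse ``raw`` into a canonical :class:`ATCCode`.

    Whitespace is stripped and letters uppercased before validation;
    malformed input raises :class:`~comedclust.errors.ATCFormatError`
    naming the offending position.
    """
    if isinstance(raw, ATCCode):
        return raw
    if raw is None:
        raise ATCFormatError("ATC code is missing")
    return ATCCode(str(raw).strip().upper())


def shared_level(a: Union[str, ATCCode], b: Union[str, ATCCode]) -> int:
    """Deepest ATC level at which the two codes' prefixes agree (0-5).

    Truncated codes are compared on their available prefix, so the
    result is capped at the shallower code's level.
    """
    ca, cb = parse_atc(a), parse_atc(b)
    for level in range(min(ca.level, cb.level), 0, -1):
        if ca.prefix(level) == cb.prefix(level):
            return level
    return 0


def validate_score_map(score_map: Mapping[int, int]) -> Mapping[int, int]:
    """Check that a level->score map is total on levels 0..5."""
    missing = [lv for lv in range(6) if lv not in score_map]
    if missing:
        raise ConfigError(f"score map is missing levels {missing}")
    return score_map


def atc_dissimilarity(
    a: Union[str, ATCCode],
    b: Union[str, ATCCode],
    score_map: Mapping[int, int] | None = None,
) -> int:
    """Hierarchy dissimilarity between two medications.

    The deepest shared ATC level is mapped through ``score_map``
    (default :data:`DEFAULT_SCORE_MAP`), yielding a symmetric score in
    {0, 1, 2, 3}: 0 for the identical substance, 3 for codes with no
    common level.
    """
    if score_map is None:
        score_map = DEFAULT_SCORE_MAP
    return score_map[shared_level(a, b)]
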