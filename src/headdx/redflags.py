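"""Secondary-headache ("red flag") screening.

The screener walks an SNNOOP10-style alarm-feature profile and emits one
warning per positive flag, in the fixed profile-field order. Warnings are
annotations: they mark the primary-headache diagnosis as pending secondary
exclusion but never suppress it, mirroring a clinic workflow where the
decision to exclude a secondary cause rests with the physician.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .records import FlagWarning, PatientRecord, RedFlagProfile

__all__ = ["FLAG_ORDER", "screen", "requires_secondary_workup",
           "ScreeningError"]

#: deterministic emission order = declaration order of the profile fields
FLAG_ORDER: tuple[str, ...] = tuple(
    name for name in RedFlagProfile.model_fields if name != "other_flags"
)


class ScreeningError(ValueError):
    """Raised when screening cannot run because flags are unanswered."""


@lru_cache(maxsize=1)
def _severity_map() -> dict[str, dict[str, str]]:
    text = resources.files("headdx.data").joinpath("redflags.yaml").read_text()
    return yaml.safe_load(text)


def screen(record: PatientRecord) -> list[FlagWarning]:
    """One warning per positive flag; empty list iff every flag is negative.

    Raises :class:`ScreeningError` when the red-flag theme is absent so that
    screening can never silently pass.
    """
    profile = record.red_flags
    if profile is None:
        raise ScreeningError(
            "red-flag items unanswered: " + ", ".join(FLAG_ORDER))
    cfg = _severity_map()
    warnings: list[FlagWarning] = []
    for flag in FLAG_ORDER:
        if getattr(profile, flag):
            entry = cfg.get(flag, {})
            warnings.append(FlagWarning(
                flag_id=flag,
                message=entry.get("message", flag.replace("_", " ")),
                severity=entry.get("severity", "advisory"),
            ))
    for flag, value in sorted(profile.other_flags.items()):
        if value:
            warnings.append(FlagWarning(
                flag_id=flag, message=flag.replace("_", " "),
                severity="advisory"))
    return warnings


def requires_secondary_workup(warnings: list[FlagWarning]) -> bool:
    """Any positive flag routes the record to secondary-cause work-up."""
    return bool(warnings)
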