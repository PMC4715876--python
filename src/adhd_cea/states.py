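"""Severity health states for the ADHD cost-utility model.

The model tracks four ordinal severity states derived from the 7-point
Clinical Global Impression--Severity (CGI-S) scale:

* Normal   — CGI-S 1
* Mild     — CGI-S 2–3 (borderline / mildly ill)
* Moderate — CGI-S 4–5 (moderately / markedly ill)
* Severe   — CGI-S 6–7 (severely ill / among the most extremely ill)

State indices (0..3) order the states by increasing severity and are used
for every array in the package.
"""

from __future__ import annotations

from enum import IntEnum


class SeverityState(IntEnum):
    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3


STATE_NAMES: tuple[str, ...] = ("Normal", "Mild", "Moderate", "Severe")

N_STATES = 4

#: CGI-S score -> state index. The bands partition {1..7}.
CGIS_TO_STATE: dict[int, int] = {1: 0, 2: 1, 3: 1, 4: 2, 5: 2, 6: 3, 7: 3}

#: state index -> tuple of CGI-S scores in the band.
STATE_TO_CGIS: dict[int, tuple[int, ...]] = {0: (1,), 1: (2, 3), 2: (4, 5), 3: (6, 7)}


def state_index(name: str) -> int:
    """Return the 0-based severity index for a state name (case-insensitive)."""
    try:
        return STATE_NAMES.index(name.capitalize())
    except ValueError:
        raise KeyError(f"unknown severity state {name!r}; expected one of {STATE_NAMES}") from None


def cgis_to_state(score: int) -> int:
    """Map a CGI-S score (1..7) to its severity-state index."""
    try:
        return CGIS_TO_STATE[int(score)]
    except KeyError:
        raise ValueError(f"CGI-S score must be in 1..7, got {score}") from None
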