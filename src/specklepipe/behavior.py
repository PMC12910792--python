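"""Y-maze spontaneous alternation scoring.

An arm-entry sequence over the three maze arms is scored for working
memory: a spontaneous alternation is a window of three consecutive entries
visiting three distinct arms, counted over all overlapping windows, and the
score is alternations / (entries − 2) × 100 — the denominator being the
number of such windows.
"""

from __future__ import annotations

from typing import Sequence

__all__ = ["spontaneous_alternation_percent"]


def spontaneous_alternation_percent(entries: Sequence[str]) -> float:
    """Percentage of overlapping entry triplets visiting three distinct arms.

    ``entries`` is the ordered arm-entry list (alphabet of at most three
    arms; staying in the current arm is not an entry, so consecutive
    duplicates are invalid).  Requires at least three entries.
    """
    seq = [str(e) for e in entries]
    if len(set(seq)) > 3:
        raise ValueError("more than three distinct arms in the entry sequence")
    if any(a == b for a, b in zip(seq, seq[1:])):
        raise ValueError("consecutive duplicate entries are not valid arm entries")
    if len(seq) < 3:
        raise ValueError("need at least 3 entries to score alternations")
    alternations = sum(
        1 for i in range(len(seq) - 2) if len({seq[i], seq[i + 1], seq[i + 2]}) == 3
    )
    return alternations / (len(seq) - 2) * 100.0
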