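"""Rule-based refinement of predicted secondary-structure strings.

A single residue cannot fold into a helix or a sheet on its own: a helix
needs at least three contiguous residues and a sheet at least two.  The
filter exploits this to clean up isolated mispredictions.  Scanning the
predicted string with the window (i-1, i, i+1):

* Case H — if position i is predicted H and both neighbours are H, it is
  kept; otherwise the examined segment is extended to (i-3, ..., i+3) and
  position i is replaced with the majority structure of that segment.
* Case E — if position i is predicted E and at least one neighbour is E, it
  is kept; otherwise the same 7-position majority replacement applies.

Coil positions are never examined.  By default every rule reads the original
(frozen) prediction and writes to a fresh output, so replacements cannot
cascade within a pass and the result is independent of scan order; an
in-place sequential mode is available for comparison.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .metrics import SovVariant, q3, sov
from .sequences import StructureString, THREE_STATES


@dataclass(frozen=True)
class FilterConfig:
    window_extension: int = 3  # half-width of the examined segment
    in_place: bool = False  # sequential scan allowing cascades

    def __post_init__(self) -> None:
        if self.window_extension < 1:
            raise ValueError("window_extension must be >= 1")


DEFAULT_FILTER = FilterConfig()


def _majority(segment: str, current: str) -> str:
    counts = Counter(segment)
    best = max(counts.values())
    winners = [s for s in THREE_STATES if counts.get(s, 0) == best]
    if len(winners) > 1:
        return current  # tie: least intervention, keep the original label
    return winners[0]


def apply_filter(
    pred: StructureString | str, cfg: FilterConfig = DEFAULT_FILTER
) -> StructureString:
    """Apply the Case H / Case E consensus rules to a predicted string.

    Neighbours beyond the sequence ends count as "not H" / "not E", so a
    terminal singleton helix or strand is always majority-checked; the
    examined segment is clipped to the sequence bounds.
    """
    states = pred.states if isinstance(pred, StructureString) else pred
    for pos, ch in enumerate(states):
        if ch not in THREE_STATES:
            raise ValueError(f"invalid state {ch!r} at position {pos}")
    ext = cfg.window_extension
    frozen = states
    out = list(states)
    for i, ch in enumerate(frozen):
        src = "".join(out) if cfg.in_place else frozen
        left = src[i - 1] if i > 0 else None
        right = src[i + 1] if i + 1 < len(src) else None
        if src[i] == "H":
            if left == "H" and right == "H":
                continue
        elif src[i] == "E":
            if left == "E" or right == "E":
                continue
        else:
            continue  # C positions are never examined
        segment = src[max(0, i - ext) : i + ext + 1]
        out[i] = _majority(segment, src[i])
    return StructureString("".join(out))


def filter_report(
    before: StructureString | str,
    after: StructureString | str,
    truth: StructureString | str,
) -> tuple[float, float, float, float]:
    """(Q3 before, Q3 after, SOV99 before, SOV99 after) against the truth."""
    return (
        q3(truth, before),
        q3(truth, after),
        sov(truth, before, SovVariant.SOV99),
        sov(truth, after, SovVariant.SOV99),
    )
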