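"""Evaluation measures for three-state secondary-structure prediction.

Q3 is the per-residue accuracy: the percentage of positions whose predicted
class equals the observed class.  The segment-overlap score SOV is
segment-based: for each structure class it compares maximal observed
segments s1 with overlapping predicted segments s2 through

    (min ov(s1, s2) + delta(s1, s2)) / max ov(s1, s2) * len(s1),

where ``min ov`` is the actual overlap, ``max ov`` the total extent of the
pair, and delta an allowance for minor boundary disagreement.  Fragmenting a
single observed helix into several predicted pieces is penalized even when
the per-residue agreement is unchanged.

Two published variants are implemented.  The 1999 definition uses
delta = min(max ov - min ov, min ov, len(s1)//2, len(s2)//2) and normalizes
by N = sum of len(s1) over all (s1, s2) pairs plus len(s1) over observed
segments with no overlapping partner, pooled over the three classes.  The
1994 definition uses the more generous delta = min(max ov - min ov, min ov),
normalizes per class by the number of observed residues of that class, and
macro-averages the per-class scores (capped at 100, since one observed
segment overlapping several predictions can push the raw 1994 sum past its
normalizer).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .sequences import StructureString, THREE_STATES


class SovVariant(enum.Enum):
    SOV94 = "sov94"
    SOV99 = "sov99"


@dataclass(frozen=True)
class Segment:
    """A maximal run of one structure state, half-open [start, end)."""

    state: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have end > start")

    def __len__(self) -> int:
        return self.end - self.start


def _states(ss: StructureString | str) -> str:
    return ss.states if isinstance(ss, StructureString) else ss


def _check_pair(truth: str, pred: str) -> None:
    if len(truth) != len(pred):
        raise ValueError(
            f"length mismatch: truth has {len(truth)} residues, "
            f"prediction has {len(pred)}"
        )
    for name, s in (("truth", truth), ("prediction", pred)):
        for pos, ch in enumerate(s):
            if ch not in THREE_STATES:
                raise ValueError(f"{name}: invalid state {ch!r} at position {pos}")


def segmentize(ss: StructureString | str) -> list[Segment]:
    """Decompose a structure string into ordered maximal runs."""
    s = _states(ss)
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            segments.append(Segment(s[start], start, i))
            start = i
    return segments


def q3(truth: StructureString | str, pred: StructureString | str) -> float:
    """Three-state per-residue accuracy, as a percentage."""
    t, p = _states(truth), _states(pred)
    _check_pair(t, p)
    if not t:
        raise ValueError("q3 requires non-empty strings")
    matches = sum(a == b for a, b in zip(t, p))
    return 100.0 * matches / len(t)


def confusion_matrix(
    truth: StructureString | str, pred: StructureString | str
) -> np.ndarray:
    """3x3 counts, rows = actual class, columns = predicted, order H, E, C."""
    t, p = _states(truth), _states(pred)
    _check_pair(t, p)
    m = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(t, p):
        m[THREE_STATES.index(a), THREE_STATES.index(b)] += 1
    return m


def precision_recall(
    truth: StructureString | str, pred: StructureString | str
) -> tuple[dict[str, float], dict[str, float], np.ndarray]:
    """Per-class precision and recall (percentages) plus the confusion matrix.

    A class never predicted has undefined precision (NaN, never 0); a class
    absent from the truth has undefined recall.
    """
    m = confusion_matrix(truth, pred)
    return _pr_from_confusion(m) + (m,)


def _pr_from_confusion(m: np.ndarray) -> tuple[dict[str, float], dict[str, float]]:
    precision, recall = {}, {}
    for k, state in enumerate(THREE_STATES):
        col = m[:, k].sum()
        row = m[k, :].sum()
        precision[state] = 100.0 * m[k, k] / col if col else float("nan")
        recall[state] = 100.0 * m[k, k] / row if row else float("nan")
    return precision, recall


def _overlap(s1: Segment, s2: Segment) -> tuple[int, int]:
    """(min ov, max ov): actual overlap and total extent of a segment pair."""
    minov = min(s1.end, s2.end) - max(s1.start, s2.start)
    maxov = max(s1.end, s2.end) - min(s1.start, s2.start)
    return minov, maxov


def _class_pairs(
    truth: str, pred: str, state: str
) -> tuple[list[tuple[Segment, Segment]], list[Segment]]:
    """Overlapping (observed, predicted) pairs and unpaired observed segments."""
    obs = [s for s in segmentize(truth) if s.state == state]
    prd = [s for s in segmentize(pred) if s.state == state]
    pairs = []
    unpaired = []
    for s1 in obs:
        partners = [s2 for s2 in prd if _overlap(s1, s2)[0] > 0]
        if partners:
            pairs.extend((s1, s2) for s2 in partners)
        else:
            unpaired.append(s1)
    return pairs, unpaired


def _sov99_terms(truth: str, pred: str) -> tuple[float, int]:
    """(score sum, normalizer) pooled over classes, 1999 definitions."""
    total, N = 0.0, 0
    for state in THREE_STATES:
        pairs, unpaired = _class_pairs(truth, pred, state)
        for s1, s2 in pairs:
            minov, maxov = _overlap(s1, s2)
            delta = max(
                0, min(maxov - minov, minov, len(s1) // 2, len(s2) // 2)
            )
            total += (minov + delta) / maxov * len(s1)
            N += len(s1)
        N += sum(len(s1) for s1 in unpaired)
    return total, N


def _sov94_per_class(truth: str, pred: str) -> dict[str, float]:
    """Per-class 1994 scores (capped at 100) for classes present in truth."""
    scores: dict[str, float] = {}
    for state in THREE_STATES:
        n_obs = truth.count(state)
        if n_obs == 0:
            continue
        pairs, _ = _class_pairs(truth, pred, state)
        total = 0.0
        for s1, s2 in pairs:
            minov, maxov = _overlap(s1, s2)
            delta = min(maxov - minov, minov)
            total += (minov + delta) / maxov * len(s1)
        scores[state] = min(100.0, 100.0 * total / n_obs)
    return scores


def sov(
    truth: StructureString | str,
    pred: StructureString | str,
    variant: SovVariant = SovVariant.SOV99,
) -> float:
    """Segment-overlap score, 1994 or 1999 variant, in [0, 100]."""
    t, p = _states(truth), _states(pred)
    _check_pair(t, p)
    return sov_multi([t], [p], variant)


def sov_multi(
    truths: list[StructureString | str],
    preds: list[StructureString | str],
    variant: SovVariant = SovVariant.SOV99,
) -> float:
    """SOV pooled over several chains (sums pooled before normalization)."""
    ts = [_states(t) for t in truths]
    ps = [_states(p) for p in preds]
    for t, p in zip(ts, ps):
        _check_pair(t, p)
    if variant is SovVariant.SOV99:
        total, N = 0.0, 0
        for t, p in zip(ts, ps):
            tot, n = _sov99_terms(t, p)
            total += tot
            N += n
        return 100.0 * total / N if N else 100.0
    # SOV94: pool per-class sums and observed counts, then macro-average
    sums = {s: 0.0 for s in THREE_STATES}
    counts = {s: 0 for s in THREE_STATES}
    for t, p in zip(ts, ps):
        for state in THREE_STATES:
            n_obs = t.count(state)
            if n_obs == 0:
                continue
            pairs, _ = _class_pairs(t, p, state)
            for s1, s2 in pairs:
                minov, maxov = _overlap(s1, s2)
                delta = min(maxov - minov, minov)
                sums[state] += (minov + delta) / maxov * len(s1)
            counts[state] += n_obs
    per_class = [
        min(100.0, 100.0 * sums[s] / counts[s])
        for s in THREE_STATES
        if counts[s] > 0
    ]
    return float(np.mean(per_class)) if per_class else 100.0


@dataclass
class SovReport:
    """Pooled evaluation of predictions against reference structures."""

    q3: float
    sov94: float
    sov99: float
    confusion: np.ndarray
    precision: dict[str, float]
    recall: dict[str, float]
    n_total: int

    def __str__(self) -> str:  # display rounds to 2 decimals; values keep full precision
        lines = [
            f"Q3     {self.q3:6.2f}",
            f"SOV94  {self.sov94:6.2f}",
            f"SOV99  {self.sov99:6.2f}",
            f"N      {self.n_total}",
            "        " + "  ".join(f"pred {s}" for s in THREE_STATES),
        ]
        for k, s in enumerate(THREE_STATES):
            row = "  ".join(f"{self.confusion[k, j]:6d}" for j in range(3))
            lines.append(f"actual {s} {row}")
        for s in THREE_STATES:
            lines.append(
                f"{s}: precision {self.precision[s]:.2f}  recall {self.recall[s]:.2f}"
            )
        return "\n".join(lines)


def evaluate(
    truths: list[StructureString | str], preds: list[StructureString | str]
) -> SovReport:
    """Q3, SOV94, SOV99, confusion and per-class precision/recall, pooled."""
    if len(truths) != len(preds):
        raise ValueError("need one prediction per reference structure")
    if not truths:
        raise ValueError("no chains to evaluate")
    confusion = np.zeros((3, 3), dtype=np.int64)
    for t, p in zip(truths, preds):
        confusion += confusion_matrix(t, p)
    n_total = int(confusion.sum())
    precision, recall = _pr_from_confusion(confusion)
    return SovReport(
        q3=100.0 * np.trace(confusion) / n_total,
        sov94=sov_multi(truths, preds, SovVariant.SOV94),
        sov99=sov_multi(truths, preds, SovVariant.SOV99),
        confusion=confusion,
        precision=precision,
        recall=recall,
        n_total=n_total,
    )
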