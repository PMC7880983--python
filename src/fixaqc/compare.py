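"""Agreement between event lists (F1) and test-retest reliability.

Two detectors (or the same detector on two recordings of the same scene)
agree on an event when their intervals overlap in time.  Matched pairs are
true positives; unmatched reference events are false negatives and
unmatched candidate events false positives; agreement is summarized by the
F1-score, the harmonic mean of precision and recall.  Test-retest
reliability is the Pearson correlation of a per-participant statistic
(rate or amplitude) across repeated recordings, within one setup (intra)
or between two setups (inter, averaged over both recording orders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError
from .events import MicrosaccadeEvent


@dataclass
class EventMatchResult:
    """Outcome of temporal event matching."""

    n_reference: int
    n_candidate: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def _check_sorted_disjoint(events: list[MicrosaccadeEvent], name: str) -> None:
    for prev, cur in zip(events, events[1:]):
        if cur.onset < prev.onset:
            raise IntegrityError(f"{name} events not sorted by onset")
        if cur.onset < prev.offset - 1e-12:
            raise IntegrityError(f"{name} events overlap at onset {cur.onset}")


def match_events(
    reference: list[MicrosaccadeEvent],
    candidate: list[MicrosaccadeEvent],
    min_overlap_s: float = 0.0,
) -> EventMatchResult:
    """Greedy one-to-one temporal matching of two sorted event lists.

    A pair matches when the intervals overlap (strictly more than
    ``min_overlap_s`` seconds; the default 0 accepts any shared sample).
    Lists must each be sorted and internally non-overlapping.  Because
    events within a list are disjoint and matching is in time order, the
    greedy pairing is an optimal (maximum-cardinality) matching.
    """
    _check_sorted_disjoint(reference, "reference")
    _check_sorted_disjoint(candidate, "candidate")
    tp = 0
    j = 0
    for ref in reference:
        while j < len(candidate) and candidate[j].offset <= ref.onset + min_overlap_s:
            j += 1
        if j < len(candidate):
            cand = candidate[j]
            overlap = min(ref.offset, cand.offset) - max(ref.onset, cand.onset)
            if overlap > min_overlap_s:
                tp += 1
                j += 1
    fn = len(reference) - tp
    fp = len(candidate) - tp
    precision = tp / len(candidate) if candidate else 0.0
    recall = tp / len(reference) if reference else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return EventMatchResult(len(reference), len(candidate), tp, fp, fn,
                            precision, recall, f1)


@dataclass
class TestRetestMatrix:
    """Symmetric setups-by-setups matrix of Pearson r for one statistic.

    The diagonal holds intra-setup retest correlations; each off-diagonal
    cell is the average of the two cross-recording comparisons (setup A
    repetition 1 vs setup B repetition 2, and vice versa).  Cells with
    fewer than three paired participants are NaN.
    """

    setups: list[str]
    matrix: pd.DataFrame


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 3:
        return np.nan
    return float(stats.pearsonr(a, b).statistic)


def test_retest(
    table: pd.DataFrame, statistic: str = "value", min_participants: int = 3
) -> TestRetestMatrix:
    """Test-retest reliability matrix from a tidy per-recording table.

    ``table`` needs columns ``participant``, ``setup``, ``repetition``
    (1 or 2) and the statistic column.  Correlations run over participants
    that have both required recordings for a cell.
    """
    need = {"participant", "setup", "repetition", statistic}
    missing = need - set(table.columns)
    if missing:
        raise KeyError(f"table lacks columns: {', '.join(sorted(missing))}")
    wide = table.pivot_table(index="participant", columns=["setup", "repetition"],
                             values=statistic, aggfunc="mean")
    setups = sorted({s for s, _ in wide.columns})
    mat = pd.DataFrame(np.nan, index=setups, columns=setups)
    for i, a in enumerate(setups):
        for b in setups[i:]:
            r = _cell(wide, a, b, min_participants)
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return TestRetestMatrix(setups, mat)


def _cell(wide: pd.DataFrame, a: str, b: str, min_n: int) -> float:
    def col(s, rep):
        return wide[(s, rep)] if (s, rep) in wide.columns else None

    def r(x, y):
        if x is None or y is None:
            return np.nan
        paired = pd.concat([x, y], axis=1).dropna()
        if len(paired) < min_n:
            return np.nan
        return _pearson(paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy())

    if a == b:
        return r(col(a, 1), col(a, 2))
    r12 = r(col(a, 1), col(b, 2))
    r21 = r(col(a, 2), col(b, 1))
    vals = [v for v in (r12, r21) if np.isfinite(v)]
    return float(np.mean(vals)) if vals else np.nan
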