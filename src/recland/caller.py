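"""Crossover detection from consecutive-marker genotype transitions.

A crossover is a change of call class between two consecutive markers
(parental homozygote <-> heterozygote scores 1; homozygote <-> opposite
homozygote implies a crossover in each gamete and scores 2).  To keep the
count from being inflated by isolated miscalls, a transition is valid only
if the new and old calls are each maintained over a confirmation window of
``window`` markers on their side (default 3).

Missing data are handled by condensing each individual's sequence to its
non-missing calls before applying the window rule (``skip_missing``, the
default); the alternative ``strict`` policy treats a missing call as
breaking the window.  At chromosome ends the window is truncated to the
markers that exist (at least one) under the default end rule; the
``strict_full`` end rule instead demands complete windows, discarding
transitions within ``window`` markers of either end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AA, BB, CODE_TO_TOKEN, MISSING, VALID_CODES, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class CallerConfig:
    window: int = 3
    missing_policy: str = "skip_missing"  # or "strict"
    end_rule: str = "truncate"  # or "strict_full"

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.missing_policy not in ("skip_missing", "strict"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.end_rule not in ("truncate", "strict_full"):
            raise ValueError(f"unknown end_rule {self.end_rule!r}")


@dataclass(frozen=True)
class CrossoverEvent:
    """One validated transition, reported at the flanking original markers."""

    left_index: int  # index into the original (non-condensed) call sequence
    right_index: int
    score: int  # 1, or 2 for homozygote -> opposite homozygote
    transition: tuple  # (old call code, new call code)


def _score(a: int, b: int) -> int:
    return 2 if {a, b} == {AA, BB} else 1


def call_crossovers_one(calls, config: CallerConfig = CallerConfig()) -> list[CrossoverEvent]:
    """Validated crossover events along one individual's chromosome."""
    c = np.asarray(calls, dtype=np.int8)
    if c.size == 0:
        return []
    if not set(np.unique(c)).issubset(VALID_CODES):
        bad = sorted(set(np.unique(c)) - VALID_CODES)
        raise ValueError(f"unknown call codes: {bad}")

    w = config.window
    if config.missing_policy == "skip_missing":
        keep = np.flatnonzero(c != MISSING)
        s = c[keep]
    else:
        keep = np.arange(c.size)
        s = c.copy()

    m = s.size
    if m < 2:
        return []

    if config.missing_policy == "strict":
        # a transition between adjacent non-missing markers; any MISSING in
        # either window invalidates it (window must be fully non-missing)
        events = []
        for i in range(m - 1):
            if s[i] == MISSING or s[i + 1] == MISSING or s[i] == s[i + 1]:
                continue
            lo, hi = i - w + 1, i + 1 + w
            if config.end_rule == "strict_full" and (lo < 0 or hi > m):
                continue
            left = s[max(0, lo) : i + 1]
            right = s[i + 1 : min(m, hi)]
            if np.all(left == s[i]) and np.all(right == s[i + 1]):
                events.append(
                    CrossoverEvent(int(keep[i]), int(keep[i + 1]), _score(s[i], s[i + 1]), (int(s[i]), int(s[i + 1])))
                )
        return events

    # skip_missing: vectorised over the condensed sequence via run lengths
    change = np.flatnonzero(s[:-1] != s[1:])  # transition at i -> i+1
    if change.size == 0:
        return []
    run_id = np.concatenate([[0], np.cumsum(s[:-1] != s[1:])])
    run_starts = np.concatenate([[0], change + 1])
    run_ends = np.concatenate([change, [m - 1]])
    events = []
    for i in change:
        if config.end_rule == "strict_full" and (i - w + 1 < 0 or i + w > m - 1):
            continue
        left_ok = run_starts[run_id[i]] <= max(0, i - w + 1)
        right_ok = run_ends[run_id[i + 1]] >= min(m - 1, i + w)
        if left_ok and right_ok:
            events.append(
                CrossoverEvent(
                    int(keep[i]), int(keep[i + 1]), _score(s[i], s[i + 1]), (int(s[i]), int(s[i + 1]))
                )
            )
    return events


def call_crossovers_reference(calls, config: CallerConfig = CallerConfig()) -> list[CrossoverEvent]:
    """Plain-loop reference transcription of the validity rule.

    Kept deliberately naive (no run-length shortcuts) as an independent
    check of :func:`call_crossovers_one`; used by the validation tests.
    """
    c = [int(x) for x in np.asarray(calls, dtype=np.int8)]
    if any(x not in VALID_CODES for x in c):
        raise ValueError("unknown call codes")
    w = config.window
    if config.missing_policy == "skip_missing":
        pairs = [(i, x) for i, x in enumerate(c) if x != MISSING]
    else:
        pairs = list(enumerate(c))
    idx = [i for i, _ in pairs]
    s = [x for _, x in pairs]
    events = []
    for i in range(len(s) - 1):
        a, b = s[i], s[i + 1]
        if a == MISSING or b == MISSING or a == b:
            continue
        if config.end_rule == "strict_full" and (i - w + 1 < 0 or i + 1 + w > len(s)):
            continue
        left = s[max(0, i - w + 1) : i + 1]
        right = s[i + 1 : i + 1 + w]
        if all(x == a for x in left) and all(x == b for x in right):
            events.append(CrossoverEvent(idx[i], idx[i + 1], _score(a, b), (a, b)))
    return events


def call_crossovers_population(
    gm: GenotypeMatrix, mm: MarkerMap, config: CallerConfig = CallerConfig()
) -> pd.DataFrame:
    """Crossover table for a whole population.

    Columns: individual, chrom, left_marker, left_bp, right_marker,
    right_bp, transition, score.  Sorted by (individual, chrom, left_bp).
    """
    if list(gm.marker_ids) != list(mm.marker_ids):
        raise ValueError("genotype matrix and marker map are not aligned")
    rows = []
    marker_ids = np.asarray(gm.marker_ids)
    for chrom in mm.chroms:
        ridx = mm.chrom_indices(chrom)
        pos = mm.positions(chrom)
        ids = marker_ids[ridx]
        block = gm.calls[ridx]
        for j, ind in enumerate(gm.individuals):
            for ev in call_crossovers_one(block[:, j], config):
                rows.append(
                    (
                        ind,
                        chrom,
                        ids[ev.left_index],
                        int(pos[ev.left_index]),
                        ids[ev.right_index],
                        int(pos[ev.right_index]),
                        f"{CODE_TO_TOKEN[ev.transition[0]]}>{CODE_TO_TOKEN[ev.transition[1]]}",
                        ev.score,
                    )
                )
    co = pd.DataFrame(
        rows,
        columns=[
            "individual",
            "chrom",
            "left_marker",
            "left_bp",
            "right_marker",
            "right_bp",
            "transition",
            "score",
        ],
    )
    return co.sort_values(["individual", "chrom", "left_bp"], kind="stable").reset_index(
        drop=True
    )
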