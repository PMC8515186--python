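"""Truth-aware evaluation of the crossover caller on simulated data.

The simulator records every gamete's true crossover positions, which lets
the caller be scored directly: a true crossover is recoverable when it is
well separated — far enough, in informative markers, from any other
crossover of the same individual and from the chromosome ends that the
confirmation windows cannot be disturbed.  These helpers locate truth in
marker-interval coordinates, select the well-separated subset, measure
sensitivity, and inject isolated singleton miscalls for robustness checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap


def truth_intervals(truths, mm: MarkerMap) -> pd.DataFrame:
    """Marker-interval index of every true crossover.

    Interval ``k`` lies between chromosome-local markers ``k`` and ``k+1``
    (0-based); crossovers before the first or after the last marker get
    k = -1 / k = n-1 and are invisible to any marker-based caller.
    """
    pos_by_chrom = {c: mm.positions(c).astype(float) for c in mm.chroms}
    rows = []
    for t in truths:
        p = pos_by_chrom[t.chrom]
        for x in t.positions:
            k = int(np.searchsorted(p, x)) - 1
            rows.append((t.individual, t.gamete, t.chrom, float(x), k, len(p)))
    return pd.DataFrame(
        rows, columns=["individual", "gamete", "chrom", "pos", "interval", "n_markers"]
    )


def well_separated(
    ti: pd.DataFrame, min_co_gap: int = 4, min_end_gap: int = 3
) -> pd.DataFrame:
    """Subset of true crossovers isolated enough to be unambiguously callable.

    Keeps crossovers whose nearest other crossover of the same individual
    and chromosome (either gamete) is at least ``min_co_gap`` marker
    intervals away and which lie at least ``min_end_gap`` markers from both
    chromosome ends.
    """
    keep = []
    for (_, _), sub in ti.groupby(["individual", "chrom"], sort=False):
        ks = sub["interval"].to_numpy()
        n = int(sub["n_markers"].iloc[0])
        for idx, k in zip(sub.index, ks):
            others = ks[ks != k] if (ks == k).sum() == 1 else np.concatenate([ks[ks != k], [k]])
            gap_ok = others.size == 0 or np.min(np.abs(others - k)) >= min_co_gap
            end_ok = (k >= min_end_gap) and (k <= n - 2 - min_end_gap)
            if gap_ok and end_ok:
                keep.append(idx)
    return ti.loc[keep]


def sensitivity(
    co: pd.DataFrame, ws: pd.DataFrame, mm: MarkerMap
) -> tuple[float, int, int]:
    """Fraction of well-separated true crossovers called exactly once.

    A match is an event of the same individual and chromosome whose
    flanking-marker interval equals the truth interval.  Returns
    (sensitivity, n_recovered, n_truth).
    """
    if len(ws) == 0:
        return np.nan, 0, 0
    pos_by_chrom = {c: mm.positions(c).astype(float) for c in mm.chroms}
    called: dict = {}
    for row in co.itertuples(index=False):
        p = pos_by_chrom[row.chrom]
        k = int(np.searchsorted(p, (row.left_bp + row.right_bp) / 2.0)) - 1
        called.setdefault((row.individual, row.chrom), []).append(k)
    hits = 0
    for row in ws.itertuples(index=False):
        ks = called.get((row.individual, row.chrom), [])
        if sum(1 for k in ks if k == row.interval) == 1:
            hits += 1
    return hits / len(ws), hits, len(ws)


def precision(co: pd.DataFrame, ti: pd.DataFrame, mm: MarkerMap, slack: int = 3) -> float:
    """Fraction of called events with a true crossover within ``slack``
    marker intervals of the called interval (same individual/chromosome)."""
    if len(co) == 0:
        return np.nan
    pos_by_chrom = {c: mm.positions(c).astype(float) for c in mm.chroms}
    truth_by_key: dict = {}
    for row in ti.itertuples(index=False):
        truth_by_key.setdefault((row.individual, row.chrom), []).append(row.interval)
    good = 0
    for row in co.itertuples(index=False):
        p = pos_by_chrom[row.chrom]
        k = int(np.searchsorted(p, (row.left_bp + row.right_bp) / 2.0)) - 1
        ks = truth_by_key.get((row.individual, row.chrom), [])
        if ks and min(abs(k - t) for t in ks) <= slack:
            good += 1
    return good / len(co)


def inject_singletons(
    gm: GenotypeMatrix,
    mm: MarkerMap,
    ti: pd.DataFrame,
    rng: np.random.Generator,
    per_individual: int = 3,
    min_gap: int = 4,
) -> tuple[GenotypeMatrix, int]:
    """Copy of ``gm`` with isolated single-marker miscalls injected.

    Eligible sites sit at least ``min_gap`` markers from every true
    crossover interval of that individual, from each other, and from the
    chromosome ends (a terminal singleton is indistinguishable from a
    terminal crossover under truncated confirmation windows).  Each
    injected call is replaced by one of the other two non-missing codes.
    Returns the perturbed matrix and the number of injections made.
    """
    calls = gm.calls.copy()
    ind_idx = {ind: j for j, ind in enumerate(gm.individuals)}
    co_by_key: dict = {}
    for row in ti.itertuples(index=False):
        co_by_key.setdefault((row.individual, row.chrom), []).append(row.interval)
    n_injected = 0
    for chrom in mm.chroms:
        ridx = mm.chrom_indices(chrom)
        m = len(ridx)
        for ind, j in ind_idx.items():
            kos = np.asarray(co_by_key.get((ind, chrom), []), dtype=int)
            eligible = []
            for marker in range(min_gap, m - min_gap):
                if kos.size and np.min(np.abs(kos - marker)) < min_gap:
                    continue
                eligible.append(marker)
            rng.shuffle(eligible)
            chosen: list[int] = []
            for marker in eligible:
                if len(chosen) >= per_individual:
                    break
                if chosen and min(abs(marker - c) for c in chosen) <= min_gap:
                    continue
                chosen.append(marker)
            for marker in chosen:
                row = ridx[marker]
                old = calls[row, j]
                if old == MISSING:
                    continue
                new = (old + 1 + rng.integers(0, 2)) % 3
                calls[row, j] = new
                n_injected += 1
    return GenotypeMatrix(calls, gm.marker_ids, gm.individuals), n_injected
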