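"""Recombination fractions, Kosambi distances and genetic-map totals.

For every pair of consecutive markers the recombination fraction is the
summed crossover score in that interval divided by the number of
individuals with data at both flanking markers; the Kosambi map function
converts it to centimorgans:

    d(cM) = 25 * ln((1 + 2r) / (1 - 2r))

Crossover scores are per F2 individual and therefore pool the two meioses
each individual carries; the resulting map length is used as computed,
without halving or a maximum-likelihood F2 estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, MarkerMap

R_CLIP = 0.49999


def kosambi_cm(r):
    """Kosambi genetic distance in cM; accepts scalars or arrays.

    ``r`` must be >= 0; values >= 0.5 are clipped to 0.49999 with a warning
    (a recombination fraction at or beyond one half carries no distance
    information under any map function).  NaN propagates.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("recombination fraction must be >= 0")
    over = arr >= 0.5
    if np.any(over):
        warnings.warn(
            f"{int(over.sum())} recombination fraction(s) >= 0.5 clipped to {R_CLIP}",
            UserWarning,
        )
        arr = np.where(over, R_CLIP, arr)
    with np.errstate(invalid="ignore"):
        cm = 25.0 * np.log((1.0 + 2.0 * arr) / (1.0 - 2.0 * arr))
    return float(cm) if np.isscalar(r) else cm


def kosambi_r(cm):
    """Inverse Kosambi: recombination fraction for a distance in cM."""
    return 0.5 * np.tanh(np.asarray(cm, dtype=float) / 50.0)


def truncate_1dp(x: float) -> float:
    """Truncate (not round) to one decimal, as map-length/CO summaries print."""
    return math.floor(x * 10 + 1e-9) / 10


@dataclass
class GeneticMap:
    """Per-interval statistics plus chromosome and genome totals."""

    intervals: pd.DataFrame  # one row per consecutive marker pair
    chrom_totals: pd.Series  # cM per chromosome
    genome_total_cm: float


def interval_stats(
    co: pd.DataFrame, gm: GenotypeMatrix, mm: MarkerMap
) -> pd.DataFrame:
    """One record per consecutive marker pair per chromosome.

    Events whose flanking markers are non-adjacent (missing calls between)
    contribute their score to the consecutive-pair interval containing the
    physical midpoint of the flanking pair.  ``n_informative`` counts
    individuals non-missing at both flanking markers; an interval with no
    informative individuals gets r = NaN and is excluded from totals.
    """
    if list(gm.marker_ids) != list(mm.marker_ids):
        raise ValueError("genotype matrix and marker map are not aligned")
    frames = []
    for chrom in mm.chroms:
        ridx = mm.chrom_indices(chrom)
        pos = mm.positions(chrom).astype(np.int64)
        ids = np.asarray(gm.marker_ids)[ridx]
        n_int = len(pos) - 1
        if n_int < 1:
            continue
        events = np.zeros(n_int, dtype=float)
        sub = co[co["chrom"] == chrom]
        if len(sub):
            mid = (sub["left_bp"].to_numpy() + sub["right_bp"].to_numpy()) / 2.0
            k = np.searchsorted(pos, mid, side="right") - 1
            k = np.clip(k, 0, n_int - 1)
            np.add.at(events, k, sub["score"].to_numpy())
        non_missing = gm.calls[ridx] != MISSING
        informative = (non_missing[:-1] & non_missing[1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(informative > 0, events / informative, np.nan)
        if np.any(informative == 0):
            warnings.warn(
                f"{int((informative == 0).sum())} interval(s) on {chrom} have no "
                "informative individuals; r undefined, excluded from totals",
                UserWarning,
            )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "left_marker": ids[:-1],
                    "right_marker": ids[1:],
                    "left_bp": pos[:-1],
                    "right_bp": pos[1:],
                    "n_events": events,
                    "n_informative": informative,
                    "r": r,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # r >= 0.5 clip warning once
        out["cm"] = kosambi_cm(out["r"].to_numpy())
    return out


def build_genetic_map(intervals: pd.DataFrame) -> GeneticMap:
    """Attach cumulative positions and compute chromosome/genome totals."""
    intervals = intervals.copy()
    cum = []
    for _, sub in intervals.groupby("chrom", sort=False):
        cm = np.nan_to_num(sub["cm"].to_numpy())
        cum.append(np.cumsum(cm))
    intervals["cum_cm"] = np.concatenate(cum)
    chrom_totals = intervals.groupby("chrom", sort=False)["cm"].sum(min_count=1)
    chrom_totals = chrom_totals.fillna(0.0)
    return GeneticMap(
        intervals=intervals,
        chrom_totals=chrom_totals,
        genome_total_cm=float(np.nansum(intervals["cm"].to_numpy())),
    )


def map_totals(gmap: GeneticMap, cm_per_co: float = 50.0) -> dict:
    """Chromosome/genome totals and the expected CO count at 50 cM per CO.

    The expected count is reported at full precision and truncated to one
    decimal (the conventional one-decimal presentation).
    """
    total = gmap.genome_total_cm
    return {
        "chrom_cm": {k: float(v) for k, v in gmap.chrom_totals.items()},
        "genome_cm": total,
        "expected_co": total / cm_per_co,
        "expected_co_1dp": truncate_1dp(total / cm_per_co),
    }


def coverage_gaps(mm: MarkerMap, chrom_lengths: dict) -> pd.DataFrame:
    """Per-chromosome physical fraction uncovered before the first and after
    the last marker (percent of chromosome length)."""
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = mm.positions(chrom)
        if pos.size == 0:
            warnings.warn(f"no markers on {chrom}: 100% uncovered", UserWarning)
            rows.append((chrom, np.nan, np.nan, 100.0, 100.0))
            continue
        if pos.max() > length or pos.min() < 1:
            raise ValueError(f"marker beyond declared length of {chrom}")
        rows.append(
            (
                chrom,
                int(pos.min()),
                int(pos.max()),
                100.0 * (pos.min() - 1) / length,
                100.0 * (length - pos.max()) / length,
            )
        )
    return pd.DataFrame(
        rows, columns=["chrom", "first_bp", "last_bp", "pct_uncovered_start", "pct_uncovered_end"]
    )
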