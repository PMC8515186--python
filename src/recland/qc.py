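"""Marker and individual quality filters for biparental F2 genotype data.

Markers are removed when monomorphic, too often missing, heterozygote-
excessive, or segregation-distorted against the 1:2:1 F2 expectation;
individuals when too often missing or heterozygote-excessive (the F2
expectation is 50% HET, so the ceiling defaults well above it).  Filtering
order is fixed: markers first, then individuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AA, BB, HET, MISSING, GenotypeMatrix, MarkerMap


@dataclass(frozen=True)
class QcCriteria:
    max_marker_missing_fraction: float = 0.10
    max_marker_het_fraction: float = 0.85
    segregation_distortion_alpha: float = 1e-6
    max_individual_missing_fraction: float = 0.20
    max_individual_het_fraction: float = 0.80

    def __post_init__(self):
        for name in (
            "max_marker_missing_fraction",
            "max_marker_het_fraction",
            "max_individual_missing_fraction",
            "max_individual_het_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.segregation_distortion_alpha <= 1:
            raise ValueError("segregation_distortion_alpha must be in (0, 1]")


def segregation_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    """Per-marker 1:2:1 goodness-of-fit chi-square p-value (NaN if no data)."""
    n_aa = (gm.calls == AA).sum(axis=1)
    n_het = (gm.calls == HET).sum(axis=1)
    n_bb = (gm.calls == BB).sum(axis=1)
    n = (n_aa + n_het + n_bb).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = (
            (n_aa - n / 4) ** 2 / (n / 4)
            + (n_het - n / 2) ** 2 / (n / 2)
            + (n_bb - n / 4) ** 2 / (n / 4)
        )
    p = stats.chi2.sf(chi2, df=2)
    p[n == 0] = np.nan
    return p


def filter_markers(
    gm: GenotypeMatrix, criteria: QcCriteria = QcCriteria()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove failing markers; report columns (id, reason, statistic, threshold).

    The first failing check in the order monomorphic -> missing -> het ->
    distortion is the reported reason.
    """
    if gm.n_markers == 0:
        raise ValueError("empty genotype matrix")
    missing = gm.marker_missing_fraction()
    het = gm.marker_het_fraction()
    n_distinct = np.zeros(gm.n_markers, dtype=int)
    for code in (AA, HET, BB):
        n_distinct += (gm.calls == code).any(axis=1)
    seg_p = segregation_pvalues(gm)

    rows = []
    drop = np.zeros(gm.n_markers, dtype=bool)
    for i in range(gm.n_markers):
        if n_distinct[i] <= 1:
            rows.append((gm.marker_ids[i], "monomorphic", float(n_distinct[i]), 1.0))
        elif missing[i] > criteria.max_marker_missing_fraction:
            rows.append(
                (gm.marker_ids[i], "missing", float(missing[i]), criteria.max_marker_missing_fraction)
            )
        elif het[i] > criteria.max_marker_het_fraction:
            rows.append(
                (gm.marker_ids[i], "het", float(het[i]), criteria.max_marker_het_fraction)
            )
        elif np.isfinite(seg_p[i]) and seg_p[i] < criteria.segregation_distortion_alpha:
            rows.append(
                (gm.marker_ids[i], "distortion", float(seg_p[i]), criteria.segregation_distortion_alpha)
            )
        else:
            continue
        drop[i] = True

    report = pd.DataFrame(rows, columns=["id", "reason", "statistic", "threshold"])
    return gm.subset_markers(~drop), report


def filter_individuals(
    gm: GenotypeMatrix, criteria: QcCriteria = QcCriteria()
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Remove individuals with excessive missing or heterozygous calls."""
    if gm.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    missing = gm.individual_missing_fraction()
    het = gm.individual_het_fraction()

    rows = []
    drop = np.zeros(gm.n_individuals, dtype=bool)
    for j in range(gm.n_individuals):
        if missing[j] > criteria.max_individual_missing_fraction:
            rows.append(
                (
                    gm.individuals[j],
                    "missing",
                    float(missing[j]),
                    criteria.max_individual_missing_fraction,
                )
            )
        elif np.isfinite(het[j]) and het[j] > criteria.max_individual_het_fraction:
            rows.append(
                (gm.individuals[j], "het", float(het[j]), criteria.max_individual_het_fraction)
            )
        else:
            continue
        drop[j] = True

    report = pd.DataFrame(rows, columns=["id", "reason", "statistic", "threshold"])
    return gm.subset_individuals(~drop), report


def apply_qc(
    gm: GenotypeMatrix, mm: MarkerMap, criteria: QcCriteria = QcCriteria()
) -> tuple[GenotypeMatrix, MarkerMap, pd.DataFrame, pd.DataFrame]:
    """Markers-then-individuals filtering; returns survivors plus both reports."""
    gm2, marker_report = filter_markers(gm, criteria)
    gm3, individual_report = filter_individuals(gm2, criteria)
    mm2 = mm.subset(gm3.marker_ids)
    return gm3, mm2, marker_report, individual_report
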