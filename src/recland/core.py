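"""Core containers: marker maps and F2 genotype matrices.

Genotype calls are stored as ``int8`` codes: ``AA=0`` (parent-A homozygote),
``HET=1``, ``BB=2`` (parent-B homozygote), ``MISSING=-1``.  The numeric coding
is deliberate: an F2 genotype is the sum of its two gamete haplotypes (0 or 1
copies of the B allele), which the simulator exploits.

Coordinates are 1-based inclusive base pairs throughout, matching how
physical positions are reported on genome assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1
AA: int = 0
HET: int = 1
BB: int = 2

CODE_TO_TOKEN = {AA: "A", HET: "H", BB: "B", MISSING: "NA"}
TOKEN_TO_CODE = {"A": AA, "H": HET, "B": BB, "NA": MISSING}
VALID_CODES = frozenset((MISSING, AA, HET, BB))


@dataclass
class MarkerMap:
    """Ordered loci with chromosome and physical position.

    ``table`` has columns ``marker`` (unique string id), ``chrom`` (string)
    and ``pos`` (1-based bp, int).  Within a chromosome positions are
    non-decreasing in storage order; physical order is the analysis order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chrom", "pos"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicated marker ids: {sorted(set(dups))[:5]}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {chrom}")

    # -- basic views ------------------------------------------------------
    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Row indices (map order) of the markers on ``chrom``."""
        return np.flatnonzero((self.table["chrom"] == chrom).to_numpy())

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def sorted(self) -> "MarkerMap":
        """Copy sorted by (chromosome, position), stable."""
        tab = self.table.sort_values(["chrom", "pos"], kind="stable")
        return MarkerMap(tab.reset_index(drop=True))

    def subset(self, marker_ids) -> "MarkerMap":
        keep = self.table["marker"].isin(set(marker_ids))
        return MarkerMap(self.table.loc[keep].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Call codes for individuals x ordered markers.

    ``calls`` is an int8 array of shape (n_markers, n_individuals), rows
    aligned to a :class:`MarkerMap`.
    """

    calls: np.ndarray
    marker_ids: list[str] = field(default_factory=list)
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.marker_ids = list(self.marker_ids)
        self.individuals = list(self.individuals)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (markers x individuals)")
        if self.calls.shape != (len(self.marker_ids), len(self.individuals)):
            raise ValueError(
                f"shape {self.calls.shape} inconsistent with "
                f"{len(self.marker_ids)} markers x {len(self.individuals)} individuals"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicated individual ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicated marker ids")
        bad = ~np.isin(self.calls, list(VALID_CODES))
        if bad.any():
            raise ValueError(f"invalid call codes: {np.unique(self.calls[bad])}")

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def align_to(self, mm: MarkerMap) -> "GenotypeMatrix":
        """Reorder rows to the order of ``mm`` (which must cover the same markers)."""
        if set(mm.marker_ids) != set(self.marker_ids):
            raise ValueError("marker sets differ between matrix and map")
        order = {m: i for i, m in enumerate(self.marker_ids)}
        idx = np.array([order[m] for m in mm.marker_ids])
        return GenotypeMatrix(self.calls[idx], list(mm.marker_ids), self.individuals)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.calls[keep],
            [self.marker_ids[i] for i in np.flatnonzero(keep) if keep.dtype == bool]
            if keep.dtype == bool
            else [self.marker_ids[i] for i in keep],
            self.individuals,
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        cols = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeMatrix(
            self.calls[:, cols], self.marker_ids, [self.individuals[i] for i in cols]
        )

    # -- per-axis summaries used by QC -------------------------------------
    def marker_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def marker_het_fraction(self) -> np.ndarray:
        """HET fraction among non-missing calls per marker (NaN if all missing)."""
        non_missing = (self.calls != MISSING).sum(axis=1).astype(float)
        het = (self.calls == HET).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(non_missing > 0, het / non_missing, np.nan)

    def individual_missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def individual_het_fraction(self) -> np.ndarray:
        non_missing = (self.calls != MISSING).sum(axis=0).astype(float)
        het = (self.calls == HET).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(non_missing > 0, het / non_missing, np.nan)
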