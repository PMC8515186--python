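"""Genomic zones, relative physical bins, and two-population comparisons.

Barley-style chromosomes partition into three zones — Z1 (distal,
gene-rich), Z2 (interstitial) and Z3 (proximal, recombination-poor) — whose
boundary coordinates are configuration data supplied as a layout table, not
code.  Recombination is additionally profiled in relative physical bins
(2% of each chromosome by default, i.e. 50 genome-wide bins after merging
chromosomes).

Population contrasts use a Pearson chi-square on crossover-score
proportions per zone (2x2, population x in/out-of-zone) and Wilcoxon
signed-rank tests on paired per-chromosome centimorgan values (genome,
zone, and bin level; the terminal-bin test pairs the first and last bin of
each chromosome, i.e. one value per chromosome arm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MarkerMap
from .genmap import GeneticMap

ZONES = ("Z1", "Z2", "Z3")


@dataclass
class GenomeLayout:
    """Zone segments per chromosome: (chrom, zone, start_bp, end_bp, arm).

    Segments are 1-based inclusive and must tile [1, length] without gap or
    overlap; a typical chromosome has five segments (Z1-Z2-Z3-Z2-Z1 with
    arm tags S, S, C, L, L).
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"chrom", "zone", "start_bp", "end_bp", "arm"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"layout needs columns {sorted(required)}")
        self.table = self.table.reset_index(drop=True)
        bad = ~self.table["zone"].isin(ZONES)
        if bad.any():
            raise ValueError(f"unknown zone labels: {sorted(set(self.table.loc[bad, 'zone']))}")
        for chrom, sub in self.table.groupby("chrom", sort=False):
            sub = sub.sort_values("start_bp")
            starts = sub["start_bp"].to_numpy()
            ends = sub["end_bp"].to_numpy()
            if starts[0] != 1 or np.any(starts[1:] != ends[:-1] + 1) or np.any(ends < starts):
                raise ValueError(f"segments do not tile chromosome {chrom}")

    @property
    def chrom_lengths(self) -> dict:
        return {c: int(sub["end_bp"].max()) for c, sub in self.table.groupby("chrom", sort=False)}

    @classmethod
    def default(cls, chrom_lengths: dict, zone_bounds=(0.04, 0.38, 0.62, 0.96)) -> "GenomeLayout":
        """Symmetric five-segment layout from relative zone boundaries."""
        rows = []
        for chrom, length in chrom_lengths.items():
            b = [int(round(f * length)) for f in zone_bounds]
            segs = [
                ("Z1", 1, b[0], "S"),
                ("Z2", b[0] + 1, b[1], "S"),
                ("Z3", b[1] + 1, b[2], "C"),
                ("Z2", b[2] + 1, b[3], "L"),
                ("Z1", b[3] + 1, length, "L"),
            ]
            rows += [(chrom, z, s, e, a) for z, s, e, a in segs]
        return cls(pd.DataFrame(rows, columns=["chrom", "zone", "start_bp", "end_bp", "arm"]))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GenomeLayout":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "zone": str, "arm": str}))

    def zone_of(self, chrom: str, positions) -> np.ndarray:
        """Zone label for 1-based position(s) on ``chrom`` (inclusive segments)."""
        sub = self.table[self.table["chrom"] == chrom].sort_values("start_bp")
        if sub.empty:
            raise ValueError(f"no layout for chromosome {chrom}")
        pos = np.atleast_1d(np.asarray(positions))
        ends = sub["end_bp"].to_numpy()
        if np.any(pos < 1) or np.any(pos > ends[-1]):
            raise ValueError(f"position outside chromosome {chrom} bounds")
        idx = np.searchsorted(ends, pos, side="left")
        return sub["zone"].to_numpy()[idx]

    def zone_mbp(self) -> pd.Series:
        """Physical Mbp per zone, genome-wide."""
        seg = (self.table["end_bp"] - self.table["start_bp"] + 1) / 1e6
        return seg.groupby(self.table["zone"]).sum().reindex(ZONES, fill_value=0.0)


def assign_zone(layout: GenomeLayout, chrom: str, left_bp: int, right_bp: int | None = None) -> str:
    """Zone of a marker, or of an interval by the physical midpoint of its
    flanking markers."""
    pos = left_bp if right_bp is None else (left_bp + right_bp) // 2
    return str(layout.zone_of(chrom, pos)[0])


def zone_summary(
    gmap: GeneticMap, mm: MarkerMap, layout: GenomeLayout, per_chrom: bool = False
) -> pd.DataFrame:
    """Per-zone cM, summed CO scores, marker counts and SNP/Mbp density.

    Intervals are assigned to zones by the midpoint of their flanking
    markers; markers by their own position.
    """
    iv = gmap.intervals
    zones_iv = np.concatenate(
        [
            layout.zone_of(chrom, ((sub["left_bp"] + sub["right_bp"]) // 2).to_numpy())
            for chrom, sub in iv.groupby("chrom", sort=False)
        ]
    )
    iv = iv.assign(zone=zones_iv)
    marker_zone = np.concatenate(
        [layout.zone_of(chrom, mm.positions(chrom)) for chrom in mm.chroms]
    )
    marker_df = pd.DataFrame({"chrom": mm.table["chrom"], "zone": marker_zone})

    keys = ["chrom", "zone"] if per_chrom else ["zone"]
    agg = iv.groupby(keys)[["cm", "n_events"]].sum(min_count=1).fillna(0.0)
    counts = marker_df.groupby(keys).size().rename("n_markers")
    out = agg.join(counts, how="outer").fillna(0.0).reset_index()
    out = out.rename(columns={"n_events": "co_score"})
    if not per_chrom:
        out = out.set_index("zone").reindex(ZONES, fill_value=0.0).reset_index()
        out["mbp"] = layout.zone_mbp().to_numpy()
        out["snp_per_mbp"] = out["n_markers"] / out["mbp"]
    return out


def zone_shares(summary: pd.DataFrame, column: str = "cm") -> pd.Series:
    """Each zone's percentage share of the genome-wide total of ``column``."""
    total = summary[column].sum()
    shares = 100.0 * summary.set_index("zone")[column] / total
    return shares.reindex(ZONES)


def chi2_zone_proportions(
    scores_a: pd.Series, scores_b: pd.Series, correction: bool = False
) -> pd.DataFrame:
    """Per-zone Pearson chi-square comparing CO-score proportions.

    For each zone a 2x2 table (population x [in-zone, out-of-zone] scores)
    is tested with 1 dof, no continuity correction by default.  A zero
    marginal leaves the p-value undefined (NaN).
    """
    zones = [z for z in ZONES if z in scores_a.index or z in scores_b.index]
    tot_a = float(scores_a.sum())
    tot_b = float(scores_b.sum())
    rows = []
    for z in zones:
        a_in = float(scores_a.get(z, 0.0))
        b_in = float(scores_b.get(z, 0.0))
        table = np.array([[a_in, tot_a - a_in], [b_in, tot_b - b_in]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            rows.append((z, np.nan, 1, np.nan))
            continue
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=correction)
        rows.append((z, float(chi2), int(dof), float(p)))
    return pd.DataFrame(rows, columns=["zone", "chi2", "dof", "p"])


def chi2_two_zones(a1: float, a2: float, b1: float, b2: float, correction: bool = False):
    """Chi-square on the 2x2 table of Z1/Z2 crossover scores for two
    populations (the distal-vs-interstitial shift test)."""
    table = np.array([[a1, a2], [b1, b2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return np.nan, np.nan
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def wilcoxon_compare(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped (standard signed-rank convention); the
    exact distribution is used up to 25 non-zero pairs when the absolute
    differences are tie-free, the tie-corrected normal approximation
    otherwise.  Fewer than two non-zero pairs leaves the p undefined.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 2:
        return np.nan, np.nan
    exact = n <= 25 and len(np.unique(np.abs(d))) == n
    res = stats.wilcoxon(d, zero_method="wilcox", method="exact" if exact else "approx", correction=False)
    return float(res.statistic), float(res.pvalue)


def bin_profile(
    gmap: GeneticMap,
    chrom_lengths: dict,
    n_bins: int = 50,
    method: str = "prorata",
) -> pd.DataFrame:
    """Genome-wide relative-bin profile of recombination.

    Bin ``k`` covers the relative physical span ((k-1)/n, k/n] of every
    chromosome (bin 1 starts at the short-arm telomere).  Each interval's
    cM is apportioned to bins pro-rata by physical overlap (``method
    'midpoint'`` instead assigns it wholly to the bin of its midpoint).
    Returns a DataFrame indexed by bin with one column per chromosome plus
    ``cm`` (the genome-wide sum).
    """
    if method not in ("prorata", "midpoint"):
        raise ValueError(f"unknown method {method!r}")
    cols = {}
    for chrom, sub in gmap.intervals.groupby("chrom", sort=False):
        L = float(chrom_lengths[chrom])
        edges = L * np.arange(n_bins + 1) / n_bins
        left = sub["left_bp"].to_numpy(dtype=float)
        right = sub["right_bp"].to_numpy(dtype=float)
        cm = np.nan_to_num(sub["cm"].to_numpy(dtype=float))
        out = np.zeros(n_bins)
        mid_bin = np.clip(np.ceil((left + right) / 2 * n_bins / L).astype(int) - 1, 0, n_bins - 1)
        if method == "midpoint":
            np.add.at(out, mid_bin, cm)
        else:
            b_lo = np.clip(np.ceil(left * n_bins / L).astype(int) - 1, 0, n_bins - 1)
            b_hi = np.clip(np.ceil(right * n_bins / L).astype(int) - 1, 0, n_bins - 1)
            same = b_lo == b_hi
            np.add.at(out, b_lo[same], cm[same])
            zero_len = (~same) & (right <= left)
            np.add.at(out, mid_bin[zero_len], cm[zero_len])
            for i in np.flatnonzero((~same) & (right > left)):
                lo, hi = b_lo[i], b_hi[i]
                span = right[i] - left[i]
                for k in range(lo, hi + 1):
                    ov = min(right[i], edges[k + 1]) - max(left[i], edges[k])
                    if ov > 0:
                        out[k] += cm[i] * ov / span
        cols[chrom] = out
    prof = pd.DataFrame(cols, index=pd.RangeIndex(1, n_bins + 1, name="bin"))
    prof["cm"] = prof.sum(axis=1)
    return prof


def markers_per_bin(mm: MarkerMap, chrom_lengths: dict, n_bins: int = 50) -> pd.Series:
    counts = np.zeros(n_bins)
    for chrom in mm.chroms:
        L = float(chrom_lengths[chrom])
        pos = mm.positions(chrom).astype(float)
        k = np.clip(np.ceil(pos * n_bins / L).astype(int) - 1, 0, n_bins - 1)
        np.add.at(counts, k, 1)
    return pd.Series(counts, index=pd.RangeIndex(1, n_bins + 1, name="bin"), name="n_markers")


def terminal_bin_test(prof_a: pd.DataFrame, prof_b: pd.DataFrame) -> tuple[float, float]:
    """Signed-rank test on the terminal bins, paired per chromosome arm.

    Pairs are the first and last bin of every chromosome (two arms per
    chromosome), comparing population A against population B.
    """
    chroms = [c for c in prof_a.columns if c != "cm"]
    first, last = prof_a.index[0], prof_a.index[-1]
    a = np.concatenate([prof_a.loc[[first, last], chroms].to_numpy().ravel()])
    b = np.concatenate([prof_b.loc[[first, last], chroms].to_numpy().ravel()])
    return wilcoxon_compare(a, b)


@dataclass
class ComparisonReport:
    """Everything the two-population contrast produces."""

    zone_a: pd.DataFrame
    zone_b: pd.DataFrame
    zone_chi2: pd.DataFrame
    z1_vs_z2_chi2: tuple
    wilcoxon_genome: tuple
    wilcoxon_zone: dict
    bins_a: pd.DataFrame
    bins_b: pd.DataFrame
    wilcoxon_bins: pd.DataFrame
    terminal_bins: tuple
    shares: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "zone_a": self.zone_a.to_dict(orient="list"),
            "zone_b": self.zone_b.to_dict(orient="list"),
            "zone_chi2": self.zone_chi2.to_dict(orient="list"),
            "z1_vs_z2_chi2": {"chi2": self.z1_vs_z2_chi2[0], "p": self.z1_vs_z2_chi2[1]},
            "wilcoxon_genome": {"stat": self.wilcoxon_genome[0], "p": self.wilcoxon_genome[1]},
            "wilcoxon_zone": {z: {"stat": s, "p": p} for z, (s, p) in self.wilcoxon_zone.items()},
            "terminal_bins": {"stat": self.terminal_bins[0], "p": self.terminal_bins[1]},
            "shares": self.shares,
        }


def compare_populations(
    gmap_a: GeneticMap,
    gmap_b: GeneticMap,
    mm: MarkerMap,
    layout: GenomeLayout,
    n_bins: int = 50,
    per_bin_tests: bool = True,
    correction: bool = False,
) -> ComparisonReport:
    """Full two-population landscape comparison.

    Wilcoxon pairing unit is the chromosome: genome-level pairs are
    per-chromosome map totals, zone-level pairs per-chromosome zone cM,
    bin-level pairs per-chromosome bin cM.
    """
    lengths = layout.chrom_lengths
    za = zone_summary(gmap_a, mm, layout)
    zb = zone_summary(gmap_b, mm, layout)
    chi2 = chi2_zone_proportions(
        za.set_index("zone")["co_score"], zb.set_index("zone")["co_score"], correction
    )
    sa = za.set_index("zone")
    sb = zb.set_index("zone")
    z12 = chi2_two_zones(
        sa.loc["Z1", "co_score"], sa.loc["Z2", "co_score"],
        sb.loc["Z1", "co_score"], sb.loc["Z2", "co_score"],
        correction,
    )

    chroms = list(gmap_a.chrom_totals.index)
    wg = wilcoxon_compare(
        gmap_a.chrom_totals.to_numpy(), gmap_b.chrom_totals.reindex(chroms).to_numpy()
    )
    pza = zone_summary(gmap_a, mm, layout, per_chrom=True).pivot_table(
        index="chrom", columns="zone", values="cm", fill_value=0.0
    )
    pzb = zone_summary(gmap_b, mm, layout, per_chrom=True).pivot_table(
        index="chrom", columns="zone", values="cm", fill_value=0.0
    )
    wz = {}
    for z in ZONES:
        if z in pza.columns or z in pzb.columns:
            a = pza[z].reindex(chroms, fill_value=0.0) if z in pza else pd.Series(0.0, index=chroms)
            b = pzb[z].reindex(chroms, fill_value=0.0) if z in pzb else pd.Series(0.0, index=chroms)
            wz[z] = wilcoxon_compare(a.to_numpy(), b.to_numpy())

    bins_a = bin_profile(gmap_a, lengths, n_bins)
    bins_b = bin_profile(gmap_b, lengths, n_bins)
    if per_bin_tests:
        rows = []
        chrom_cols = [c for c in bins_a.columns if c != "cm"]
        for k in bins_a.index:
            s, p = wilcoxon_compare(
                bins_a.loc[k, chrom_cols].to_numpy(), bins_b.loc[k, chrom_cols].to_numpy()
            )
            rows.append((k, s, p))
        wbins = pd.DataFrame(rows, columns=["bin", "stat", "p"])
    else:
        wbins = pd.DataFrame(columns=["bin", "stat", "p"])
    term = terminal_bin_test(bins_a, bins_b)

    shares = {
        "a_cm_pct": zone_shares(za, "cm").round(4).to_dict(),
        "b_cm_pct": zone_shares(zb, "cm").round(4).to_dict(),
        "a_co_pct": zone_shares(za, "co_score").round(4).to_dict(),
        "b_co_pct": zone_shares(zb, "co_score").round(4).to_dict(),
    }
    return ComparisonReport(
        zone_a=za,
        zone_b=zb,
        zone_chi2=chi2,
        z1_vs_z2_chi2=z12,
        wilcoxon_genome=wg,
        wilcoxon_zone=wz,
        bins_a=bins_a,
        bins_b=bins_b,
        wilcoxon_bins=wbins,
        terminal_bins=term,
        shares=shares,
    )
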