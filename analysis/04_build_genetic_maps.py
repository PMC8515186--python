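"""Build Kosambi genetic maps for both populations.

Computes per-interval recombination fractions and Kosambi distances,
chromosome and genome map totals, the expected crossover count at
50 cM/CO, and the physical coverage gaps before the first and after the
last marker of each chromosome.  Writes results/maps/.
"""

import json
from pathlib import Path

from recland import io
from recland.genmap import build_genetic_map, coverage_gaps, interval_stats, map_totals
from recland.landscape import GenomeLayout

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    layout = GenomeLayout.read(ROOT / "data" / "layout.tsv")
    out = ROOT / "maps"
    out.mkdir(parents=True, exist_ok=True)
    for name in ("control", "shifted"):
        gm, mm = io.read_genotypes(
            ROOT / "qc" / name / "genotypes.qc.tsv", ROOT / "qc" / name / "markers.qc.tsv"
        )
        co = io.read_crossovers(ROOT / "crossovers" / f"{name}.tsv")
        gmap = build_genetic_map(interval_stats(co, gm, mm))
        io.write_intervals(gmap.intervals, out / f"{name}.genetic_map.tsv")
        io.intervals_to_bedgraph(gmap.intervals, out / f"{name}.bedgraph")
        summary = map_totals(gmap)
        with open(out / f"{name}.summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        cov = coverage_gaps(mm, layout.chrom_lengths)
        cov.to_csv(out / f"{name}.coverage.tsv", sep="\t", index=False)
        per_chrom = ", ".join(f"{k} {v:.1f}" for k, v in summary["chrom_cm"].items())
        print(f"{name}: genome map {summary['genome_cm']:.1f} cM "
              f"(~{summary['expected_co_1dp']} COs/individual at 50 cM/CO)")
        print(f"  per chromosome: {per_chrom}")
        print(f"  max terminal coverage gap: "
              f"{max(cov['pct_uncovered_start'].max(), cov['pct_uncovered_end'].max()):.3f}%")


if __name__ == "__main__":
    main()
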