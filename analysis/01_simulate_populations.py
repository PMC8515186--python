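"""Simulate the two study populations.

Generates a control F2 population (90 individuals, 7 MorexV2-sized
chromosomes, ~11,000 evenly spaced markers, distally concentrated
U-shaped landscape) and a knockdown-like population in which 10% of the
interstitial genetic length has been moved to the terminal 2% of each
chromosome arm.  Writes genotypes, marker maps, truth records and the
genome zone layout under results/data/.
"""

import sys
from pathlib import Path

from recland import io
from recland.landscape import GenomeLayout
from recland.simulate import SimConfig, simulate_f2, with_shifted_landscape

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    control_cfg = SimConfig(seed=SEED)
    shifted_cfg = with_shifted_landscape(SimConfig(seed=SEED + 1), 0.10)
    for name, cfg in (("control", control_cfg), ("shifted", shifted_cfg)):
        gm, mm, truths = simulate_f2(cfg)
        pop = OUT / name
        pop.mkdir(exist_ok=True)
        meta = {"population": name, "seed": cfg.seed}
        io.write_genotypes(gm, pop / "genotypes.tsv", meta)
        io.write_marker_map(mm, pop / "markers.tsv", meta)
        io.write_truth(truths, pop / "truth.jsonl")
        print(f"{name}: {gm.n_individuals} individuals x {gm.n_markers} markers (seed {cfg.seed})")
    layout = GenomeLayout.default({c.name: c.length_bp for c in control_cfg.chromosomes})
    layout.write(OUT / "layout.tsv")
    print(f"zone layout for {len(layout.chrom_lengths)} chromosomes -> {OUT / 'layout.tsv'}")


if __name__ == "__main__":
    main()
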