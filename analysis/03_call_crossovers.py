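"""Call validated crossovers in both populations.

Uses the three-marker confirmation window with missing-call condensation,
writes the crossover tables (TSV + BED) under results/crossovers/, and —
because the populations are simulated — scores the caller against the
recorded truth: total score versus true crossover count and sensitivity on
well-separated crossovers.
"""

from pathlib import Path

from recland import io
from recland.caller import CallerConfig, call_crossovers_population
from recland.simulate import total_true_crossovers
from recland.validation import precision, sensitivity, truth_intervals, well_separated

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = CallerConfig(window=3)
    out = ROOT / "crossovers"
    out.mkdir(parents=True, exist_ok=True)
    for name in ("control", "shifted"):
        gm, mm = io.read_genotypes(
            ROOT / "qc" / name / "genotypes.qc.tsv", ROOT / "qc" / name / "markers.qc.tsv"
        )
        co = call_crossovers_population(gm, mm, cfg)
        io.write_crossovers(co, out / f"{name}.tsv", cfg.__dict__)
        io.crossovers_to_bed(co).to_csv(out / f"{name}.bed", sep="\t", index=False, header=False)
        truths = io.read_truth(ROOT / "data" / name / "truth.jsonl")
        truths = [t for t in truths if t.individual in set(gm.individuals)]
        ti = truth_intervals(truths, mm)
        ws = well_separated(ti)
        sens, hits, n_ws = sensitivity(co, ws, mm)
        prec = precision(co, ti, mm)
        print(f"{name}: {len(co)} events, total score {int(co['score'].sum())} "
              f"(true crossovers {total_true_crossovers(truths)}); "
              f"sensitivity on {n_ws} well-separated truths: {100 * sens:.1f}%; "
              f"precision: {100 * prec:.1f}%")


if __name__ == "__main__":
    main()
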