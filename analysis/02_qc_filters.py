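"""Apply marker and individual quality filters to both populations.

Mirrors the bookkeeping of an array-genotyping study: logs how many
markers and individuals survive each filter and writes the filtered
genotypes plus removal reports under results/qc/.
"""

from pathlib import Path

from recland import io
from recland.qc import QcCriteria, apply_qc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    crit = QcCriteria()
    for name in ("control", "shifted"):
        pop = ROOT / "data" / name
        gm, mm = io.read_genotypes(pop / "genotypes.tsv", pop / "markers.tsv")
        n_mark0, n_ind0 = gm.n_markers, gm.n_individuals
        gm2, mm2, mrep, irep = apply_qc(gm, mm, crit)
        out = ROOT / "qc" / name
        out.mkdir(parents=True, exist_ok=True)
        io.write_genotypes(gm2, out / "genotypes.qc.tsv", crit.__dict__)
        io.write_marker_map(mm2, out / "markers.qc.tsv", crit.__dict__)
        mrep.to_csv(out / "removed_markers.tsv", sep="\t", index=False)
        irep.to_csv(out / "removed_individuals.tsv", sep="\t", index=False)
        print(f"{name}: markers {n_mark0} -> {gm2.n_markers}, "
              f"individuals {n_ind0} -> {gm2.n_individuals}")
        if len(mrep):
            print(f"  marker removals by reason: {mrep['reason'].value_counts().to_dict()}")


if __name__ == "__main__":
    main()
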