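"""Calibrate the comparison statistics on replicated simulations.

Null: two populations drawn from the same landscape — the zone chi-square
and terminal-bin Wilcoxon p-values should be uniform.  Alternative: 10% of
the interstitial genetic length moved to the terminal 2% of each arm —
the tests should detect the shift.  Replicate counts are reduced here for
a quick narrative run; the acceptance script runs the full calibration.
"""

import json
import sys
from pathlib import Path

from recland.experiments import calibration_alternative, calibration_null

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026
N_NULL = int(sys.argv[2]) if len(sys.argv) > 2 else 100
N_ALT = int(sys.argv[3]) if len(sys.argv) > 3 else 50
OUT = Path(__file__).resolve().parents[1] / "results" / "calibration"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    null = calibration_null(SEED, n_rep=N_NULL)
    print(f"null ({N_NULL} replicates, n=60/population):")
    print(f"  Z1 chi-square p-values: KS-uniform p = {null['z1_chi2_ks_p']:.3f}, "
          f"reject rate at 0.05 = {null['z1_chi2_reject_rate']:.3f}")
    print(f"  terminal-bin Wilcoxon p-values: exact-null GOF p = "
          f"{null['terminal_wilcoxon_calibration_p']:.3f}, "
          f"reject rate at 0.05 = {null['terminal_reject_rate']:.3f}")
    alt = calibration_alternative(SEED, n_rep=N_ALT)
    print(f"alternative ({N_ALT} replicates, n=90/population, 10% interstitial moved):")
    print(f"  terminal-bin Wilcoxon detection: {alt['wilcoxon_detection_rate']:.2f}")
    print(f"  Z1-vs-Z2 chi-square detection:  {alt['chi2_detection_rate']:.2f}")
    print(f"  joint: {alt['joint_detection_rate']:.2f}, "
          f"either: {alt['either_detection_rate']:.2f}")
    with open(OUT / "calibration.json", "w") as fh:
        json.dump({"null": null, "alternative": alt}, fh, indent=2)


if __name__ == "__main__":
    main()
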