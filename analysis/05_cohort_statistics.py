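"""Cohort-level comparisons with exact nonparametric tests.

Mirrors the study's comparison structure: paired two-tailed signed-rank
tests of Quiet vs Active for each Vm quantity within each cell class, and
one-tailed signed-rank tests of the hypothesized uEPSP-amplitude and
baseline-Vm contrasts (PV increase/depolarization, Sst decrease/
hyperpolarization).  Prints the test table and writes
results/cohort_statistics.json.
"""

import csv
import json
from collections import defaultdict
from pathlib import Path

from statephys import box_stats, signed_rank_exact

BASE = Path(__file__).resolve().parents[1] / "results"

VM_KEYS = ("mean_vm_mV", "sd_vm_mV", "ap_rate_hz", "band_amp_1_5_mV", "peak_xcorr")
DIRECTION = {"PV": "greater", "Sst": "less"}


def _load(name):
    with open(BASE / name, newline="") as f:
        return list(csv.DictReader(f))


def main() -> None:
    vm_rows = _load("vm_state_stats.csv")
    ue_rows = _load("uepsp_measurements.csv")
    by_cell = defaultdict(dict)
    for r in vm_rows:
        by_cell[r["session"]][r["state"]] = r
    report = {}
    for cls in ("PV", "Sst"):
        cells = {k: v for k, v in by_cell.items() if v["Quiet"]["cell_class"] == cls}
        entry = {}
        for key in VM_KEYS:
            diffs = [float(v["Active"][key]) - float(v["Quiet"][key])
                     for v in cells.values()]
            t = signed_rank_exact(diffs, sided="two")
            entry[key] = {"diffs": [round(d, 4) for d in diffs],
                          "p_two_tailed": t.p_value,
                          "box": vars(box_stats(diffs))}
            print(f"{cls} {key:16s} Active-Quiet median "
                  f"{entry[key]['box']['median']:+.3f}  p={t.p_value:.3g}")
        ue_cells = defaultdict(dict)
        for r in ue_rows:
            if r["cell_class"] == cls and r["amplitude_mV"]:
                ue_cells[r["session"]][r["state"]] = r
        for key, label in (("amplitude_mV", "uepsp_amplitude"),
                           ("baseline_vm_mV", "uepsp_baseline")):
            diffs = [float(v["Active"][key]) - float(v["Quiet"][key])
                     for v in ue_cells.values() if len(v) == 2]
            t = signed_rank_exact(diffs, sided="one", direction=DIRECTION[cls])
            entry[label] = {"diffs": [round(d, 4) for d in diffs],
                            "direction": DIRECTION[cls],
                            "p_one_tailed": t.p_value, "n": t.n}
            print(f"{cls} {label:16s} one-tailed ({DIRECTION[cls]}) "
                  f"n={t.n}  p={t.p_value:.3g}")
        report[cls] = entry
    (BASE / "cohort_statistics.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    print("wrote results/cohort_statistics.json")


if __name__ == "__main__":
    main()
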