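"""State-resolved spontaneous Vm statistics per cell.

For every session and both states: mean Vm and SD with APs excised,
spontaneous AP rate, 1–5 Hz Vm FFT band amplitude, and peak Vm–LFP
cross-correlation — the per-cell quantities behind the cohort comparisons.
Writes results/vm_state_stats.csv.
"""

import csv
import json
from pathlib import Path

from statephys import analyze_vm_state, detect_aps, read_session

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    index = json.loads((BASE / "sessions" / "index.json").read_text())
    rows = []
    for entry in index:
        session = read_session(BASE / "sessions" / entry["name"])
        vm = session.traces["vm"]
        spikes = detect_aps(vm)
        for state in ("Quiet", "Active"):
            s = analyze_vm_state(vm, session.traces["lfp"], session.states[state],
                                 spikes, session.stim_times_s)
            rows.append({
                "session": entry["name"], "cell_class": session.cell_class,
                "state": state,
                "mean_vm_mV": round(s.mean_vm_mV, 3),
                "sd_vm_mV": round(s.sd_vm_mV, 3),
                "ap_rate_hz": round(s.ap_rate_hz, 3),
                "band_amp_1_5_mV": round(s.band_amp_1_5_mV, 4),
                "peak_xcorr": round(s.peak_xcorr, 4),
                "n_segments": s.n_segments,
            })
        q, a = rows[-2], rows[-1]
        print(f"{entry['name']} ({session.cell_class}): "
              f"mean Vm quiet {q['mean_vm_mV']} -> active {a['mean_vm_mV']} mV, "
              f"rate {q['ap_rate_hz']} -> {a['ap_rate_hz']} Hz")
    with open(BASE / "vm_state_stats.csv", "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=rows[0].keys())
        w.writeheader()
        w.writerows(rows)
    print(f"wrote {len(rows)} rows to results/vm_state_stats.csv")


if __name__ == "__main__":
    main()
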