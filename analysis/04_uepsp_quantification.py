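"""Optogenetically evoked responses: presynaptic APs and postsynaptic uEPSPs.

Per session: evoked-AP reliability/latency/jitter on the juxtacellular
channel (10 ms criterion), then for each state the stimulus-triggered
smoothed Vm average (excluding stimuli with postsynaptic APs in the 50 ms
window starting 20 ms before onset) and its uEPSP quantification —
amplitude, onset latency, peak time, 20–80% rise time, baseline Vm.
Writes results/uepsp_measurements.csv.
"""

import csv
import json
from pathlib import Path

from statephys import (
    detect_aps,
    evoked_ap_stats,
    quantify_uepsp,
    read_session,
    triggered_average,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    index = json.loads((BASE / "sessions" / "index.json").read_text())
    rows = []
    for entry in index:
        session = read_session(BASE / "sessions" / entry["name"])
        vm = session.traces["vm"]
        spikes = detect_aps(vm)
        evoked = evoked_ap_stats(session.traces["juxta"], session.stim_times_s)
        for state in ("Quiet", "Active"):
            wf, n_used = triggered_average(vm, session.stim_times_s,
                                           session.states[state], spikes)
            m = (quantify_uepsp(wf, session.cell_class, n_used, state)
                 if wf is not None else None)
            rows.append({
                "session": entry["name"], "cell_class": session.cell_class,
                "state": state, "n_stimuli_used": n_used,
                "amplitude_mV": round(m.amplitude_mV, 4) if m and m.detected else "",
                "onset_latency_ms": round(m.onset_latency_ms, 3) if m and m.detected else "",
                "rise_time_20_80_ms": round(m.rise_time_20_80_ms, 3) if m and m.detected else "",
                "baseline_vm_mV": round(m.baseline_vm_mV, 3) if m and m.detected else "",
                "evoked_ap_reliability": round(evoked.reliability, 3),
                "evoked_ap_latency_ms": round(evoked.latency_ms, 3),
                "evoked_ap_jitter_ms": round(evoked.jitter_ms, 3),
            })
        q, a = rows[-2], rows[-1]
        print(f"{entry['name']} ({session.cell_class}): uEPSP quiet "
              f"{q['amplitude_mV']} mV ({q['n_stimuli_used']} stim) -> active "
              f"{a['amplitude_mV']} mV ({a['n_stimuli_used']} stim)")
    with open(BASE / "uepsp_measurements.csv", "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=rows[0].keys())
        w.writeheader()
        w.writerows(rows)
    print(f"wrote {len(rows)} rows to results/uepsp_measurements.csv")


if __name__ == "__main__":
    main()
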