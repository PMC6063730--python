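"""Simulate the study's two cohorts: five PV-like and five Sst-like cells.

Each synthetic session carries 20 kHz Vm/LFP/juxtacellular channels, a
200 Hz whisker-angle channel, 1 Hz optogenetic stimulation in alternating
stimulation/spontaneous blocks, and planted quiet/active epochs with
cell-class-appropriate Vm coupling and uEPSP amplitudes.  Sessions are
written as inspectable directories under results/sessions/ together with
their ground truth.
"""

import json
from pathlib import Path

from statephys import GeneratorConfig, generate_cohort, write_session

OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"
SEED = 2018
N_CELLS = 5
# 360 s of recording at 1 Hz stimulation in half-duty blocks yields ~50
# usable stimuli per state, the scale of the recorded data sets
DURATION_S = 360.0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    index = []
    for k, (cls, make) in enumerate(
        (("PV", GeneratorConfig.pv_like), ("Sst", GeneratorConfig.sst_like))
    ):
        cohort = generate_cohort(N_CELLS, make(duration_s=DURATION_S), seed=SEED + k)
        for i, (session, truth) in enumerate(cohort):
            name = f"{cls}_{i}"
            write_session(session, OUT / name)
            gt = {
                "state_intervals": {k: v.intervals.tolist()
                                    for k, v in truth.state_intervals.items()},
                "planted_uepsp_amp_mV": truth.planted_uepsp_amp_mV,
                "spike_times_s": truth.spike_times_s.tolist(),
                "stim_states": truth.stim_states,
            }
            (OUT / name / "ground_truth.json").write_text(json.dumps(gt, indent=1))
            index.append({"name": name, "cell_class": cls,
                          "n_stimuli": int(session.stim_times_s.size),
                          "n_planted_spikes": int(truth.spike_times_s.size)})
            print(f"{name}: {session.duration_s:.0f} s, "
                  f"{session.stim_times_s.size} stimuli, "
                  f"{truth.spike_times_s.size} planted spikes")
    (OUT / "index.json").write_text(json.dumps(index, indent=1))
    print(f"wrote {len(index)} sessions to {OUT}")


if __name__ == "__main__":
    main()
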