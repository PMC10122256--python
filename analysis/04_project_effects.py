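#!/usr/bin/env python
"""Stage 4: project accumulated header effects forward over rest days.

Uses the posterior-mean point estimates from stage 3 in the worked
scenario — roughly a group-average recent history of 36 short and 6 long
headers over the last four sessions — and adds 0-14 header-free days.
The short-header effect decays within days; the long-header effect barely
moves on this horizon.

Writes results/projection.csv (per-task trajectories).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

import headerlag as hl  # noqa: E402

OUT = ROOT / "results"
ADDED_DAYS = list(range(0, 15))


def main() -> None:
    params = hl.read_params(OUT / "posterior_mean_params.json")
    frames = []
    for task in (hl.Task.pro_point, hl.Task.anti_point):
        sc = hl.example_scenario(params, task=task)
        traj = hl.project_forward(sc, ADDED_DAYS)
        traj.insert(0, "task", task.value)
        frames.append(traj)
        s0, l0 = traj.iloc[0][["short_effect_ms", "long_effect_ms"]]
        s10 = traj.loc[traj["added_days"] == 10, "short_effect_ms"].item()
        l10 = traj.loc[traj["added_days"] == 10, "long_effect_ms"].item()
        print(f"{task.value}: day 0 short {s0:+.2f} ms, long {l0:+.2f} ms; "
              f"after 10 rest days short {s10:+.2f} ms "
              f"({100 * (1 - abs(s10) / abs(s0)):.1f}% smaller), "
              f"long {l10:+.2f} ms "
              f"({100 * abs(l10 - l0) / abs(l0):.2f}% change)")
        print(f"  per-header magnitude ratio |long/short|: "
              f"{hl.magnitude_ratio(params, task):.2f}")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "projection.csv", index=False)
    print(f"wrote {OUT / 'projection.csv'}")


if __name__ == "__main__":
    main()
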