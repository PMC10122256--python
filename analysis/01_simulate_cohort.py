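#!/usr/bin/env python
"""Stage 1: simulate the default synthetic cohort and write it to results/.

The generator reproduces the study design: 16 exposed and 14 control
adolescent athletes over a 29-day season, 1-4 training sessions per week,
negative-binomial header counts per session (mean 6.5, about one in seven
long), and 48-trial pro-/anti-point RT blocks before and after each session
with planted incorrect responses (3.6%) and +600 ms attention-lapse
outliers (4.2% of correct trials).

Output: results/cohort/{athletes,trials,exposures}.csv plus a small
summary JSON.  All downstream stages read from results/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import headerlag as hl  # noqa: E402

SEED = 1
OUT = ROOT / "results"


def main() -> None:
    cohort = hl.simulate_cohort(seed=SEED)
    d = cohort.dataset
    out = OUT / "cohort"
    hl.write_dataset(d, out)
    hl.write_params(cohort.config.true_params, OUT / "generating_params.json")

    n_exposed = sum(1 for a in d.athletes if a.group == hl.Group.exposed)
    summary = {
        "seed": SEED,
        "n_athletes": len(d.athletes),
        "n_exposed": n_exposed,
        "n_control": len(d.athletes) - n_exposed,
        "n_occasions": len(d.occasions),
        "n_trials": d.n_trials(),
        "n_header_days": len(d.exposures),
        "total_short_headers": sum(e.n_short for e in d.exposures),
        "total_long_headers": sum(e.n_long for e in d.exposures),
    }
    (OUT / "cohort_summary.json").write_text(json.dumps(summary, indent=1))
    for k, v in summary.items():
        print(f"{k:>20}: {v}")
    print(f"wrote {out}/ and {OUT / 'generating_params.json'}")


if __name__ == "__main__":
    main()
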