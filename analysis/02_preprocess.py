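#!/usr/bin/env python
"""Stage 2: clean the simulated cohort and write the analysis dataset.

Removes incorrect trials, then applies the iterative per-block chi-squared
outlier test (alpha = 0.005) to the correct RTs.  Writes the cleaned
dataset to results/clean/ and the removal bookkeeping to
results/preprocess_report.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import headerlag as hl  # noqa: E402

OUT = ROOT / "results"


def main() -> None:
    raw = hl.read_dataset(OUT / "cohort", require_complete=True)
    clean, report = hl.preprocess(raw)
    hl.write_dataset(clean, OUT / "clean")
    (OUT / "preprocess_report.json").write_text(json.dumps(report.to_dict(), indent=1))

    print(f"incorrect removed: {report.n_incorrect_removed} "
          f"({100 * report.frac_incorrect:.2f}% of all trials)")
    print(f"outliers removed:  {report.n_outliers_removed} "
          f"({100 * report.frac_outliers:.2f}% of correct trials)")
    print(f"trials remaining:  {clean.n_trials()}")
    print(f"wrote {OUT / 'clean'}/ and {OUT / 'preprocess_report.json'}")


if __name__ == "__main__":
    main()
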