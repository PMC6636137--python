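"""Regenerate the summary report from the CSV/JSON outputs of steps 01-04.

Reads everything back from the results directory (proving the round trip)
and prints one table per statistic: per-k consistency for each method, the
adjacent-design summary, the fixed-n summary and the calibration optima.
"""

import argparse
from pathlib import Path

from mosqsub.experiment import summarize


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    report = summarize(args.out_dir)
    for name, table in report.items():
        print(f"\n== {name} ==")
        print(table.to_string(index=False, max_rows=30))


if __name__ == "__main__":
    main()
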