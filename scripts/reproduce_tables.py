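#!/usr/bin/env python
"""OPTIONAL, UNTESTED convenience script: batch per-subject metric tables.

Runs the full analysis over a directory of PAMAP2 protocol ``.dat`` files
(or generic two-column CSVs) and prints one metric table per subject:
longest period and area above a threshold for the raw trace, the P1- and
P2-filtered traces, an optional fixed baseline window, and the
uncertainty-adjusted values.

The source recordings are NOT bundled and must be downloaded separately
(PAMAP2 from the UCI repository; the simultaneous physiological
measurements collection from PhysioNet).  Which subjects map to which
published rows, and what preprocessing the published tables applied, is not
specified anywhere, so this script makes no attempt to match them — it only
provides the batch plumbing.

Usage:
    python scripts/reproduce_tables.py DATA_DIR --format pamap2 \
        --threshold 105 --max-window 250 [--baseline-window 230]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

from sadjerk import AnalysisConfig, run_analysis


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("data_dir", type=Path)
    parser.add_argument("--format", choices=["pamap2", "csv"], default="pamap2")
    parser.add_argument("--threshold", type=float, default=105.0)
    parser.add_argument("--max-window", type=int, default=250)
    parser.add_argument("--baseline-window", type=int, default=None)
    args = parser.parse_args()

    pattern = "*.dat" if args.format == "pamap2" else "*.csv"
    files = sorted(args.data_dir.glob(pattern))
    if not files:
        print(f"no {pattern} files under {args.data_dir}", file=sys.stderr)
        return 1

    header = f"{'subject':<20} {'window':>8} {'l_max[s]':>10} {'area[beats]':>12} {'total[beats]':>12}"
    for path in files:
        config = AnalysisConfig(
            input_path=str(path),
            input_format=args.format,
            threshold=args.threshold,
            max_window=args.max_window,
            baseline_window=args.baseline_window,
        )
        try:
            report = run_analysis(config)
        except Exception as exc:  # batch mode: report and continue
            print(f"{path.name}: FAILED ({exc})", file=sys.stderr)
            continue
        print(header)
        for r in report.threshold_reports:
            label = "raw" if r.filter_window == 0 else str(r.filter_window)
            print(
                f"{path.stem:<20} {label:>8} {r.l_max:>10.0f} "
                f"{r.area_above:>12.1f} {r.total_area:>12.1f}"
            )
        u = report.uncertainty
        if u is not None:
            print(
                f"{path.stem:<20} {'adj':>8} {u.l_adj:>10d} {u.A_adj:>12.1f} {'':>12}"
            )
        print()
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
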