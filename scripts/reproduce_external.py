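#!/usr/bin/env python
"""Reproduce full-scale riboswitch landscape scans with an external backend.

The per-riboswitch landscape features reported for wild-type sequences (for
example a ~12 kcal/mol functional-window barrier, or a downhill window at
specific positions) depend on a full experimental nearest-neighbor parameter
set and on the published wild-type sequences, neither of which ships with
this package.  This optional script runs the identical pipeline with the
ViennaRNA command-line tools (RNAfold / RNAsubopt / RNAeval / RNAheat on
PATH) on a user-supplied FASTA of riboswitch sequences:

    python scripts/reproduce_external.py <riboswitches.fasta> --out <dir> \
        [--config run.yaml] [--seed N]

Note: RNAsubopt performs its own stochastic backtracking without a seed
option, so external-backend runs are not bit-reproducible; the landscape
statistics are stable across runs at the default 1,000-structure depth.
"""

from __future__ import annotations

import argparse
import dataclasses
from pathlib import Path

from riboscan.backends import ExternalBackend
from riboscan.cli_report import RunConfig, run_scan
from riboscan.rna_core import read_fasta


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fasta", type=Path)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--config", type=Path, default=None)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    cfg = RunConfig.from_yaml(args.config) if args.config else RunConfig()
    cfg = dataclasses.replace(cfg, backend="external", seed=args.seed)
    backend = ExternalBackend()
    for seq in read_fasta(args.fasta):
        report = run_scan(seq, cfg, backend=backend, keep_landscapes=True)
        outdir = args.out / seq.id.replace("/", "_")
        report.to_dir(outdir, write_landscapes=True)
        print(
            f"{seq.id}: {report.control.mechanism} control; windows: "
            f"{', '.join(f'{w.kind} {w.start_len}-{w.end_len}' for w in report.windows) or 'none'}"
        )


if __name__ == "__main__":
    main()
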