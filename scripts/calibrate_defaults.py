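#!/usr/bin/env python
"""Re-derive the calibrated default generator configuration.

Runs the calibration search (`affectcontagion.calibrate.calibrate_config`)
that produced the numbers frozen in
`affectcontagion.simulate.default_calibrated_config`, and prints the
resulting configuration together with its verified cell means and SDs.

Usage:
    python scripts/calibrate_defaults.py [--n-sim 3000] [--n-check 2000]
                                         [--seed 2026] [--out config.yaml]
"""

from __future__ import annotations

import argparse
import json

import yaml

from affectcontagion.calibrate import calibrate_config


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n-sim", type=int, default=3000)
    parser.add_argument("--n-check", type=int, default=2000)
    parser.add_argument("--seed", type=int, default=2026)
    parser.add_argument("--out", type=str, default=None,
                        help="write the calibrated config as YAML")
    args = parser.parse_args()

    result = calibrate_config(n_sim=args.n_sim, n_check=args.n_check, seed=args.seed)
    print(json.dumps(
        {
            "config": result.config.to_dict(),
            "target_means": result.target_means,
            "target_sds": result.target_sds,
            "checked_cell_means": result.checked_cell_means,
            "checked_cell_sds": result.checked_cell_sds,
            "max_abs_error_on_means": result.max_abs_error,
        },
        indent=2,
        sort_keys=True,
    ))
    if args.out:
        with open(args.out, "w", encoding="utf-8") as handle:
            yaml.safe_dump(result.config.to_dict(), handle, sort_keys=True)


if __name__ == "__main__":
    main()
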