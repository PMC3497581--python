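"""Regenerate the packaged Monte Carlo critical-value table for Rao's U.

Usage: python scripts/make_rao_table.py [--reps 200000] [--max-n 100]

Writes src/acsiva/data/rao_critical_values.tsv.  Run once; the table is
checked in so the package works offline and deterministically.
"""

import argparse
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from acsiva.rao_table import LEVELS, critical_values  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=200000)
    ap.add_argument("--max-n", type=int, default=100)
    ap.add_argument("--seed", type=int, default=20120726)
    args = ap.parse_args()

    out = pathlib.Path(__file__).resolve().parents[1] / "src/acsiva/data/rao_critical_values.tsv"
    out.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)
    lines = ["n\t" + "\t".join(f"u_{a}" for a in LEVELS)]
    for n in range(4, args.max_n + 1):
        crits = critical_values(n, args.reps, rng)
        lines.append(f"{n}\t" + "\t".join(f"{c:.3f}" for c in crits))
        print(f"n={n} done", flush=True)
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
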