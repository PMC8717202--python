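"""Regenerate the packaged ¹⁷⁷Lu dose-point-kernel table.

Runs the condensed-history generator in prrtdose.dose_engine.dpk with its
fixed seed and writes the CSV asset the dose engine loads by default.

Usage: python scripts/make_kernel.py [--histories N] [--seed S]
"""

import argparse
from pathlib import Path

from prrtdose.dose_engine import dpk


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--histories", type=int, default=400_000)
    ap.add_argument("--seed", type=int, default=20177)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1]
        / "src/prrtdose/dose_engine/data/lu177_dpk_water_synthetic.csv",
    )
    args = ap.parse_args()

    radius_um, cum = dpk.generate_lu177_kernel(n_histories=args.histories, seed=args.seed)
    lines = dpk.kernel_table_header()
    lines += [f"{r:.1f},{c:.8f}" for r, c in zip(radius_um, cum)]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text("\n".join(lines) + "\n")
    print(f"wrote {args.out} ({len(radius_um)} radial bins)")


if __name__ == "__main__":
    main()
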