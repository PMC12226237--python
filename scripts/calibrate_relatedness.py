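"""Regenerate the IBD degree-band calibration table.

Simulates pedigree pairs of known relationship degree, summarizes
their true IBD segments (sum of segments >12 cM, count of segments
>16 cM), and derives band thresholds as geometric midpoints between
adjacent degree-band distributions.  Writes
src/adnapop/data/ibd_calibration.json.

Run from the repository root:

    python scripts/calibrate_relatedness.py [--seed 2024] [--reps 150]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from adnapop.synthetic import lineal_pedigree, sibling_pedigree, simulate_pedigree


def pair_sums(pedigree, pair, reps, seed0):
    sums = []
    for r in range(reps):
        real = simulate_pedigree(pedigree, seed0 + r)
        lengths = np.array([e - s for _, s, e in real.ibd_segments(*pair)])
        sums.append(float(lengths[lengths > 12.0].sum()))
    return np.array(sums)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--reps", type=int, default=150)
    ap.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parents[1] / "src/adnapop/data/ibd_calibration.json",
    )
    args = ap.parse_args()

    bands: dict[str, np.ndarray] = {}
    chunks = {"first": [], "second_fourth": [], "fifth_seventh": []}
    chunks["first"].append(pair_sums(sibling_pedigree(), ("S1", "S2"), args.reps, args.seed))
    chunks["first"].append(pair_sums(lineal_pedigree(1), ("G0", "G1"), args.reps, args.seed + 10_000))
    for d in (2, 3, 4):
        chunks["second_fourth"].append(
            pair_sums(lineal_pedigree(d), ("G0", f"G{d}"), args.reps, args.seed + d * 10_000)
        )
    for d in (5, 6, 7):
        chunks["fifth_seventh"].append(
            pair_sums(lineal_pedigree(d), ("G0", f"G{d}"), args.reps, args.seed + d * 10_000)
        )
    for k, v in chunks.items():
        bands[k] = np.concatenate(v)

    # geometric midpoint between a low quantile of the closer band and a
    # high quantile of the more distant band
    lo_first = np.quantile(bands["first"], 0.005)
    hi_second = np.quantile(bands["second_fourth"], 0.995)
    t_first = float(np.sqrt(lo_first * hi_second))
    lo_second = np.quantile(bands["second_fourth"], 0.05)
    hi_fifth = np.quantile(np.maximum(bands["fifth_seventh"], 1.0), 0.95)
    t_second = float(np.sqrt(lo_second * hi_fifth))

    cal = {
        "first_degree_sum_cM": round(t_first, 1),
        "second_fourth_sum_cM": round(t_second, 1),
        "min_detectable_cM": 16.0,
        "min_n_long": 2,
        "calibration": {
            "seed": args.seed,
            "replicates_per_relationship": args.reps,
            "band_means_cM": {k: round(float(v.mean()), 1) for k, v in bands.items()},
            "band_sd_cM": {k: round(float(v.std()), 1) for k, v in bands.items()},
        },
    }
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(cal, indent=1, sort_keys=True) + "\n")
    print(json.dumps(cal, indent=1, sort_keys=True))


if __name__ == "__main__":
    main()
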