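#!/usr/bin/env python
"""Quantify accretion, macroboring, grazing and microboring per block.

Reads the simulated scan pairs from scratch/sim/, calibrates densitometry
from the phantom table, runs the registration/partition pipeline on every
pre/post pair, and writes one row per block to
results/functional_group_rates.csv (standardized metrics plus, since
these are simulations, the ground-truth recovery errors).

Usage: python analysis/02_quantify_blocks.py
"""

import json
from pathlib import Path

import pandas as pd

import barct
from barct.volume_io import fit_densitometry, read_volume

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    scratch = ROOT / "scratch" / "sim"
    phantoms = pd.read_csv(results / "phantoms.csv")
    cal = fit_densitometry(list(zip(phantoms.mean_attenuation, phantoms.density_gcc)))
    print(f"densitometry: {cal.slope:.5f} g/cc per unit, r² = {cal.r_squared:.4f}")

    blocks = pd.read_csv(results / "blocks.csv")
    rows = []
    for _, blk in blocks.iterrows():
        pre = read_volume(scratch / f"{blk.bar_id}_pre.nrrd")
        post = read_volume(scratch / f"{blk.bar_id}_post.nrrd")
        truth = json.loads((scratch / f"{blk.bar_id}_truth.json").read_text())
        analysis = barct.analyze_bar_pair(pre, post, cal)
        r = analysis.rates
        c = analysis.labels.counts()
        vv = analysis.labels.voxel_volume_cm3
        rows.append(
            {
                "bar_id": blk.bar_id,
                "site": blk.site,
                "mean_field_ph": blk.mean_field_ph,
                "accretion_cm3_per_cm2": r.accretion_cm3_per_cm2,
                "macroboring_cm3_per_cm2": r.macroboring_cm3_per_cm2,
                "grazing_cm3_per_cm2": r.grazing_cm3_per_cm2,
                "microboring_g_per_cm2": r.microboring_g_per_cm2,
                "initial_surface_area_cm2": r.initial_surface_area_cm2,
                "final_surface_area_cm2": r.final_surface_area_cm2,
                "deployment_days": r.deployment_days,
                "accretion_relerr": c["accretion"] * vv / truth["accretion_volume_cm3"] - 1,
                "macroboring_relerr": c["macroboring_void"] * vv / truth["macroboring_volume_cm3"] - 1,
                "grazing_relerr": c["grazed"] * vv / truth["grazing_volume_cm3"] - 1,
            }
        )
        print(
            f"{blk.bar_id} ({blk.site}, pH {blk.mean_field_ph}): "
            f"macroboring {rows[-1]['macroboring_cm3_per_cm2']:.2e} cm³/cm², "
            f"recovery errors ≤ {max(abs(rows[-1][k]) for k in ('accretion_relerr','macroboring_relerr','grazing_relerr')):.1%}"
        )

    out = results / "functional_group_rates.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
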