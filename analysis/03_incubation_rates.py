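#!/usr/bin/env python
"""Reduce chamber incubations to calcification and O₂ rates per block.

Reads results/incubation_records.csv, blank-corrects each block's light
and dark runs against the paired blank chambers at its pH level, and
writes light/dark/24-h calcification (µmol CaCO₃ cm⁻² h⁻¹) plus net
photosynthesis and dark respiration (µg O₂ cm⁻² min⁻¹) to
results/incubation_rates.csv.

Usage: python analysis/03_incubation_rates.py
"""

from pathlib import Path

import pandas as pd

from barct.incubation_chem import frame_to_records, rates_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    records = frame_to_records(pd.read_csv(results / "incubation_records.csv"))
    table = rates_table(records)
    blocks = pd.read_csv(results / "blocks.csv")
    table = table.merge(blocks[["bar_id", "site", "mean_field_ph"]], on="bar_id")
    out = results / "incubation_rates.csv"
    table.to_csv(out, index=False)
    neg = (table.g_24h < 0).sum()
    print(f"{len(table)} blocks; {neg} net-dissolving over 24 h")
    print(f"g_24h range: {table.g_24h.min():.3f} to {table.g_24h.max():.3f} µmol cm⁻² h⁻¹")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
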