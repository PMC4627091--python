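#!/usr/bin/env python
"""Fit the simulated curves and assemble the four landscapes.

Reads the dataset written by 02_simulate_chip.py, fits every titration
(K_d, amplitude) and melt (T_m, dH_T), runs the per-replicate Van't
Hoff regression, and assembles the relative landscape (S_m, ddG, ddH,
dTm vs wild type) with propagated errors.  Compares the recovered
landscape against the generating truth.  Writes results/landscape/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from spinachscan import io, pipeline

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "landscape"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    truth = io.read_table(BASE / "simulated" / "truth.tsv", ["mutant_id", "position"])
    titr = io.read_titrations(BASE / "simulated" / "titrations.tsv")
    melts = io.read_melts(BASE / "simulated" / "melts.tsv")

    positions = {
        r.mutant_id: (() if r.mutant_id in ("WT", "NEG") else (int(r.position),))
        for r in truth.itertuples(index=False)
    }
    seq = io.read_fasta(BASE / "simulated" / "reference.fasta")

    cfg = pipeline.RunConfig(seed=args.seed)
    result = pipeline.run_pipeline(titr, melts, positions, len(seq), cfg, outdir=OUT)
    land = result.landscape.set_index("mutant_id")
    tr = truth.set_index("mutant_id")
    print(
        f"landscape: {land.shape[0]} mutants, "
        f"{int(land['fluorogenic'].sum())} fluorogenic"
    )
    for got, want, unit in [("s_m", "amplitude", ""), ("ddg", "ddg", "kcal/mol"),
                            ("ddh", "ddh", "kcal/mol"), ("dtm", "dtm_C", "C")]:
        err = (land[got] - tr[want].astype(float)).abs().dropna().median()
        print(f"  median |recovered - truth| {got:4s}: {err:.4f} {unit}")
    wt_kd = result.binding_fits.query("mutant_id == 'WT' and temperature_C == 23")[
        "kd_uM"
    ].mean()
    print(f"  wild-type Kd at 23 C: {wt_kd:.3f} uM (truth 1.180)")
    if result.warnings:
        print("warnings:", "; ".join(result.warnings))
    print(f"wrote fits + landscape -> {OUT}")


if __name__ == "__main__":
    main()
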