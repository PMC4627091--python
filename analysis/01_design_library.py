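#!/usr/bin/env python
"""Enumerate the scanning-mutagenesis libraries and plan the chip.

Builds the full single-point mutant (SPM) library, the complete
compensatory double-point mutant (DPM) scan, two-fragment assembly
designs for every SPM, and a 640-cell / 4-replicate chip layout for the
first chip's worth of mutants.  Writes tables under results/library/.
"""

import argparse
from pathlib import Path

import pandas as pd

from spinachscan import io, library, simulate

OUT = Path(__file__).resolve().parent.parent / "results" / "library"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    seq, stem_pairs = simulate.synthetic_reference()
    print(f"reference: {len(seq)} nt, {len(stem_pairs)} designed stem pairs")

    spms = library.enumerate_spms(seq)
    dpms = library.enumerate_compensatory_dpms(seq)
    print(f"SPM library: {len(spms)} mutants (3 per position)")
    print(f"complete compensatory DPM scan: {len(dpms)} mutants (3 per pair)")
    stem_dpms = library.enumerate_compensatory_dpms(
        seq, pairs=stem_pairs, pairing_map=stem_pairs
    )
    print(f"stem-rescue DPM subset: {len(stem_dpms)} Watson-Crick-restoring mutants")

    io.write_mutants(OUT / "spm_library.tsv", spms)
    io.write_mutants(OUT / "stem_dpm_library.tsv", stem_dpms)

    rows = []
    for spec in spms:
        mut_seq = library.apply_mutations(seq, spec)
        frag = library.design_fragments(
            mut_seq, [m.position for m in spec.substitutions]
        )
        assert library.stitch_fragments(frag) == mut_seq
        rows.append({"id": spec.id, "placement": frag.mutation_placement})
    placements = pd.DataFrame(rows)
    print("fragment placements:", placements["placement"].value_counts().to_dict())
    io.write_table(OUT / "fragment_placements.tsv", placements)

    chip_mutants = [library.wildtype_spec(), library.negative_control_spec()]
    chip_mutants += spms[:158]
    layout = library.plan_chip_layout(
        chip_mutants, n_cells=640, replicates=4, seed=args.seed
    )
    io.write_table(OUT / "chip_layout.tsv", layout.to_frame())
    print(
        f"chip: {layout.n_cells} cells, {layout.replicates} replicates, "
        f"capacity {layout.capacity} mutants -> {OUT}"
    )


if __name__ == "__main__":
    main()
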