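#!/usr/bin/env python
"""Score the landscape per position and select engineering candidates.

Reads the assembled landscape, reports the landscape correlations
(fluorescence vs ddG / ddH / dTm), and lists the mutants inside the
beneficial 10% quantile of fluorescence, binding free energy and
melting temperature simultaneously.  Writes results/scores/.
"""

import argparse
from pathlib import Path

from spinachscan import io, landscape

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "scores"


def main():
    argparse.ArgumentParser().parse_args()

    land = io.read_landscape(BASE / "landscape" / "landscape.tsv")
    spms = land[land["positions"].astype(str).str.fullmatch(r"\d+")].copy()
    scored = landscape.score_spms(spms)
    n_pos = spms["positions"].astype(int).max()
    track = landscape.position_score(scored, n_pos)
    io.write_table(OUT / "score_track.tsv", track)
    print(
        f"scored {len(scored)} SPMs over {n_pos} positions; "
        f"track range [{track['score'].min():.2f}, {track['score'].max():.2f}]"
    )

    for x in ("ddg", "ddh", "dtm"):
        slope, intercept, r = landscape.correlate_landscapes(land, x, "s_m")
        print(f"  s_m vs {x:3s}: slope {slope:+.3f}, r {r:+.3f}")

    candidates = landscape.intersect_candidates(spms, ("s_m", "ddg", "dtm"), q=0.10)
    io.write_table(OUT / "candidates.tsv", candidates)
    print(
        f"{len(candidates)} mutants in all three beneficial 10% quantiles: "
        f"{', '.join(candidates['mutant_id']) or '(none)'}"
    )
    print(f"wrote scores -> {OUT}")


if __name__ == "__main__":
    main()
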