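#!/usr/bin/env python
"""Generate the four composition movies used throughout the analysis.

One synthetic SH movie per membrane composition (DOPC:DOPA, DOPC:DOPA:Chol,
DPhPC:DPhPA, SLPC:SLPA), 30 frames at a 1-min period, 64x64 px, R = 10 um,
written as TIFF + JSON sidecar + ground-truth tau CSV under results/movies/.
The cholesterol pair for the slowdown comparison (02/03) is generated there
with a longer schedule; these are the default Fig-1E-style acquisitions.
"""

from pathlib import Path

from shgflux.io import write_movie
from shgflux.synthetic import (
    PRESETS,
    OpticsConfig,
    default_geometry,
    default_schedule,
    generate_movie,
)

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "movies"


def main() -> None:
    optics = OpticsConfig()
    geometry = default_geometry(optics=optics)
    schedule = default_schedule(30, 60.0)
    for name in PRESETS:
        movie = generate_movie(PRESETS[name], geometry, optics, schedule,
                               seed=SEED)
        fname = name.replace(":", "_") + ".tif"
        path = write_movie(movie, OUT / fname)
        tau = movie.truth.tau_field.tau
        kind = ("no decay" if not movie.truth.preset.translocating
                else f"tau {tau.min():.0f}-{tau.max():.0f} s")
        print(f"{name:16s} -> {path.name:24s} ({kind})")


if __name__ == "__main__":
    main()
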