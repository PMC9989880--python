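#!/usr/bin/env python
"""Convert the measured decay map into Ca2+ translocation kinetics.

Uses the decay map from 02 plus the physical anchors (headgroup charge
density 1 mC/m^2, R = 10 um, 5 mM CaCl2) to compute, under both valence
conventions: the bound-ion count, the per-ion translocation time for the
fastest/slowest ROI and the whole-GUV mean, and the permeability
coefficient.  Also reports the single-pore permeability implied by an
open-pore flux of 660 ions/us at 1000 mM, and the open-pore duty cycle a
GUV would need to sustain a 1e-8 cm/s permeability through such pores.

Writes results/kinetics/kinetics.json.
"""

import json
import math
from pathlib import Path

import pandas as pd

from shgflux.energetics import required_duty_cycle
from shgflux.kinetics import (
    KineticsInputs,
    ValenceConvention,
    bound_ion_count,
    grahame_potential,
    per_ion_translocation_time,
    permeability_coefficient,
    single_pore_permeability,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    df = pd.read_csv(ROOT / "decay_mapping" / "decay_map.csv")
    finite = df.loc[df["converged"] & ~df["no_decay"], "tau_s"]
    taus = {
        "fastest_roi": float(finite.min()),
        "mean": float(finite.mean()),
        "slowest_roi": float(finite.max()),
    }
    results = {"tau_s": taus, "conventions": {}}
    for conv in ValenceConvention:
        block = {}
        for label, tau in taus.items():
            inp = KineticsInputs(sigma=1e-3, radius_m=10e-6,
                                 c_bulk_molar=5e-3, tau_eff_s=tau,
                                 valence_convention=conv)
            n = bound_ion_count(inp)
            block[label] = {
                "n_ions": n,
                "t_ion_us": per_ion_translocation_time(inp, n) * 1e6,
                "P_cm_per_s": permeability_coefficient(inp, n),
            }
        results["conventions"][conv.value] = block
        f = block["fastest_roi"]
        print(f"{conv.value:18s} fastest ROI: N = {f['n_ions']:.3g}, "
              f"t_ion = {f['t_ion_us']:.1f} us, P = {f['P_cm_per_s']:.2e} cm/s")

    p_pore = single_pore_permeability(660e6, 1.0)
    area_cm2 = 4.0 * math.pi * (10e-4) ** 2
    duty = required_duty_cycle(1e-8, p_pore, area_cm2)
    results["single_pore"] = {
        "p_pore_cm3_per_s": p_pore,
        "duty_cycle_for_1e-8_cm_per_s": duty,
    }
    print(f"single-pore permeability: {p_pore:.2e} cm3/s; open-pore duty "
          f"cycle for P = 1e-8 cm/s over the GUV: {duty:.2e}")

    psi = grahame_potential(-1e-3, ((2.0, 0.005), (-1.0, 0.010))).psi0_V
    results["surface_potential_V_at_1mC_5mM"] = psi
    print(f"Grahame surface potential at -1 mC/m^2 in 5 mM CaCl2: "
          f"{psi*1e3:.2f} mV (domain-scale potentials of ~-300 mV imply far "
          f"higher local charge densities)")

    out = ROOT / "kinetics"
    out.mkdir(parents=True, exist_ok=True)
    (out / "kinetics.json").write_text(json.dumps(results, indent=1,
                                                  sort_keys=True))


if __name__ == "__main__":
    main()
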