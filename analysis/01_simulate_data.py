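"""Generate the synthetic datasets used by the downstream analyses.

Writes DMC-like and ISEP-like particle tracks, a lipid titration, the
calibration standards with cluster spots, and five-site photobleaching
traces under results/data/, all from one master seed.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fisbkit.synth import (
    SimulationSpec,
    gen_bleach_traces,
    gen_brownian_tracks,
    gen_calibration_and_spots,
    gen_titration,
)
from fisbkit.tracking import write_tracks_csv

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    dmc = SimulationSpec(seed=SEED)  # 24 tracks, 250 s, D = 2800 nm^2/s
    write_tracks_csv(gen_brownian_tracks(dmc), OUT / "tracks_dmc.csv")

    isep = SimulationSpec(seed=SEED + 1, diffusivity=28.0, n_tracks=25)
    write_tracks_csv(gen_brownian_tracks(isep), OUT / "tracks_isep.csv")

    for name, kd in (("cl", 1.0e-6), ("pg", 3.6e-6), ("kk", 9.1e-6)):
        t = gen_titration(SimulationSpec(seed=SEED, true_kd=kd))
        pd.DataFrame(
            {"lipid_conc_M": t.lipid_conc, "fraction_bound": t.fraction_bound}
        ).to_csv(OUT / f"titration_{name}.csv", index=False)

    calib, spots = gen_calibration_and_spots(SimulationSpec(seed=SEED))
    calib.to_csv(OUT / "calibration.csv", index=False)
    spots.to_csv(OUT / "spots.csv", index=False)

    bleach = gen_bleach_traces(SimulationSpec(seed=SEED))
    pd.DataFrame(
        {
            "trace_id": np.arange(len(bleach.step_counts)),
            "steps": bleach.step_counts,
        }
    ).to_csv(OUT / "bleach.csv", index=False)

    print(f"wrote synthetic fixtures to {OUT}")
    print(
        "  tracks: 24 DMC-like (D=2800 nm^2/s), 25 ISEP-like (D=28 nm^2/s)"
    )
    print("  titrations: Kd = 1.0 (CL), 3.6 (PG), 9.1 (KK) uM")
    print("  calibration: slope 29.56 au/copy; 100 spots at 40 emitters")
    print("  bleach: 200 five-site traces at p = 0.80")


if __name__ == "__main__":
    main()
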