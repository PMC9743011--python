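"""Generate the synthetic study inputs: root observations, shoot series,
impedance spectra and chamber concentration records.

Emulates the measurement design — 16 seedlings in 4 soil-temperature
treatments, ~3-week minirhizotron imaging over two growing seasons plus
dormancy, 5–9-day shoot measurements, 36-frequency impedance spectra per
treatment, and 6–8-minute chamber records — with known ground truth
written alongside.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from _shared import BASE_SEED, OUT, demography_params, scenario_config
from rootdyn.eis import spectra_to_frame
from rootdyn.simulate import (
    EISimParams,
    ShootSimParams,
    simulate_chamber_series,
    simulate_eis,
    simulate_root_demography,
    simulate_shoot_growth,
)


def main() -> None:
    cfg = scenario_config()
    OUT.mkdir(parents=True, exist_ok=True)
    sc = cfg["scenario"]

    obs, truth = simulate_root_demography(demography_params(cfg))
    obs.to_csv(OUT / "observations.csv")
    truth.to_csv(OUT / "ground_truth.csv", index=False)
    print(f"simulated {len(truth)} roots ({truth.observed.sum()} observed, "
          f"{len(truth) - truth.observed.sum()} died within one imaging interval "
          "and were never photographed live)")

    rows = []
    for s in range(sc["n_seedlings"]):
        series, t0 = simulate_shoot_growth(
            ShootSimParams(asymptote=sc["shoot"]["asymptote_mm"],
                           midpoint_day=sc["shoot"]["midpoint_day"],
                           steepness=sc["shoot"]["steepness"],
                           season_end=sc["seasons"]["GS2"][1],
                           noise_sd=sc["shoot"]["noise_sd"]),
            seed=BASE_SEED + 100 + s,
        )
        for d, v in zip(series.days, series.values):
            rows.append({"seedling_id": f"s{s:03d}", "day": d, "height_mm": v,
                         "true_inflection_day": t0})
    pd.DataFrame(rows).to_csv(OUT / "shoots.csv", index=False)

    spectra = simulate_eis(EISimParams(
        classes={k: tuple(v) for k, v in sc["eis"]["classes"].items()},
        n_per_class=sc["eis"]["n_per_class"], noise_sd=sc["eis"]["noise_sd"],
        seed=BASE_SEED + 300,
    ))
    spectra_to_frame(spectra).to_csv(OUT / "spectra.csv", index=False)

    chamber_rows = []
    for i, (trt, slope) in enumerate(sorted(sc["chamber_slopes_ppm_h"].items())):
        t, c, true = simulate_chamber_series(slope, noise_sd=0.02,
                                             seed=BASE_SEED + 400 + i)
        for ts, cs in zip(t, c):
            chamber_rows.append({"treatment": trt, "time_s": ts,
                                 "concentration_ppm": cs, "true_slope_ppm_h": true})
    pd.DataFrame(chamber_rows).to_csv(OUT / "chamber.csv", index=False)
    print(f"wrote inputs for {sc['n_seedlings']} seedlings, "
          f"{len(spectra)} spectra, 4 chamber records -> {OUT}")


if __name__ == "__main__":
    main()
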