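"""Circadian phasing of [GABA]e and [Ca2+]i against the TTFL reference.

Registers each slice's fitted acrophase to circadian time (reference peak =
CT12), runs Rayleigh tests, and writes the single-cycle waveform averages.
The headline geometry: [GABA]e peaks in circadian night (~CT19.7), in
antiphase to daytime neuronal calcium (~CT6).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from scnrhythm import circular_mean, rayleigh_test, read_traces, single_cycle_average
from scnrhythm.circular import phase_table, register_acrophases

COHORT = Path("results/cohorts/wildtype")
OUT = Path("results/phase_geometry")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traces = [read_traces(p) for p in sorted(COHORT.glob("slice*.csv"))]
    rows = []
    samples = []
    for channel in ("GABAe", "Ca"):
        phases = register_acrophases(traces, channel, "PER2LUC")
        samples.extend(phases)
        mean_ct, r = circular_mean(phases)
        stat = rayleigh_test(phases)
        rows.append(
            dict(channel=channel, mean_ct=round(mean_ct, 2), R=round(r, 3),
                 rayleigh_p=stat.p, n=stat.n)
        )
        print(
            f"{channel}: peak CT {mean_ct:.2f}, R = {r:.3f}, "
            f"Rayleigh p = {stat.p:.2g} (n = {stat.n})"
        )
    pd.DataFrame(rows).to_csv(OUT / "circular_stats.csv", index=False)
    phase_table(samples).to_csv(OUT / "phases.csv", index=False)

    for channel in ("PER2LUC", "GABAe", "Ca"):
        wa = single_cycle_average(traces, channel, "PER2LUC")
        pd.DataFrame(
            dict(ct=wa.phase_grid, mean=wa.mean, sem=wa.sem)
        ).to_csv(OUT / f"waveform_{channel}.csv", index=False)
    print(f"waveform averages written to {OUT}")


if __name__ == "__main__":
    main()
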