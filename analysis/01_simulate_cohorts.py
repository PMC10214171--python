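"""Generate the synthetic study cohorts and write them as wide CSVs.

Three cohorts mirror the experiment families: a wild-type multiplexed
cohort (TTFL reference + [GABA]e + [Ca2+]i), a GABA-uptake-blocker
treatment cohort (trough-elevating intervention on a single reporter), and
a clock-null initiation cohort whose rhythm switches on at treatment.
"""

from pathlib import Path

from scnrhythm import CohortSpec, InterventionSpec, ReporterSpec, generate_cohort
from scnrhythm.simulate import (
    cohort_spec_to_json,
    initiation_cohort_spec,
    wildtype_cohort_spec,
    write_cohort,
)

OUT = Path("results/cohorts")
SEED = 1


def main() -> None:
    specs = {
        "wildtype": wildtype_cohort_spec(n_slices=8, seed=SEED),
        "treatment": CohortSpec(
            n_slices=7,
            duration=204.0,
            dt=0.5,
            reporters=[
                ReporterSpec(
                    name="GABAe",
                    period=24.1,
                    amplitude=1.0,
                    baseline_level=3.0,
                    noise_sd=0.1,
                    waveform="asymmetric",
                    sharpness=3.0,
                )
            ],
            interventions=[
                InterventionSpec(
                    start_time=144.0, trough_scale=0.56, amplitude_scale=0.8
                )
            ],
            inter_slice_period_sd=0.2,
            inter_slice_phase_sd=0.5,
            seed=SEED + 1,
        ),
        "initiation": initiation_cohort_spec(n_slices=4, seed=SEED + 2),
    }
    for name, spec in specs.items():
        outdir = OUT / name
        traces = generate_cohort(spec)
        write_cohort(traces, outdir)
        (outdir / "cohort_spec.json").write_text(cohort_spec_to_json(spec))
        print(f"{name}: wrote {spec.n_slices} slices ({spec.duration:g} h) -> {outdir}")


if __name__ == "__main__":
    main()
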