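#!/usr/bin/env python
"""Generate the synthetic switching datasets used by the downstream analyses.

Produces, under results/sim/:
  - one rendered ramp video (30 -> 45 -> 30 degC at 0.04 degC/s) per dose,
    with the truth transition temperature following the linear 43 -> 36 degC
    dose trend over 50 -> 90 kGy;
  - one 20-cycle 28-42 degC trace with 0.34 % per-cycle irreversible loss.

Videos are sampled every 5 s (instead of the camera's 0.9 frames/s) to keep
the rendered stacks small; the truth parameters are recorded alongside.
"""
import dataclasses
import json
import os

from gelswitch import SyntheticTruth, area_tracking, imaging_io, synthetic

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "sim")
DT = 5.0
DOSES = [50, 60, 70, 80, 90]


def tt_for_dose(dose: float) -> float:
    """Linear truth trend matching the observed 43 degC @ 50 kGy -> 36 @ 90."""
    return 43.0 - 0.175 * (dose - 50.0)


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    manifest = {}
    for dose in DOSES:
        profile = synthetic.make_temperature_profile("ramp", 30, 45, 0.04, sampling_dt=DT)
        truth = SyntheticTruth(T_t=tt_for_dose(dose), stroke_area=0.8, width_w=0.7,
                               seed=dose)
        trace, _ = synthetic.make_contraction_trace(profile, truth, noise_sd=0.005)
        series = synthetic.render_contraction_frames(
            trace, pixel_size=0.02, include_reference_object=True, seed=dose)
        d = os.path.join(OUT, f"ramp_{dose}kGy")
        imaging_io.save_frames(os.path.join(d, "frames"), series,
                               temps=profile.temperature_at(series.times),
                               meta_extra={"truth": dataclasses.asdict(truth),
                                           "dose_kGy": dose})
        imaging_io.write_temperature_log(os.path.join(d, "profile.csv"), profile)
        manifest[f"ramp_{dose}kGy"] = {"T_t_truth": truth.T_t, "frames": len(series)}
        print(f"dose {dose} kGy: truth T_t = {truth.T_t:.2f} degC, "
              f"{len(series)} frames rendered")

    profile = synthetic.make_temperature_profile("cyclic", 28, 42, 0.04, n_cycles=20,
                                                 dwell=300, sampling_dt=2.0)
    truth = SyntheticTruth(T_t=40.0, stroke_area=0.8, width_w=0.7,
                           loss_per_cycle=0.0034, seed=1)
    trace, _ = synthetic.make_contraction_trace(profile, truth, noise_sd=0.002)
    d = os.path.join(OUT, "cyclic_60kGy")
    os.makedirs(d, exist_ok=True)
    imaging_io.write_temperature_log(os.path.join(d, "profile.csv"), profile)
    area_tracking.trace_to_csv(os.path.join(d, "trace.csv"), trace)
    with open(os.path.join(d, "truth.json"), "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
    manifest["cyclic_60kGy"] = {"loss_truth": truth.loss_per_cycle,
                                "samples": len(trace)}
    print(f"cyclic trace: {len(trace)} samples, truth loss "
          f"{100 * truth.loss_per_cycle:.2f} % per cycle")

    with open(os.path.join(OUT, "datasets.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
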