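"""Simulate the desk-scale synthetic cohort and store it.

Generates the two-group cohort (10 subjects/group x 40 trials on a
2,000-vertex sphere by default; override with --config) with a planted
50% attenuation of the parietal 325 ms evoked component in the patient
group, attaches a correlated clinical score, and writes the HDF5 cohort
container plus the metadata CSV under results/cohort/.

The stored trial data are the raw simulated sources; preprocessing and
volumization happen in 02_build_volumes.py.
"""

import argparse
from pathlib import Path

from cortexcam import io, synthdata
from cortexcam.orchestrate import (
    PipelineConfig,
    build_cohort,
    config_hash,
    load_config,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default=None)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/cohort")
    args = ap.parse_args()

    config = load_config(args.config) if args.config else PipelineConfig(seed=args.seed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    surface, espec, cohort, _ = build_cohort(config)
    trial_iter = (ts for _, ts in synthdata.iter_subject_trials(surface, espec, cohort))
    io.save_cohort(
        str(out / "cohort.h5"), surface, cohort, trial_iter,
        csv_path=str(out / "cohort.csv"),
        meta={"seed": config.seed, "config_hash": config_hash(config)},
    )
    n_pat = (cohort.group == "patient").sum()
    print(f"wrote {out/'cohort.h5'}: {len(cohort)} subjects "
          f"({n_pat} patients), {cohort.n_trials.iloc[0]} trials each; "
          f"planted delta={espec.delta} in region {espec.roi_region_id} "
          f"at {espec.window_ms} ms")


if __name__ == "__main__":
    main()
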