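"""Preprocess the stored cohort and build classifier input volumes.

Applies the trial preprocessing (zero-phase 30 Hz lowpass, -200..0 ms
baseline correction), projects each trial through the Mollweide map onto
the pixel grid, averages 50 ms bins over 0-800 ms and z-scores each
frame, then writes the stacked volumes to results/cohort/volumes.h5.
"""

import argparse
from pathlib import Path

from cortexcam import cnn, io, synthdata, volumize
from cortexcam.orchestrate import PipelineConfig, config_hash, load_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--config", default=None)
    ap.add_argument("--cohort", default="results/cohort")
    args = ap.parse_args()

    config = load_config(args.config) if args.config else PipelineConfig()
    src = Path(args.cohort) / "cohort.h5"
    surface = io.load_surface(str(src))
    mmap = volumize.make_mollweide_map(surface, config.volumize.grid_size)

    parts = []
    for ts in io.iter_saved_subjects(str(src)):
        pre = synthdata.preprocess_trial(ts.data, ts.fs_hz, ts.t_start_ms)
        ts_pre = synthdata.SourceTrialSet(
            pre, ts.t_start_ms, ts.t_end_ms, ts.fs_hz, ts.subject_id, ts.group
        )
        parts.append(
            cnn.stack_volumes(
                volumize.volumize_trialset(ts_pre, mmap, config.volumize.mode)
            )
        )
        print(f"  {ts.subject_id}: {ts.data.shape[0]} volumes")
    ds = cnn.VolumeDataset.concat(parts)
    dst = Path(args.cohort) / "volumes.h5"
    io.save_volumes(str(dst), ds, meta={"config_hash": config_hash(config)})
    print(f"wrote {dst}: {len(ds)} volumes of shape {ds.X.shape[1:-1]}")


if __name__ == "__main__":
    main()
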