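#!/usr/bin/env python
"""Simulate the study conditions: a wild-type two-pacemaker atrium (SAR
dominant, AVC latent), an SAR-silenced heart (AVC escape rhythm), and a
morphant-style heart (slow, pausing SAR).

Writes ground-truth event logs and summaries under results/simulation/;
the raw 16-bit split-frame movies go to scratch/ (they are regenerated
on demand by the downstream drivers and are not part of the tracked
outputs).
"""

import json
from pathlib import Path

import numpy as np

from pacemap import io, simulate as sim

RESULTS = Path("results/simulation")
SCRATCH = Path("scratch/movies")
SEED = 1

CONDITIONS = {
    "wildtype": dict(sar_period_ms=60000.0 / 176.0, avc_period_ms=600.0),
    "sar_silenced": dict(sar_enabled=False, avc_period_ms=60000.0 / 80.2),
    "morphant_like": dict(sar_period_ms=60000.0 / 80.2, avc_period_ms=2500.0,
                          sar_pause_probability=0.2,
                          sar_pause_duration_ms=900.0, jitter_sd_ms=15.0),
}


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, kw in CONDITIONS.items():
        cfg = sim.two_pacemaker_config(grid_shape=(64, 64), duration_s=15.0,
                                       **kw)
        movie, gt = sim.simulate_fret_movie(cfg, seed=SEED)
        io.write_movie_tiff(movie, SCRATCH / f"{name}.tif")
        # per-pixel truth tables are bulky; keep them in scratch and only
        # the event log + config in results
        io.write_ground_truth(gt, SCRATCH / f"{name}_truth")
        (RESULTS / name).mkdir(parents=True, exist_ok=True)
        io.write_json(
            {"firing_events": [{"time_ms": t, "pacemaker": pm,
                                "origin": list(site)}
                               for t, pm, site in gt.firing_events],
             "realized_beat_times_ms": gt.realized_beat_times.tolist()},
            RESULTS / name / "events.json")
        io.config_to_yaml(cfg, RESULTS / name / "config.yaml")
        intervals = np.diff(gt.realized_beat_times)
        summary[name] = {
            "n_beats": len(gt.realized_beat_times),
            "origin_sites": sorted({tuple(site)
                                    for _, _, site in gt.firing_events}),
            "mean_interval_ms": float(intervals.mean()) if intervals.size else None,
            "rate_bpm": 60000.0 / float(intervals.mean()) if intervals.size else None,
        }
        print(f"{name}: {summary[name]['n_beats']} beats, "
              f"{summary[name]['rate_bpm']:.1f} bpm, "
              f"origins {summary[name]['origin_sites']}")
    io.write_json(summary, RESULTS / "summary.json")
    print("Wild-type beats all originate at the SAR pole (overdrive "
          "suppression); silencing the SAR hands the rhythm to the AVC "
          "at its slower escape rate.")


if __name__ == "__main__":
    main()
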