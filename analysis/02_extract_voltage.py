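#!/usr/bin/env python
"""Run the ratiometric voltage-extraction chain (split → register →
acceptor/donor ratio → 3×3 adaptive Wiener filter → per-pixel min–max
normalization) on the simulated wild-type movie and record the
processing provenance and the mask-mean voltage trace."""

import warnings
from pathlib import Path

import numpy as np

from pacemap import activation, extract, io, simulate as sim

RESULTS = Path("results/extraction")
SEED = 1


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = sim.two_pacemaker_config(grid_shape=(64, 64), duration_s=15.0,
                                   sar_period_ms=60000.0 / 176.0)
    movie, _ = sim.simulate_fret_movie(cfg, seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm, mask = extract.extract_voltage(
            movie, mask=np.ones(cfg.grid_shape, dtype=bool))
    trace = activation.spatial_mean_trace(norm, mask)
    io.write_stack_tiff(norm.frames, Path("scratch") / "wildtype_norm.tif")
    np.savetxt(RESULTS / "mask_mean_trace.csv", trace, header="normalized_ratio",
               comments="")
    io.write_json({"provenance": norm.provenance,
                   "mask_pixels": int(mask.values.sum()),
                   "trace_range": [float(trace.min()), float(trace.max())]},
                  RESULTS / "provenance.json")
    print(f"Extracted {norm.frames.shape[0]} frames; mask of "
          f"{int(mask.values.sum())} px; steps: "
          f"{[p['step'] for p in norm.provenance]}")


if __name__ == "__main__":
    main()
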