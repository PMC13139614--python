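#!/usr/bin/env python
"""Acquisition-timing arithmetic of the repeated-raster protocol.

Enumerates the interleaved block-raster schedule of the reference protocol
(8 blocks x 16 B-scan locations x 32 repeats at a 204.8 ms revisit period),
verifies the printed timing quantities, and exports the frame schedule and
the study timepoint grids.

Finding: the schedule comprises 4096 frames; one block's repeated raster
spans 6.55 s and a full volume 52.4 s; the OCDS delay window of lags 1-6
runs 204.8-1228.8 ms; imaging 100 h at 4 h gives 26 timepoints and at
30 min gives 201 volumes per sample.
"""

from pathlib import Path

import pandas as pd

from spheroid_doct.scan_protocol import (
    ScanProtocol,
    block_duration,
    build_schedule,
    delay_grid,
    study_timepoints,
    volume_duration,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "protocol"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    p = ScanProtocol()
    print(f"frames per volume      : {p.frames_per_volume}")
    print(f"block duration         : {block_duration(p):.4f} s (prints as {block_duration(p):.2f})")
    print(f"volume acquisition     : {volume_duration(p):.4f} s (prints as {volume_duration(p):.1f})")
    g = delay_grid(p, max_lag=6)
    print(f"OCDS delay grid        : {g.delays_ms[0]:.1f} .. {g.delays_ms[-1]:.1f} ms ({len(g.delays_ms)} lags)")

    sched = build_schedule(p)
    df = pd.DataFrame(sched.to_records())
    df.to_csv(OUT / "frame_schedule.csv", index=False)
    print(f"schedule exported      : {len(df)} rows -> {OUT / 'frame_schedule.csv'}")

    for label, interval in (("study1_4hr", 4.0), ("study2_30min", 0.5)):
        s = study_timepoints(100.0, interval)
        pd.Series(s.timepoints_hr, name="time_hr").to_csv(OUT / f"{label}_timepoints.csv", index=False)
        print(f"{label:<22} : {s.n_timepoints} timepoints")


if __name__ == "__main__":
    main()
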