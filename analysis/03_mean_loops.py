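#!/usr/bin/env python
"""Build the canonical 40-point mean PV loops before and after intervention.

Each recording's steady-state beats are canonicalized (4 limbs x 10
arc-length-spaced points) and averaged pointwise; patient mean loops are
then averaged into the cohort mean loop per phase.  The post loop is
expected to sit right of and slightly above the pre loop — larger
end-systolic volume with higher end-diastolic pressure.

Run:  python analysis/03_mean_loops.py
Reads: results/cohort/   Writes: results/loops/mean_{pre,post}.csv (+ .png)
"""

import argparse
import json
from pathlib import Path

from pvloop import read_recording
from pvloop.loopdigitize import mean_loop, mean_loop_of_recording, write_canonical_loop

ap = argparse.ArgumentParser()
ap.add_argument("--in-dir", type=Path, default=Path("results/cohort"))
ap.add_argument("--out-dir", type=Path, default=Path("results/loops"))
args = ap.parse_args()

manifest = json.loads((args.in_dir / "manifest.json").read_text())
args.out_dir.mkdir(parents=True, exist_ok=True)

loops = {}
for phase in ("pre", "post"):
    per_patient = [
        mean_loop_of_recording(read_recording(args.in_dir / f"{m['patient_id']}_{phase}.csv"))
        for m in manifest
    ]
    loops[phase] = mean_loop(per_patient)
    write_canonical_loop(loops[phase], args.out_dir / f"mean_{phase}.csv")

pre, post = loops["pre"], loops["post"]
print(f"mean loop pre : EDV {pre.edv:6.1f} ml  EDP {pre.edp:5.1f} mmHg  area {pre.area:7.0f} mmHg.ml")
print(f"mean loop post: EDV {post.edv:6.1f} ml  EDP {post.edp:5.1f} mmHg  area {post.area:7.0f} mmHg.ml")
dv = post.volume.mean() - pre.volume.mean()
print(f"post loop shifted {dv:+.1f} ml in mean volume, {post.edp - pre.edp:+.1f} mmHg in EDP "
      f"({'right/up' if dv > 0 and post.edp > pre.edp else 'unexpected direction'})")

try:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(figsize=(5, 4))
    for phase, style in (("pre", "-o"), ("post", "-s")):
        lo = loops[phase]
        v = list(lo.volume) + [lo.volume[0]]
        p = list(lo.pressure) + [lo.pressure[0]]
        axis.plot(v, p, style, ms=3, label=phase)
    axis.set_xlabel("LV volume (ml)")
    axis.set_ylabel("LV pressure (mmHg)")
    axis.legend()
    fig.tight_layout()
    fig.savefig(args.out_dir / "mean_loops.png", dpi=120)
    print(f"figure: {args.out_dir}/mean_loops.png")
except ImportError:
    pass
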