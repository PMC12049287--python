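"""A miniature two-group phantom study in the shape of the clinical tables.

Group "0deg" holds wedge-shaped resections (what a 0-degree cut produces
on a varus joint line), group "3deg" rectangular ones. Each specimen runs
through the full pipeline; the cohort table reports per-group mean +/- sd
and a Welch t-test per metric. Three specimens per group keep this
example quick — expect noisier p-values than a full-size cohort.
"""

import tempfile
from pathlib import Path

from resectfit import (PhantomSpec, PipelineConfig, make_cohort, run_cohort,
                       write_mesh, write_volume)

spec_wedge = PhantomSpec(wedge_angle_deg=3.0, sclerotic_fraction=0.05)
spec_rect = PhantomSpec(wedge_angle_deg=0.0, sclerotic_fraction=0.05)
cohort = make_cohort(3, spec_wedge, spec_rect, seed=7)

with tempfile.TemporaryDirectory() as td:
    td = Path(td)
    rows = ["id,group,volume_path,implant_path"]
    for item in cohort:
        d = td / item["id"]
        d.mkdir()
        write_volume(item["volume"], d / "vol.nii.gz")
        write_mesh(item["implant"], d / "tray.stl")
        rows.append(f"{item['id']},{item['group']},"
                    f"{d / 'vol.nii.gz'},{d / 'tray.stl'}")
    (td / "manifest.csv").write_text("\n".join(rows) + "\n")

    config = PipelineConfig(render=False)       # skip PNGs for speed
    table, results = run_cohort(td / "manifest.csv", config, td / "out")

cols = ["0deg_mean", "0deg_sd", "3deg_mean", "3deg_sd", "p"]
print(table[cols].round(3).to_string())
print("\nquotient < 1 in the wedge group = medial overstuffing; "
      "the rectangular group sits near 1 or is undefined (no surplus).")
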