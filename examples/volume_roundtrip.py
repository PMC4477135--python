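"""Render synthetic NIfTI volumes and recover the node series.

Paints one subject's node series into 3 mm spheres on a 2 mm MNI grid
with background noise, writes the volume to disk, extracts it back with
the full preprocessing chain, and reports per-node recovery.
"""

import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from triplenet import (
    SimulationConfig,
    default_atlas,
    extract_cohort,
    preprocess_series,
    render_synthetic_volume,
    simulate_cohort,
)

atlas = default_atlas()
config = SimulationConfig(n_per_group=2, n_timepoints=240, seed=1)
subject = simulate_cohort(atlas, config)[0]

data, affine = render_synthetic_volume(subject, atlas, background_noise_sd=0.5, seed=3)
print(f"rendered volume shape {data.shape} "
      f"({np.prod(data.shape[:3])} voxels x {data.shape[3]} time points)")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((2.0, 2.0, 2.0, config.tr_seconds))
    nib.save(img, str(tmp / "subj.nii"))
    pd.DataFrame(
        [{"subject_id": subject.subject_id, "group": subject.group, "file": "subj.nii"}]
    ).to_csv(tmp / "manifest.tsv", sep="\t", index=False)

    recovered = extract_cohort(tmp / "manifest.tsv", atlas, tr_seconds=2.0, discard=10)[0]

expected = preprocess_series(subject.data[:, 10:], 2.0)
for i, name in enumerate(atlas.names):
    r = np.corrcoef(recovered.data[i], expected[i])[0, 1]
    print(f"  node {name:>7}: recovered-vs-input correlation {r:.6f}")
print("(correlations near 1: sphere averaging recovers each series; the "
      "10-volume discard, detrend and 0.01-0.08 Hz band-pass are applied to both)")
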