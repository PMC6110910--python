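"""Simulate a gantry-tilted, variable-thickness CT acquisition of a head
phantom and recover the geometry through DICOM ingestion.

The phantom writer encodes tilt the way scanners do (axial orientation
cosines, per-slice positions advancing along the tilted normal), so the
naive slice stack is sheared; ingestion undoes the shear from the
position tags and resamples the mixed 5/2 mm gaps to a uniform grid.
"""

import tempfile

import numpy as np

from edemascan.core import dice, resample_like
from edemascan.ingest import compute_slice_spacing, ingest_series, load_dicom_dir
from edemascan.phantom import PhantomSpec, make_head_phantom, write_dicom_series
from scipy import ndimage

spec = PhantomSpec(seed=8, noise_sd=0.0)
vol, truth = make_head_phantom(spec)

with tempfile.TemporaryDirectory() as d:
    write_dicom_series(vol, d, tilt_deg=20.0, thickness_profile=[5.0] * 19 + [2.0] * 18)
    series = load_dicom_dir(d)[0]
    gaps, uniform = compute_slice_spacing(series)
    rec = ingest_series(series)

skull = rec.data > 500
cranial = np.zeros_like(skull)
for k in range(skull.shape[2]):
    cranial[:, :, k] = ndimage.binary_fill_holes(skull[:, :, k])
cranial &= ~skull
truth_on_grid = resample_like(truth["cranial"], rec, order=0)

print(f"emitted slice gaps (mm): {sorted(set(round(g, 2) for g in gaps))}, uniform={uniform}")
print(f"reconstructed grid: {rec.shape} voxels at {tuple(round(s, 2) for s in rec.spacing)} mm")
print(f"cranial Dice vs ground truth: {dice(cranial, truth_on_grid.data):.4f}")
v = cranial.sum() * np.prod(rec.spacing) / 1000.0
print(f"cranial volume: {v:.1f} ml (truth {truth['cranial'].volume_ml():.1f} ml)")
# A Dice near 1 and a sub-percent volume error mean the tilt shear and the
# variable slice gaps were fully resolved from the position tags alone.
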