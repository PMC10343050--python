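"""Generate a tiny synthetic phantom dataset and inspect one case.

Writes four BraTS-layout case directories (four modalities + labels as
NIfTI) and prints the compartment volumes of the first case. The region
counts demonstrate the nesting ET ⊂ TC ⊂ WT that the evaluation relies on.
"""

import tempfile
from pathlib import Path

import numpy as np

from hdcseg import PhantomSpec, labels_to_regions, load_case, make_dataset

out = Path(tempfile.mkdtemp()) / "phantoms"
spec = PhantomSpec(shape=(48, 48, 48), n_cases=4, seed=0)
dirs = make_dataset(spec, out)
print(f"wrote {len(dirs)} cases under {out}")

vol, lab = load_case(dirs[0])
print(f"volume shape {vol.data.shape}, labels {sorted(int(v) for v in np.unique(lab.labels))}")
regions = labels_to_regions(lab)
for name, mask in regions:
    print(f"  {name.upper():3s}: {int(mask.sum()):6d} voxels")
# WT >= TC >= ET because the evaluation regions are nested unions of labels
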