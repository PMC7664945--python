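"""Generate a synthetic dataset with missing values and reload it from CSV.

The arrhythmia-shaped preset writes "?" for missing cells, mirroring the
UCI convention; the loader median-imputes and min-max scales to [0, 1].
"""

import tempfile
from pathlib import Path

import numpy as np

from saepso import get_preset, load_tabular, make_classification_dataset
from saepso.synthetic import write_dataset_csv

spec = get_preset("arrhythmia-like", seed=0)  # 450 x 279, 16 classes, 5% missing
x, y = make_classification_dataset(spec)
print(f"generated {x.shape[0]} x {x.shape[1]} with "
      f"{np.isnan(x).mean():.1%} missing entries, "
      f"{y.n_classes} classes (largest: {np.bincount(y.labels).max()} samples)")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "arrhythmia_like.csv"
    write_dataset_csv(x, y, path)
    loaded, labels = load_tabular(path)

print(f"reloaded: {loaded.shape}, feature range "
      f"[{loaded.min():.2f}, {loaded.max():.2f}], no missing entries: "
      f"{not np.any(np.isnan(loaded))}")
print(f"labels preserved exactly: {np.array_equal(labels.labels, y.labels)}")
# after imputation and scaling every feature lies in [0, 1], which the
# sigmoid auto-encoder requires for its reconstruction targets
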