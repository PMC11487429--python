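"""List-mode coincidence file I/O (CSV and HDF5).

Schema v1 columns: crystal1, crystal2, group1, group2, event1, event2,
dt_ns, time_ns, klass (0 true / 1 scattered / 2 random).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .coincidence import COINCIDENCE_DTYPE

SCHEMA_VERSION = 1
_COLUMNS = [name for name in COINCIDENCE_DTYPE.names]


def save_listmode(coincidences: np.ndarray, path) -> None:
    path = Path(path)
    df = pd.DataFrame({c: coincidences[c] for c in _COLUMNS})
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            for c in _COLUMNS:
                f.create_dataset(c, data=coincidences[c])
    else:
        df.to_csv(path, index=False)


def load_listmode(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            n = len(f["crystal1"])
            out = np.empty(n, dtype=COINCIDENCE_DTYPE)
            for c in _COLUMNS:
                out[c] = f[c][:]
            return out
    df = pd.read_csv(path)
    out = np.empty(len(df), dtype=COINCIDENCE_DTYPE)
    for c in _COLUMNS:
        out[c] = df[c].to_numpy()
    return out
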