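"""Reading and writing the package's tabular formats.

Omics matrices are TSV/CSV files with the sample ID in the first column and a
header row of feature IDs; missing entries are empty fields or "NA".  Label
files are two columns: sample ID and integer cluster label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import OmicsView

_NA = ["", "NA", "NaN", "nan"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_view(path: str | Path, name: str | None = None) -> OmicsView:
    """Load one omics matrix (samples x features) from TSV/CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, na_values=_NA,
                     keep_default_na=True)
    return OmicsView(
        name=name or path.stem,
        samples=[str(s) for s in df.index],
        features=[str(f) for f in df.columns],
        X=df.to_numpy(dtype=np.float64),
    )


def write_view(view: OmicsView, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(view.X, index=view.samples, columns=view.features)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep(path), na_rep="NA")


def read_labels(path: str | Path) -> pd.Series:
    """Two-column sample-ID / integer-label file -> Series indexed by ID."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected exactly two columns (sample ID, label)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=np.int64),
                  index=df.iloc[:, 0].astype(str))
    s.index.name = "sample_id"
    return s


def write_labels(samples: list[str], labels: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": samples, "cluster": np.asarray(labels, dtype=int)}) \
        .to_csv(path, sep=_sep(path), index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
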