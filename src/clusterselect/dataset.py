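"""The universal input container: a sample x feature matrix with optional labels and axis.

Spectroscopy datasets carry a wavenumber axis (cm^-1, one coordinate per
feature); multivariate datasets do not. Class labels, when known, are integer
codes; the reserved value :data:`OUTLIER_LABEL` marks points that are outliers
by construction (synthetic data) or by annotation, and is never counted as a
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Reserved integer label for outlier/noise points in ground-truth labellings.
OUTLIER_LABEL = -1


@dataclass
class DatasetMatrix:
    """An ``n_samples x n_features`` numeric matrix with optional metadata.

    Parameters
    ----------
    values:
        Real matrix, samples as rows. No missing values are allowed.
    labels:
        Optional integer class labels, one per sample. ``OUTLIER_LABEL`` (-1)
        marks outliers.
    axis:
        Optional feature coordinates (e.g. wavenumbers in cm^-1), one per
        feature. Present for spectra, absent for plain multivariate data.
    name:
        Free-text identifier used in reports.
    """

    values: np.ndarray
    labels: np.ndarray | None = None
    axis: np.ndarray | None = None
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x features matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.n_samples,):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"{self.n_samples} samples"
                )
        if self.axis is not None:
            self.axis = np.asarray(self.axis, dtype=float)
            if self.axis.shape != (self.n_features,):
                raise ValueError("axis length does not match feature count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int | None:
        """Number of non-outlier classes, or None when unlabelled."""
        if self.labels is None:
            return None
        return len(set(self.labels[self.labels != OUTLIER_LABEL]))

    def replace(self, **kwargs) -> "DatasetMatrix":
        """Return a copy with some fields replaced."""
        out = {
            "values": self.values,
            "labels": self.labels,
            "axis": self.axis,
            "name": self.name,
        }
        out.update(kwargs)
        return DatasetMatrix(**out)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write as CSV: feature columns (headed by wavenumbers if an axis is
        present, else ``f0..f{p-1}``) plus a trailing ``label`` column when
        labelled."""
        if self.axis is not None:
            cols = [f"{w:g}" for w in self.axis]
        else:
            cols = [f"f{j}" for j in range(self.n_features)]
        df = pd.DataFrame(self.values, columns=cols)
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path,
        label_column: str | None = "label",
        name: str | None = None,
    ) -> "DatasetMatrix":
        """Read a CSV matrix written by :meth:`to_csv` (or any samples-as-rows
        CSV). If every feature column name parses as a number, it is taken as
        the wavenumber axis."""
        df = pd.read_csv(path)
        labels = None
        if label_column is not None and label_column in df.columns:
            labels = df.pop(label_column).to_numpy(dtype=int)
        if df.isna().any().any():
            raise ValueError(f"{path}: missing values are not supported")
        axis = None
        try:
            axis = np.array([float(c) for c in df.columns])
        except ValueError:
            pass
        return cls(
            values=df.to_numpy(dtype=float),
            labels=labels,
            axis=axis,
            name=name or str(path),
        )
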