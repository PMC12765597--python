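"""Labelled symmetric distance matrices.

Every distance used in the analysis (genetic F_ST, geographic, morphological,
acoustic) is carried as a :class:`DistanceMatrix` so that Mantel tests can
check label agreement instead of trusting positional order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix"]


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal matrix over ordered labels.

    Parameters
    ----------
    labels
        Ordered site (or group) identifiers.
    values
        Square symmetric array, ``values[i, j]`` = distance between
        ``labels[i]`` and ``labels[j]``.
    metric_name
        Free-text name of the metric ("fst", "geographic_km", ...).
    allow_negative
        Weir-Cockerham theta can legitimately be slightly negative; such
        matrices set this flag instead of failing validation.
    """

    labels: list[str]
    values: np.ndarray
    metric_name: str = "distance"
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        # enforce exact symmetry and zero diagonal
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)
        if not self.allow_negative and np.nanmin(self.values) < -1e-12:
            raise ValueError(f"negative entries in {self.metric_name!r} matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal entries (i < j), row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns permuted into ``labels`` order."""
        idx = [self.labels.index(str(l)) for l in labels]
        return DistanceMatrix(
            [self.labels[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.metric_name,
            self.allow_negative,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric_name: str = "distance",
                   allow_negative: bool = False) -> "DistanceMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float),
                   metric_name, allow_negative)

    @classmethod
    def from_csv(cls, path, metric_name: str = "distance",
                 allow_negative: bool = False) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls.from_frame(df, metric_name, allow_negative)

    def same_labels(self, other: "DistanceMatrix") -> bool:
        return self.labels == other.labels
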