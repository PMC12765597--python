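"""Geographic and per-feature colony distance matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

from .distmat import DistanceMatrix
from .sites import validate_sites

__all__ = ["EARTH_RADIUS_KM", "geographic_distance_matrix", "colony_feature_distance"]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def geographic_distance_matrix(sites: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances between sites, in km."""
    validate_sites(sites)
    coords = np.radians(sites[["lat_deg", "lon_deg"]].to_numpy(dtype=float))
    d = haversine_distances(coords) * EARTH_RADIUS_KM
    return DistanceMatrix(list(sites["site_id"]), d, "geographic_km")


def colony_feature_distance(table: pd.DataFrame, feature: str,
                            colony_col: str = "colony",
                            labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise |mean_i - mean_j| of one feature's colony means.

    Missing values are ignored when averaging; a colony with no data for
    the feature is an error. ``labels`` fixes the output site order
    (defaults to first appearance order).
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    if labels is None:
        labels = list(pd.unique(table[colony_col]))
    means = []
    for lab in labels:
        vals = table.loc[table[colony_col] == lab, feature].dropna()
        if len(vals) == 0:
            raise ValueError(f"colony {lab!r} has no data for feature {feature!r}")
        means.append(float(vals.mean()))
    m = np.asarray(means)
    d = np.abs(m[:, None] - m[None, :])
    return DistanceMatrix([str(l) for l in labels], d, f"mean_{feature}")
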