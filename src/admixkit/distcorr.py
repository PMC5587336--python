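"""Geographic and linguistic distance matrices and the Mantel test.

The Mantel statistic is the Pearson correlation of the upper-triangle
entries of two distance matrices over the same labels; significance comes
from jointly permuting rows and columns of the second matrix.  The test is
one-sided (positive correlation), matching the usual "genetic distance
increases with geographic/linguistic distance" hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

DEFAULT_LEVEL_VALUES = (4.0, 3.0, 2.0, 1.0)  # differ at root, family, subgroup, language


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def geographic_distance_matrix(coords: dict[str, tuple[float, float]]) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between population midpoints.

    ``coords`` maps population -> (lat, lon) in degrees.
    """
    labels = list(coords)
    missing = [p for p, c in coords.items() if c is None or any(v is None for v in c)]
    if missing:
        raise ValueError(f"missing coordinates for populations: {missing}")
    lat = np.radians([coords[p][0] for p in labels])
    lon = np.radians([coords[p][1] for p in labels])
    if np.any(np.abs(np.degrees(lat)) > 90) or np.any(np.abs(np.degrees(lon)) > 180):
        raise ValueError("coordinates out of range")
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d, "geographic")


def linguistic_distance_matrix(
    classification: dict[str, list[str]],
    level_values: tuple[float, ...] = DEFAULT_LEVEL_VALUES,
) -> DistanceMatrix:
    """Distances from a rooted linguistic classification.

    ``classification`` maps population -> path of increasingly specific
    labels (e.g. [family, subgroup, language]).  The distance between two
    populations is the value assigned to the level of their lowest common
    ancestor: identical paths score 0; paths diverging at depth k score
    ``level_values[k]`` (default 4 at the root down to 1 at the language
    level).
    """
    labels = list(classification)
    unplaced = [p for p, path in classification.items() if not path]
    if unplaced:
        raise ValueError(f"populations without a classification path: {unplaced}")
    depth = max(len(p) for p in classification.values())
    if len(level_values) < depth:
        raise ValueError("level_values shorter than classification depth")
    k = len(labels)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = classification[labels[i]], classification[labels[j]]
            div = None
            for lvl in range(max(len(a), len(b))):
                va = a[lvl] if lvl < len(a) else None
                vb = b[lvl] if lvl < len(b) else None
                if va != vb:
                    div = lvl
                    break
            m[i, j] = m[j, i] = 0.0 if div is None else level_values[div]
    return DistanceMatrix(labels, m, "linguistic")


def mantel_test(
    X: DistanceMatrix,
    Y: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    method: str = "pearson",
) -> tuple[float, float]:
    """Mantel correlation of two distance matrices with permutation p-value.

    r is the Pearson (or Spearman) correlation of upper-triangle entries;
    p = (1 + #{permuted r >= observed}) / (n_perm + 1), one-sided greater.
    Rows and columns of Y are permuted jointly.
    """
    if X.labels != Y.labels:
        raise ValueError("distance matrices must share labels and order")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(X.labels)
    iu = np.triu_indices(k, 1)
    x = X.values[iu]

    def flat(mat):
        v = mat[iu]
        if method == "spearman":
            v = pd.Series(v).rank().to_numpy()
        return v

    if method == "spearman":
        x = pd.Series(x).rank().to_numpy()
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    y = flat(Y.values)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = flat(Y.values[np.ix_(perm, perm)])
        if np.corrcoef(x, yp)[0, 1] >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, float(p)
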