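"""Cortical parcel schemes: parcel ids, network labels, hemispheres, centroids.

A :class:`ParcelScheme` describes a whole-cortex parcellation in which every
parcel carries one of the seven canonical functional-network labels
(visual, somatomotor, dorsal attention, ventral attention, limbic,
frontoparietal control, default mode) plus a hemisphere label and a
unit-sphere centroid.  The centroids exist so that spatially constrained
("spin") null models can rotate maps on the sphere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical Yeo-7 network labels, in fixed order.
YEO7_NETWORKS: tuple[str, ...] = ("VIS", "SOM", "DAN", "VAN", "LIM", "FPC", "DMN")

#: Parcel counts per Yeo-7 network in the Schaefer 400-parcel scheme.
SCHAEFER400_SIZES: tuple[int, ...] = (61, 77, 46, 47, 26, 52, 91)

_SCHEME_COLUMNS = ("parcel_id", "network", "hemisphere", "x", "y", "z")


class SchemeError(ValueError):
    """Raised when a parcel scheme violates its structural invariants."""


@dataclass
class ParcelScheme:
    """Parcel table with network / hemisphere labels and spherical centroids.

    Parameters
    ----------
    table
        DataFrame with columns ``parcel_id, network, hemisphere, x, y, z``.
        Parcel ids must be unique, every network label must come from the
        Yeo-7 set (and all seven must be present), hemispheres are ``L``/``R``
        and centroids must have unit norm to within 1e-6.
    """

    table: pd.DataFrame
    _index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        missing = [c for c in _SCHEME_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemeError(f"parcel table missing columns: {missing}")
        tab = self.table.reset_index(drop=True)
        if tab["parcel_id"].duplicated().any():
            dup = tab.loc[tab["parcel_id"].duplicated(), "parcel_id"].tolist()
            raise SchemeError(f"duplicate parcel ids: {dup[:5]}")
        bad_net = set(tab["network"]) - set(YEO7_NETWORKS)
        if bad_net:
            raise SchemeError(f"unknown network labels: {sorted(bad_net)}")
        absent = set(YEO7_NETWORKS) - set(tab["network"])
        if absent:
            raise SchemeError(f"networks with no parcels: {sorted(absent)}")
        if not set(tab["hemisphere"]) <= {"L", "R"}:
            raise SchemeError("hemisphere labels must be 'L' or 'R'")
        xyz = tab[["x", "y", "z"]].to_numpy(float)
        norms = np.linalg.norm(xyz, axis=1)
        off = np.abs(norms - 1.0) > 1e-6
        if off.any():
            raise SchemeError(
                f"{int(off.sum())} centroids are not unit-norm "
                f"(first: parcel {tab.loc[np.argmax(off), 'parcel_id']})"
            )
        object.__setattr__(self, "table", tab)
        object.__setattr__(
            self,
            "_index",
            {n: np.flatnonzero((tab["network"] == n).to_numpy()) for n in YEO7_NETWORKS},
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def parcel_ids(self) -> list:
        return self.table["parcel_id"].tolist()

    @property
    def networks(self) -> tuple[str, ...]:
        return YEO7_NETWORKS

    @property
    def network_labels(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    def indices(self, network: str) -> np.ndarray:
        """Row indices of the parcels belonging to ``network``."""
        if network not in self._index:
            raise SchemeError(f"unknown network label: {network!r}")
        return self._index[network]

    def centroids(self) -> np.ndarray:
        """(P, 3) array of unit-sphere centroid coordinates."""
        return self.table[["x", "y", "z"]].to_numpy(float)

    def hemisphere_indices(self, hemisphere: str) -> np.ndarray:
        if hemisphere not in ("L", "R"):
            raise SchemeError(f"unknown hemisphere: {hemisphere!r}")
        return np.flatnonzero((self.table["hemisphere"] == hemisphere).to_numpy())

    @staticmethod
    def network_pairs() -> list[tuple[str, str]]:
        """The 21 unordered network pairs, in canonical Yeo order."""
        return list(itertools.combinations(YEO7_NETWORKS, 2))

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelScheme":
        return cls(pd.read_csv(path, sep="\t"))

    def __eq__(self, other) -> bool:
        return isinstance(other, ParcelScheme) and self.table.equals(other.table)
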