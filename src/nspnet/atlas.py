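"""Region-to-system atlas handling.

Regions are grouped into seven canonical resting-state functional systems
(visual, motor, dorsal attention, salient attention, limbic, control,
default-mode). The atlas is the lookup used everywhere a regional quantity
is aggregated to the system level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical seven-system vocabulary.
SYSTEMS: tuple[str, ...] = ("VIS", "MOT", "DOR", "SAL", "LIM", "CON", "DMN")


@dataclass(frozen=True)
class AtlasMap:
    """Mapping from region ids to functional-system labels.

    Parameters
    ----------
    region_ids
        Ordered region identifiers, one per parcel.
    systems
        System label per region, same order; labels must come from the
        seven-system vocabulary (or a caller-supplied vocabulary when
        fewer systems are simulated).
    """

    region_ids: tuple[str, ...]
    systems: tuple[str, ...]
    vocabulary: tuple[str, ...] = field(default=SYSTEMS)

    def __post_init__(self) -> None:
        if len(self.region_ids) != len(self.systems):
            raise ValueError("region_ids and systems must have equal length")
        unknown = sorted(set(self.systems) - set(self.vocabulary))
        if unknown:
            raise ValueError(f"system labels outside vocabulary: {unknown}")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def system_names(self) -> tuple[str, ...]:
        """Vocabulary entries that actually occur, in vocabulary order."""
        present = set(self.systems)
        return tuple(s for s in self.vocabulary if s in present)

    def system_of(self, region_id: str) -> str:
        try:
            return self.systems[self.region_ids.index(region_id)]
        except ValueError:
            raise KeyError(f"region {region_id!r} not in atlas") from None

    def indices(self, system: str) -> np.ndarray:
        """Integer positions of the regions belonging to ``system``."""
        return np.flatnonzero(np.asarray(self.systems) == system)

    def labels_array(self) -> np.ndarray:
        return np.asarray(self.systems)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": self.region_ids, "system": self.systems})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AtlasMap":
        if not {"region", "system"} <= set(df.columns):
            raise ValueError("atlas table needs 'region' and 'system' columns")
        return cls(tuple(df["region"].astype(str)), tuple(df["system"].astype(str)))

    @classmethod
    def evenly_split(
        cls,
        n_regions: int,
        system_sizes: tuple[int, ...] | None = None,
        vocabulary: tuple[str, ...] = SYSTEMS,
    ) -> "AtlasMap":
        """Build an atlas with contiguous system blocks.

        When ``system_sizes`` is omitted the regions are divided as evenly
        as possible across the vocabulary (earlier systems absorb the
        remainder), mirroring how a parcellation distributes parcels over
        networks.
        """
        if system_sizes is None:
            k = len(vocabulary)
            base, rem = divmod(n_regions, k)
            system_sizes = tuple(base + (1 if i < rem else 0) for i in range(k))
        if sum(system_sizes) != n_regions:
            raise ValueError(
                f"system sizes sum to {sum(system_sizes)}, expected {n_regions}"
            )
        systems: list[str] = []
        for name, size in zip(vocabulary, system_sizes):
            systems.extend([name] * size)
        region_ids = tuple(f"R{i + 1:03d}" for i in range(n_regions))
        return cls(region_ids, tuple(systems), vocabulary=vocabulary)


def aggregate_by_system(
    values: np.ndarray, atlas: AtlasMap, region_ids: tuple[str, ...] | None = None
) -> pd.Series:
    """Unweighted mean of a regional vector within each system.

    Raises ``KeyError`` if a region is missing from the atlas.
    """
    values = np.asarray(values, dtype=float)
    if region_ids is None:
        region_ids = atlas.region_ids
    if values.shape[0] != len(region_ids):
        raise ValueError("values length does not match region ids")
    missing = [r for r in region_ids if r not in atlas.region_ids]
    if missing:
        raise KeyError(f"regions not mapped by atlas: {missing[:5]}")
    labels = np.asarray([atlas.system_of(r) for r in region_ids])
    out = {}
    for name in atlas.system_names:
        mask = labels == name
        if mask.any():
            out[name] = float(values[mask].mean())
    return pd.Series(out, name="system_mean")
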