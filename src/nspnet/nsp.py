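"""Nested spectral partition (NSP) of a functional-connectivity matrix.

The FC matrix ``C`` is eigendecomposed into functional modes sorted by
descending eigenvalue. Mode 1 defines the whole-brain module (level 1);
at each further level ``i`` every existing module is split in two by the
sign pattern of eigenvector ``i`` restricted to that module, modules
whose members share a single sign being carried forward indivisible.
Each level contributes a component

    H_i = Lambda_i^2 * M_i * (1 - p_i) / N,
    p_i = sum_j |m_j - N / M_i| / N,

where ``M_i`` is the module count, ``m_j`` the module sizes and ``p_i``
penalizes deviation from equal module sizes. The global integration
component is ``H_In = H_1 / N`` and the segregation component is
``H_Se = sum_{i=2}^{N} H_i / N``; a region's share of either is weighted
by its squared eigenvector entries (``H_In^j = H_1 U_1j^2`` and
``H_Se^j = sum_{i>=2} H_i U_ij^2``).

Sign conventions (the raw eigenproblem leaves them free):

* each eigenvector is canonicalized so its entry-sum is positive; if the
  sum is numerically zero, the largest-magnitude entry (first on ties) is
  made positive;
* zero entries join the positive-sign group when splitting.

Degenerate (tied) eigenvalues make the partition non-unique; a warning is
emitted because empirical FC matrices are generically non-degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .atlas import AtlasMap, aggregate_by_system
from .fc import FCMatrix

_SYM_TOL = 1e-8
_DEGENERACY_TOL = 1e-10
_SUM_TOL = 1e-12


@dataclass
class EigenSpectrum:
    """Full symmetric eigendecomposition, modes sorted by descending eigenvalue.

    ``U[:, i]`` is the unit-norm, sign-canonicalized eigenvector of
    ``eigenvalues[i]``.
    """

    eigenvalues: np.ndarray
    U: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass
class PartitionLevel:
    """One level of the nested partition."""

    index: int  # 1-based level / mode index
    membership: np.ndarray  # region -> module label (0-based, order of appearance)
    sizes: np.ndarray  # module sizes m_j
    p: float  # size-heterogeneity correction p_i
    eigenvalue: float
    H: float  # level component H_i

    @property
    def n_modules(self) -> int:
        return int(self.sizes.shape[0])


@dataclass
class NestedPartition:
    """All ``N`` partition levels of one FC matrix."""

    levels: list[PartitionLevel]
    spectrum: EigenSpectrum

    def module_counts(self) -> np.ndarray:
        return np.array([lv.n_modules for lv in self.levels])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (level, module, region) table."""
        rows = []
        for lv in self.levels:
            for region, module in enumerate(lv.membership):
                rows.append((lv.index, int(module), region))
        return pd.DataFrame(rows, columns=["level", "module", "region"])


@dataclass
class SIProfile:
    """Global and regional segregation/integration components."""

    h_in: float
    h_se: float
    regional_in: np.ndarray  # H_In^j
    regional_se: np.ndarray  # H_Se^j
    region_ids: tuple[str, ...] | None = None

    def system_means(self, atlas: AtlasMap) -> pd.DataFrame:
        ids = self.region_ids or atlas.region_ids
        return pd.DataFrame(
            {
                "H_In": aggregate_by_system(self.regional_in, atlas, ids),
                "H_Se": aggregate_by_system(self.regional_se, atlas, ids),
            }
        )


def _canonical_sign(u: np.ndarray) -> float:
    s = u.sum()
    if abs(s) > _SUM_TOL:
        return 1.0 if s > 0 else -1.0
    j = int(np.argmax(np.abs(u)))  # first index on ties
    return 1.0 if u[j] >= 0 else -1.0


def eigendecompose_sorted(C: FCMatrix | np.ndarray) -> EigenSpectrum:
    """Eigendecompose a symmetric matrix, sort modes by descending eigenvalue,
    and canonicalize every eigenvector's sign (entry-sum positive)."""
    A = C.C if isinstance(C, FCMatrix) else np.asarray(C, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if np.max(np.abs(A - A.T)) > _SYM_TOL:
        raise ValueError("matrix is not symmetric within tolerance")
    w, V = eigh((A + A.T) / 2.0)
    order = np.argsort(-w, kind="stable")
    w = w[order]
    V = V[:, order]
    for i in range(V.shape[1]):
        V[:, i] *= _canonical_sign(V[:, i])
    if np.any(np.abs(np.diff(w)) < _DEGENERACY_TOL):
        warnings.warn(
            "degenerate eigenvalues: nested partition is not unique",
            stacklevel=2,
        )
    return EigenSpectrum(eigenvalues=w, U=V)


def size_correction(sizes: np.ndarray, n: int) -> float:
    """Heterogeneity correction p = sum_j |m_j - N/M| / N."""
    sizes = np.asarray(sizes, dtype=float)
    m = sizes.shape[0]
    return float(np.abs(sizes - n / m).sum() / n)


def level_component(sizes: np.ndarray, eigenvalue: float, n: int) -> tuple[float, float]:
    """Return ``(p_i, H_i)`` for one level given its module sizes."""
    sizes = np.asarray(sizes)
    if int(sizes.sum()) != n:
        raise ValueError("module sizes must sum to N")
    p = size_correction(sizes, n)
    h = eigenvalue**2 * sizes.shape[0] * (1.0 - p) / n
    return p, h


def nested_partition(spectrum: EigenSpectrum) -> NestedPartition:
    """Run the nested sign-splitting partition over all ``N`` modes.

    Level 1 is the whole-brain module. At level ``i`` each module is split
    by the signs of ``U[:, i-1]`` restricted to its members (zeros count as
    positive); single-signed modules are indivisible and carried forward.
    Once every module is a singleton, the remaining levels repeat the
    singleton partition.
    """
    n = spectrum.n
    levels: list[PartitionLevel] = []
    membership = np.zeros(n, dtype=int)
    for i in range(1, n + 1):
        if i > 1 and levels[-1].n_modules < n:
            pos = spectrum.U[:, i - 1] >= 0.0
            # pair (module, sign) defines the refined modules; relabel by
            # order of first appearance for determinism
            key = membership * 2 + np.where(pos, 0, 1)
            _, membership = np.unique(key, return_inverse=True)
            membership = _first_appearance_labels(membership)
        elif i > 1:
            membership = np.arange(n)  # fully fragmented: repeat singletons
        sizes = np.bincount(membership)
        p, h = level_component(sizes, float(spectrum.eigenvalues[i - 1]), n)
        levels.append(
            PartitionLevel(
                index=i,
                membership=membership.copy(),
                sizes=sizes,
                p=p,
                eigenvalue=float(spectrum.eigenvalues[i - 1]),
                H=h,
            )
        )
    return NestedPartition(levels=levels, spectrum=spectrum)


def _first_appearance_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel integer labels by order of first appearance (stable)."""
    _, first = np.unique(labels, return_index=True)
    order = np.argsort(np.argsort(first))
    return order[labels]


def si_components(
    C: FCMatrix | np.ndarray, region_ids: tuple[str, ...] | None = None
) -> SIProfile:
    """Global and regional integration/segregation components of one FC matrix."""
    if isinstance(C, FCMatrix) and region_ids is None:
        region_ids = C.region_ids
    spectrum = eigendecompose_sorted(C)
    partition = nested_partition(spectrum)
    H = np.array([lv.H for lv in partition.levels])
    n = spectrum.n
    h_in = H[0] / n
    h_se = float(H[1:].sum() / n)
    U2 = spectrum.U**2
    regional_in = H[0] * U2[:, 0]
    regional_se = U2[:, 1:] @ H[1:]
    return SIProfile(
        h_in=float(h_in),
        h_se=h_se,
        regional_in=regional_in,
        regional_se=regional_se,
        region_ids=region_ids,
    )


def system_aggregate(profile: SIProfile, atlas: AtlasMap) -> pd.DataFrame:
    """Per-system unweighted means of the regional loadings."""
    return profile.system_means(atlas)
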