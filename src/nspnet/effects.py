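"""Opposite-effect decomposition of symptom scores on regional measures.

For every region a multiple regression

    H ~ SANS + SAPS + SANS x SAPS + sex + age + FD

is fitted within the patient group (scores exist only there); the SANS,
SAPS and interaction coefficients form regional effect maps. SANS and
SAPS are mean-centered before the product is formed, which leaves the
interaction coefficient unchanged but decorrelates it from the main
effects. Paired effect maps are reduced by a two-column PCA whose first
component (the "coeffect") is signed so positive scores align with the
SANS effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AtlasMap, aggregate_by_system
from .stats import StatResult, pearson_with_t


@dataclass
class EffectMap:
    """Per-region regression coefficients (and their SEs) for one measure."""

    measure: str
    coef: pd.DataFrame  # regions x predictors
    se: pd.DataFrame

    def vector(self, predictor: str) -> np.ndarray:
        return self.coef[predictor].to_numpy()


@dataclass
class CoeffectMap:
    """First-PC scores over two paired effect vectors."""

    scores: np.ndarray
    explained: float  # explained-variance fraction of PC1, in (0, 1]
    loadings: np.ndarray  # PC1 loadings on (first, second) input column
    sign_flipped: bool


PREDICTORS = ("sans", "saps", "interaction", "sex", "age", "fd")


def fit_effect_model(
    values: np.ndarray,
    records: pd.DataFrame,
    measure: str = "measure",
    region_ids: tuple[str, ...] | None = None,
) -> EffectMap:
    """Per-region OLS of a regional measure on symptom scores + nuisance.

    ``values`` is subjects x regions; ``records`` must carry sans_total,
    saps_total, sex, age, fd for the same subjects (patient group).
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    n, n_regions = V.shape
    sans = records["sans_total"].to_numpy(dtype=float)
    saps = records["saps_total"].to_numpy(dtype=float)
    sans_c = sans - sans.mean()
    saps_c = saps - saps.mean()
    X = np.column_stack([
        np.ones(n), sans, saps, sans_c * saps_c,
        records["sex"].to_numpy(dtype=float),
        records["age"].to_numpy(dtype=float),
        records["fd"].to_numpy(dtype=float),
    ])
    if n <= X.shape[1]:
        raise ValueError("need more subjects than predictors")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which added column kills the rank
        names = ("const",) + PREDICTORS
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear predictor(s): {bad}")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ V  # (p+1) x regions
    resid = V - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    ids = region_ids or tuple(f"R{i + 1:03d}" for i in range(n_regions))
    cols = ("const",) + PREDICTORS
    return EffectMap(
        measure=measure,
        coef=pd.DataFrame(beta.T, index=ids, columns=cols),
        se=pd.DataFrame(se.T, index=ids, columns=cols),
    )


def effect_vector_correlation(map_a: np.ndarray, map_b: np.ndarray) -> StatResult:
    """Pearson correlation of two effect maps across regions."""
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect maps must cover the same regions")
    return pearson_with_t(a, b)


def pca_coeffect(effect_sans: np.ndarray, effect_saps: np.ndarray) -> CoeffectMap:
    """First principal component of two standardized effect vectors.

    Columns are z-scored (the two maps are coefficients of different
    measures with different scales); PC1 scores are computed per region
    and the sign is fixed so the loading on the first (SANS) column is
    positive — positive scores then indicate SANS-dominant effects.
    """
    a = np.asarray(effect_sans, dtype=float)
    b = np.asarray(effect_saps, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect vectors must cover the same regions")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant effect column; PCA undefined")
    Z = np.column_stack([(a - a.mean()) / a.std(), (b - b.mean()) / b.std()])
    # SVD of the centered (already zero-mean) matrix
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    explained = float(s[0] ** 2 / (s**2).sum())
    pc1 = Vt[0]
    flipped = False
    if pc1[0] < 0 or (pc1[0] == 0 and pc1[1] < 0):
        pc1 = -pc1
        flipped = True
    scores = Z @ pc1
    return CoeffectMap(
        scores=scores, explained=explained, loadings=pc1, sign_flipped=flipped
    )


def overall_effect(coeffect_f_in: np.ndarray, coeffect_f_se: np.ndarray) -> CoeffectMap:
    """First PC of two coeffect (or interaction-effect) maps.

    Same mechanics and SANS-positive sign convention as
    :func:`pca_coeffect`; used to pool the integration- and
    segregation-variability coeffects into one overall effect map.
    """
    return pca_coeffect(coeffect_f_in, coeffect_f_se)


def system_effect_summary(
    values: np.ndarray, atlas: AtlasMap, region_ids: tuple[str, ...] | None = None
) -> pd.Series:
    """Unweighted per-system means of a regional effect/coeffect map."""
    return aggregate_by_system(values, atlas, region_ids)
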