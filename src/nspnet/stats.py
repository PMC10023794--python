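"""Group statistics: ANCOVA with motion covariate, BH-FDR, correlations,
relative changes and the system-level permutation test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasMap


@dataclass
class SubjectRecord:
    """Clinical record: group, demographics, motion and symptom scores.

    SANS dimensions: avolition, alogia, anhedonia, attention, affective
    flattening; SAPS dimensions: hallucinations, delusions, bizarre
    behavior, thought disorder, blunted affect. Totals are the dimension
    sums.
    """

    subject_id: str
    group: str  # "HC" or "SCH"
    sex: int  # 0 male, 1 female
    age: float
    fd: float  # mean framewise displacement, mm
    sans: dict[str, float] | None = None
    saps: dict[str, float] | None = None

    @property
    def sans_total(self) -> float | None:
        return None if self.sans is None else float(sum(self.sans.values()))

    @property
    def saps_total(self) -> float | None:
        return None if self.saps is None else float(sum(self.saps.values()))


SANS_DIMENSIONS = (
    "avolition", "alogia", "anhedonia", "attention", "affective_flattening",
)
SAPS_DIMENSIONS = (
    "hallucinations", "delusions", "bizarre_behavior", "thought_disorder",
    "blunted_affect",
)


def records_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject": r.subject_id, "group": r.group, "sex": r.sex,
            "age": r.age, "fd": r.fd,
        }
        if r.sans is not None:
            row.update({f"sans_{k}": v for k, v in r.sans.items()})
            row["sans_total"] = r.sans_total
        if r.saps is not None:
            row.update({f"saps_{k}": v for k, v in r.saps.items()})
            row["saps_total"] = r.saps_total
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StatResult:
    statistic: float
    df: float
    p: float
    r: float | None = None
    p_fdr: float | None = None


def ancova_group(
    values: np.ndarray,
    groups: np.ndarray,
    fd: np.ndarray,
    patient_label: str = "SCH",
) -> StatResult:
    """Between-group test of a network measure with FD as covariate.

    Fits ``value ~ group + FD`` by OLS and reports the group-indicator
    t statistic (positive = patient group higher) with the model's
    residual degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if np.ptp(values) == 0:
        raise ValueError("values are constant; ANCOVA undefined")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    g = (groups == patient_label).astype(float)
    X = sm.add_constant(np.column_stack([g, np.asarray(fd, dtype=float)]))
    fit = sm.OLS(values, X).fit()
    return StatResult(
        statistic=float(fit.tvalues[1]),
        df=float(fit.df_resid),
        p=float(fit.pvalues[1]),
    )


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def pearson_with_t(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Pearson r with its t statistic t = r sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r**2, np.finfo(float).tiny))
    return StatResult(statistic=float(t), df=float(n - 2), p=float(p), r=float(r))


def r_to_t(r: float, n: int) -> float:
    """t statistic implied by a Pearson r at sample size n."""
    return r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)


def relative_change(hc_mean: float, sch_mean: float) -> float:
    """Percent change from the control mean to the patient mean."""
    if hc_mean == 0:
        raise ValueError("zero baseline mean")
    return 100.0 * (sch_mean - hc_mean) / hc_mean


def system_permutation_test(
    regional_changes: np.ndarray,
    atlas: AtlasMap,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.Series:
    """Permutation test of whether any system's mean change stands out.

    The observed statistic per system is |system mean - grand mean| of the
    regional change values; the null shuffles region→system labels. The
    add-one convention keeps p strictly positive:
    p = (1 + #{null >= obs}) / (1 + n_perm).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(regional_changes, dtype=float)
    if x.shape[0] != atlas.n_regions:
        raise ValueError("changes length must match atlas regions")
    grand = x.mean()
    systems = atlas.system_names
    name_to_int = {s: i for i, s in enumerate(systems)}
    labels = np.array([name_to_int[s] for s in atlas.labels_array()])
    k = len(systems)
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.bincount(labels, weights=x, minlength=k)
    obs = np.abs(sums / counts - grand)
    exceed = np.zeros(k)
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        c = np.bincount(perm, minlength=k)
        while (c == 0).any():
            rng.shuffle(perm)  # a system emptied by the shuffle is reshuffled
            c = np.bincount(perm, minlength=k)
        null = np.abs(np.bincount(perm, weights=x, minlength=k) / c - grand)
        exceed += null >= obs
    return pd.Series(
        {s: (1 + exceed[i]) / (1 + n_perm) for i, s in enumerate(systems)},
        name="p_perm",
    )


def group_comparison_table(
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    measures: tuple[str, ...] = ("H_In", "H_Se", "F_In", "F_Se"),
    scope: str = "system",
    patient_label: str = "SCH",
) -> pd.DataFrame:
    """ANCOVA per measure per unit with BH-FDR within each measure family."""
    rec = records.set_index("subject")
    out = []
    for measure in measures:
        sub = metrics[(metrics["measure"] == measure) & (metrics["scope"] == scope)]
        units = sub["unit"].unique()
        results = []
        for unit in units:
            u = sub[sub["unit"] == unit]
            fd = rec.loc[u["subject"], "fd"].to_numpy()
            res = ancova_group(
                u["value"].to_numpy(), u["group"].to_numpy(), fd,
                patient_label=patient_label,
            )
            results.append((measure, unit, res.statistic, res.df, res.p))
        padj = bh_fdr(np.array([r[4] for r in results]))
        for row, q in zip(results, padj):
            out.append((*row, q))
    return pd.DataFrame(
        out, columns=["measure", "unit", "t", "df", "p", "p_fdr"]
    )
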