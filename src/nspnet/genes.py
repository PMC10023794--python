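"""Gene-association screening against regional effect maps.

Every gene's regional expression profile is correlated (Pearson, across
regions) with an effect map; BH-FDR across all genes yields a
positive-significant and a negative-significant set. Ranked lists are
exported for external GO-enrichment tooling, and significant sets can be
intersected with a user-supplied gene panel.

Regions are treated as exchangeable samples — no spatial-autocorrelation
correction is applied, a documented limitation of this screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr


@dataclass
class GeneAssociationResult:
    table: pd.DataFrame  # gene, r, p, p_fdr, call
    alpha: float

    @property
    def positive(self) -> list[str]:
        t = self.table
        return t.loc[t["call"] == "positive", "gene"].tolist()

    @property
    def negative(self) -> list[str]:
        t = self.table
        return t.loc[t["call"] == "negative", "gene"].tolist()


def gene_effect_correlations(
    effect_vec: np.ndarray, expression: pd.DataFrame, alpha: float = 0.05
) -> GeneAssociationResult:
    """Correlate an effect map with every gene's expression profile.

    ``expression`` is regions x genes with unique gene-symbol columns.
    Constant gene columns are excluded with a warning (their correlation
    is undefined). FDR is controlled in one family across all genes.
    """
    x = np.asarray(effect_vec, dtype=float)
    if expression.shape[0] != x.shape[0]:
        raise ValueError("expression rows must match effect-map regions")
    if expression.shape[0] < 3:
        raise ValueError("need at least 3 regions")
    if expression.columns.duplicated().any():
        raise ValueError("gene symbols must be unique")
    E = expression.to_numpy(dtype=float)
    n = x.shape[0]
    sd = E.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} constant gene column(s) excluded from the screen"
        )
    xc = x - x.mean()
    x_sd = xc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (E - E.mean(axis=0)).T @ xc / (n * sd * x_sd)
    r = np.where(keep, r, np.nan)
    rc = np.clip(r[keep], -1 + 1e-15, 1 - 1e-15)
    t = rc * np.sqrt(n - 2) / np.sqrt(1 - rc**2)
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p_fdr = bh_fdr(p)
    genes = expression.columns.to_numpy()
    table = pd.DataFrame({"gene": genes, "r": r})
    table["p"] = np.nan
    table["p_fdr"] = np.nan
    table.loc[keep, "p"] = p
    table.loc[keep, "p_fdr"] = p_fdr
    call = np.full(genes.shape, "none", dtype=object)
    sig = np.zeros(genes.shape, dtype=bool)
    sig[keep] = p_fdr < alpha
    call[sig & (table["r"].to_numpy() > 0)] = "positive"
    call[sig & (table["r"].to_numpy() < 0)] = "negative"
    call[~keep] = "excluded"
    table["call"] = call
    return GeneAssociationResult(table=table, alpha=alpha)


def panel_overlap(result: GeneAssociationResult, panel: list[str]) -> pd.DataFrame:
    """Intersect significant sets with a gene panel (case-insensitive)."""
    norm = {g.upper(): g for g in panel}
    rows = []
    for name, genes in (("positive", result.positive), ("negative", result.negative)):
        hits = [g for g in genes if g.upper() in norm]
        rows.append((name, len(hits), ";".join(sorted(hits))))
    return pd.DataFrame(rows, columns=["set", "n_overlap", "genes"])


def export_ranked_list(result: GeneAssociationResult, path: str) -> None:
    """Write tab-delimited ranked gene lists (by |r| within each signed set)."""
    t = result.table
    parts = []
    for name in ("positive", "negative"):
        sub = t[t["call"] == name].copy()
        sub["abs_r"] = sub["r"].abs()
        sub = sub.sort_values(["abs_r", "gene"], ascending=[False, True])
        sub["set"] = name
        parts.append(sub[["set", "gene", "r", "p", "p_fdr"]])
    out = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str) -> list[str]:
    """Read a one-symbol-per-line gene panel file."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
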