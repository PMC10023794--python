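"""End-to-end orchestration: simulate -> FC -> decomposition -> dynamics ->
group statistics -> prediction -> effect decomposition -> gene screen.

Every stage writes tidy TSV outputs into a run directory together with a
provenance record (config, seeds, package versions), and each stage can
be re-run individually from the saved intermediates.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import AtlasMap
from .dynamics import cohort_si_metrics
from .effects import fit_effect_model, overall_effect, pca_coeffect
from .fc import WindowSpec
from .genes import export_ranked_list, gene_effect_correlations
from .io import save_atlas, save_clinical, save_expression, save_timeseries
from .prediction import PredictionModelSpec, permutation_pvalue, select_best_k, system_weights
from .simulate import ScoreLink, SimulationSpec, simulate_cohort, simulate_expression, simulate_scores
from .stats import group_comparison_table, records_frame, relative_change, system_permutation_test


@dataclass
class RunConfig:
    """Configuration of one pipeline run (persisted alongside outputs)."""

    out_dir: str = "nspnet_run"
    seed: int = 0
    n_regions: int = 60
    n_subjects_per_group: int = 20
    n_frames: int = 152
    window: WindowSpec = field(default_factory=WindowSpec)
    n_perm_system: int = 1000
    n_perm_prediction: int = 1000
    fdr_alpha: float = 0.05
    selection_mode: str = "in-fold"
    prediction_measure: str = "F_Se"
    patient_label: str = "SCH"
    k_grid_max: int | None = 20
    write_series: bool = False


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic-cohort analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    spec = SimulationSpec(
        n_regions=config.n_regions,
        n_subjects_per_group=config.n_subjects_per_group,
        n_frames=config.n_frames,
        seed=config.seed,
        score_link=(
            ScoreLink("saps.hallucinations", "H_In",
                      _system_regions(config, "DOR"), slope=2.0, noise_sd=1.0),
            ScoreLink("sans.avolition", "H_Se",
                      _system_regions(config, "DMN"), slope=-2.0, noise_sd=1.0),
        ),
    )
    cohort = simulate_cohort(spec)
    cohort = simulate_scores(cohort, patient_group=config.patient_label)
    atlas = cohort.atlas
    save_atlas(atlas, out / "atlas.tsv")
    save_clinical(cohort.records, out / "clinical.tsv")
    if config.write_series:
        series_dir = out / "timeseries"
        series_dir.mkdir(exist_ok=True)
        for group, lst in cohort.series.items():
            for ts in lst:
                save_timeseries(ts, series_dir / f"{ts.subject_id}.tsv")

    # --- dynamics: calibrated strengths/variabilities ---
    metrics = cohort_si_metrics(cohort.series, config.window, atlas=atlas)
    metrics.to_csv(out / "si_metrics.tsv", sep="\t", index=False)

    # --- group statistics ---
    records = records_frame(cohort.records)
    comparisons = group_comparison_table(
        metrics, records, scope="system", patient_label=config.patient_label
    )
    comparisons.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    reg = metrics[(metrics["scope"] == "region") & (metrics["measure"] == "H_Se")]
    means = reg.pivot_table(index="unit", columns="group", values="value")
    changes = np.array([
        relative_change(means.loc[r, "HC"], means.loc[r, config.patient_label])
        for r in atlas.region_ids
    ])
    perm_p = system_permutation_test(
        changes, atlas, n_perm=config.n_perm_system, rng=rng
    )
    perm_p.to_frame().to_csv(out / "system_permutation.tsv", sep="\t")

    # --- symptom prediction (patients only) ---
    pat = records[records["group"] == config.patient_label].set_index("subject")
    features = _regional_feature_matrix(
        metrics, config.patient_label, config.prediction_measure, atlas
    )
    pspec = PredictionModelSpec(
        measure=config.prediction_measure, selection=config.selection_mode,
        seed=config.seed,
    )
    k_grid = np.arange(1, min(config.k_grid_max or features.shape[1],
                              features.shape[1]) + 1)
    pred_rows = []
    weights_by_scale = {}
    for scale in ("sans_total", "saps_total"):
        y = pat.loc[_patients_order(metrics, config.patient_label), scale].to_numpy()
        res = select_best_k(features, y, pspec, k_grid=k_grid)
        res.permutation_p = permutation_pvalue(
            features, y, PredictionModelSpec(
                pspec.measure, res.k, pspec.selection, pspec.seed
            ),
            res.accuracy_r, n_perm=config.n_perm_prediction, rng=rng,
        )
        weights_by_scale[scale] = res.weights
        sw = system_weights(res.weights, atlas)
        pred_rows.append({
            "scale": scale, "measure": config.prediction_measure, "k": res.k,
            "accuracy_r": res.accuracy_r, "p_perm": res.permutation_p,
            **{f"w_{s}": v for s, v in sw.items()},
        })
    pd.DataFrame(pred_rows).to_csv(out / "prediction.tsv", sep="\t", index=False)

    # --- effect decomposition (Eq.-8-style per-region regression) ---
    order = _patients_order(metrics, config.patient_label)
    rec_pat = pat.loc[order].reset_index()
    eff_maps = {}
    for measure in ("F_In", "F_Se"):
        vals = _regional_feature_matrix(
            metrics, config.patient_label, measure, atlas
        )
        eff_maps[measure] = fit_effect_model(
            vals, rec_pat, measure=measure, region_ids=atlas.region_ids
        )
    co_in = pca_coeffect(
        eff_maps["F_In"].vector("sans"), eff_maps["F_In"].vector("saps")
    )
    co_se = pca_coeffect(
        eff_maps["F_Se"].vector("sans"), eff_maps["F_Se"].vector("saps")
    )
    overall = overall_effect(co_in.scores, co_se.scores)
    eff_out = pd.DataFrame({
        "region": atlas.region_ids,
        "beta_sans_F_In": eff_maps["F_In"].vector("sans"),
        "beta_saps_F_In": eff_maps["F_In"].vector("saps"),
        "beta_sans_F_Se": eff_maps["F_Se"].vector("sans"),
        "beta_saps_F_Se": eff_maps["F_Se"].vector("saps"),
        "coeffect_F_In": co_in.scores,
        "coeffect_F_Se": co_se.scores,
        "overall_effect": overall.scores,
    })
    eff_out.to_csv(out / "effects.tsv", sep="\t", index=False)

    # --- gene-association screen on the overall effect ---
    cohort = simulate_expression(cohort, effect_vector=overall.scores)
    save_expression(cohort.expression, out / "expression.tsv")
    screen = gene_effect_correlations(
        overall.scores, cohort.expression, alpha=config.fdr_alpha
    )
    screen.table.to_csv(out / "gene_screen.tsv", sep="\t", index=False)
    export_ranked_list(screen, str(out / "ranked_genes.tsv"))

    _write_provenance(out, config, spec)
    return out


def _system_regions(config: RunConfig, system: str) -> tuple[int, ...]:
    atlas = AtlasMap.evenly_split(config.n_regions)
    return tuple(int(i) for i in atlas.indices(system))


def _patients_order(metrics: pd.DataFrame, patient_label: str) -> list[str]:
    sub = metrics[metrics["group"] == patient_label]
    return list(dict.fromkeys(sub["subject"]))


def _regional_feature_matrix(
    metrics: pd.DataFrame, group: str, measure: str, atlas: AtlasMap
) -> np.ndarray:
    sub = metrics[
        (metrics["group"] == group)
        & (metrics["scope"] == "region")
        & (metrics["measure"] == measure)
    ]
    wide = sub.pivot_table(index="subject", columns="unit", values="value")
    wide = wide.loc[_patients_order(metrics, group), list(atlas.region_ids)]
    return wide.to_numpy()


def _write_provenance(out: Path, config: RunConfig, spec) -> None:
    payload = {
        "nspnet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {
            k: (v if isinstance(v, (int, float, str, bool, type(None)))
                else repr(v))
            for k, v in vars(config).items()
        },
        "simulation": {
            "n_regions": spec.n_regions,
            "n_subjects_per_group": spec.n_subjects_per_group,
            "n_frames": spec.n_frames,
            "dwell_integrated": spec.dwell_integrated,
        },
    }
    (out / "provenance.json").write_text(json.dumps(payload, indent=2))
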