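"""Synthetic two-group cohorts with state-switching covariance structure.

Each subject's regional BOLD record is drawn from a two-state generative
model: the brain alternates between an "integrated" state (uniform
correlation everywhere) and a "segregated" state (high correlation inside
each functional-system block, low correlation between blocks). The state
sequence is a two-state Markov chain whose stationary probability of the
integrated state (the dwell parameter) can differ between groups — a
patient-like group with a lower dwell spends less time integrated, which
plants the weaker-integration/stronger-segregation phenotype downstream
analyses should detect.

Clinical scores are linear functions of the subject's true network
features plus noise, clipped and rounded to nonnegative integers like
real symptom-scale sums. Gene expression planted on an effect map allows
recovery tests of the association screen. A ground-truth ledger records
the state sequences, score-link slopes and planted gene identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import AtlasMap, SYSTEMS
from .fc import RegionalTimeSeries, pearson_fc
from .nsp import si_components
from .stats import SANS_DIMENSIONS, SAPS_DIMENSIONS, SubjectRecord


@dataclass(frozen=True)
class ScoreLink:
    """A planted linear link from a network feature to a symptom dimension.

    ``dimension`` is e.g. ``"saps.hallucinations"``; ``measure`` is the
    regional measure averaged over ``regions`` (indices) to form the
    feature; the z-scored feature enters the score with ``slope``.
    """

    dimension: str
    measure: str  # "H_In" | "H_Se" (static regional loadings)
    regions: tuple[int, ...]
    slope: float
    noise_sd: float = 1.0
    baseline: float = 6.0


@dataclass(frozen=True)
class GeneSpec:
    n_genes: int = 2000
    n_planted: int = 50
    planted_noise_sd: float = 0.5
    system_effect_sd: float = 0.3  # shared per-system component of null genes


@dataclass
class SimulationSpec:
    """All knobs of the cohort generator, validated at construction."""

    n_regions: int = 200
    n_systems: int = 7
    system_sizes: tuple[int, ...] | None = None
    n_subjects_per_group: int = 50
    n_frames: int = 152
    tr_seconds: float = 2.0
    dwell_integrated: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.6, "SCH": 0.3}
    )
    mean_dwell_frames: float = 8.0
    within_block_corr: float = 0.5
    between_block_corr: float = 0.05
    integrated_corr: float = 0.6
    score_link: tuple[ScoreLink, ...] = ()
    gene_spec: GeneSpec = field(default_factory=GeneSpec)
    #: optional per-system within-block correlation overrides applied to the
    #: patient-like group's segregated state only — plants a
    #: system-concentrated group effect (e.g. a limbic-style alteration)
    patient_system_corr: dict[str, float] | None = None
    patient_label: str = "SCH"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system_sizes is None:
            k = self.n_systems
            base, rem = divmod(self.n_regions, k)
            self.system_sizes = tuple(
                base + (1 if i < rem else 0) for i in range(k)
            )
        if sum(self.system_sizes) != self.n_regions:
            raise ValueError("system_sizes must sum to n_regions")
        for g, d in self.dwell_integrated.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"dwell_integrated[{g}] outside [0, 1]")
        for name in ("within_block_corr", "between_block_corr", "integrated_corr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        checks = [
            ("integrated_corr", self.integrated_cov()),
            ("within_block_corr/between_block_corr", self.segregated_cov()),
        ]
        if self.patient_system_corr:
            checks.append(
                ("patient_system_corr", self.segregated_cov(patient=True))
            )
        for name, cov in checks:
            w = np.linalg.eigvalsh(cov)
            if w.min() < -1e-10:
                raise ValueError(f"state covariance for {name} is not PSD")
        if self.gene_spec.n_planted > self.gene_spec.n_genes:
            raise ValueError("n_planted exceeds n_genes")

    def atlas(self) -> AtlasMap:
        vocab = SYSTEMS[: self.n_systems] if self.n_systems <= len(SYSTEMS) else tuple(
            f"SYS{i + 1}" for i in range(self.n_systems)
        )
        return AtlasMap.evenly_split(self.n_regions, self.system_sizes, vocab)

    def integrated_cov(self) -> np.ndarray:
        c = self.integrated_corr
        S = np.full((self.n_regions, self.n_regions), c)
        np.fill_diagonal(S, 1.0)
        return S

    def segregated_cov(self, patient: bool = False) -> np.ndarray:
        overrides = self.patient_system_corr if patient else None
        atlas_names = self.atlas().vocabulary
        S = np.full((self.n_regions, self.n_regions), self.between_block_corr)
        start = 0
        for name, size in zip(atlas_names, self.system_sizes):
            c = self.within_block_corr
            if overrides and name in overrides:
                c = overrides[name]
            S[start : start + size, start : start + size] = c
            start += size
        np.fill_diagonal(S, 1.0)
        return S


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth needed to score recovery."""

    spec: SimulationSpec
    series: dict[str, list[RegionalTimeSeries]]  # group -> subjects
    records: list[SubjectRecord]
    atlas: AtlasMap
    expression: pd.DataFrame | None = None
    ground_truth: dict = field(default_factory=dict)

    def records_of(self, group: str) -> list[SubjectRecord]:
        return [r for r in self.records if r.group == group]


def _markov_states(
    rng: np.random.Generator, n_frames: int, dwell: float, mean_dwell: float
) -> np.ndarray:
    """Two-state chain (1 = integrated) with stationary P(integrated) = dwell."""
    a = (1.0 - dwell) / mean_dwell  # leave integrated
    b = dwell / mean_dwell  # enter integrated
    states = np.empty(n_frames, dtype=int)
    states[0] = int(rng.random() < dwell)
    for t in range(1, n_frames):
        if states[t - 1] == 1:
            states[t] = 0 if rng.random() < a else 1
        else:
            states[t] = 1 if rng.random() < b else 0
    return states


def simulate_cohort(spec: SimulationSpec) -> SyntheticCohort:
    """Draw the full two-group cohort (deterministic given spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    chol_int = np.linalg.cholesky(
        spec.integrated_cov() + 1e-10 * np.eye(spec.n_regions)
    )
    chol_seg = np.linalg.cholesky(
        spec.segregated_cov() + 1e-10 * np.eye(spec.n_regions)
    )
    chol_seg_patient = (
        np.linalg.cholesky(
            spec.segregated_cov(patient=True) + 1e-10 * np.eye(spec.n_regions)
        )
        if spec.patient_system_corr
        else chol_seg
    )
    atlas = spec.atlas()
    series: dict[str, list[RegionalTimeSeries]] = {}
    records: list[SubjectRecord] = []
    truth_states: dict[str, np.ndarray] = {}
    demo = {
        # group -> (age mean, age sd, fd mean, fd sd, n female)
        "HC": (34.84, 9.03, 0.160, 0.159, 12),
        "SCH": (36.46, 8.88, 0.267, 0.215, 12),
    }
    for group, dwell in spec.dwell_integrated.items():
        series[group] = []
        age_m, age_sd, fd_m, fd_sd, n_f = demo.get(group, (35.0, 9.0, 0.2, 0.15, 12))
        seg_chol = chol_seg_patient if group == spec.patient_label else chol_seg
        for k in range(spec.n_subjects_per_group):
            sid = f"{group}-{k + 1:03d}"
            states = _markov_states(rng, spec.n_frames, dwell, spec.mean_dwell_frames)
            z = rng.standard_normal((spec.n_frames, spec.n_regions))
            x = np.where(
                states[:, None] == 1, z @ chol_int.T, z @ seg_chol.T
            )
            series[group].append(
                RegionalTimeSeries(
                    x, tr_seconds=spec.tr_seconds, subject_id=sid,
                    region_ids=atlas.region_ids,
                )
            )
            truth_states[sid] = states
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    sex=int(k < n_f * spec.n_subjects_per_group / 50),
                    age=float(np.clip(rng.normal(age_m, age_sd), 18, 65)),
                    fd=float(max(rng.normal(fd_m, fd_sd), 0.01)),
                )
            )
    cohort = SyntheticCohort(
        spec=spec, series=series, records=records, atlas=atlas,
        ground_truth={"states": truth_states, "score_links": spec.score_link},
    )
    return cohort


def static_regional_features(
    cohort: SyntheticCohort, group: str, measure: str
) -> np.ndarray:
    """Subjects x regions matrix of static regional loadings for one group."""
    if measure not in ("H_In", "H_Se"):
        raise ValueError("measure must be 'H_In' or 'H_Se'")
    rows = []
    for ts in cohort.series[group]:
        prof = si_components(pearson_fc(ts))
        rows.append(prof.regional_in if measure == "H_In" else prof.regional_se)
    return np.stack(rows)


def simulate_scores(
    cohort: SyntheticCohort,
    patient_group: str = "SCH",
    rng: np.random.Generator | None = None,
    features: dict[str, np.ndarray] | None = None,
) -> SyntheticCohort:
    """Fill patient symptom scores from the planted score links.

    Each linked dimension is ``baseline + slope * z(feature) + noise``
    clipped at zero and rounded to an integer; unlinked dimensions are
    noise around the baseline. ``features`` may supply precomputed
    subjects x regions matrices per measure (e.g. variability measures);
    static loadings are computed on demand otherwise.
    """
    spec = cohort.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_subjects_per_group
    feat_cache: dict[str, np.ndarray] = dict(features or {})
    links_by_dim: dict[str, list[ScoreLink]] = {}
    for link in spec.score_link:
        if max(link.regions, default=0) >= spec.n_regions:
            raise ValueError(f"score link {link.dimension}: region outside atlas")
        links_by_dim.setdefault(link.dimension, []).append(link)

    def dim_scores(scale: str, dim: str) -> np.ndarray:
        key = f"{scale}.{dim}"
        base = np.full(n, 5.0)
        noise_sd = 1.5
        for link in links_by_dim.get(key, []):
            if link.measure not in feat_cache:
                feat_cache[link.measure] = static_regional_features(
                    cohort, patient_group, link.measure
                )
            f = feat_cache[link.measure][:, list(link.regions)].mean(axis=1)
            z = (f - f.mean()) / f.std() if f.std() > 0 else np.zeros(n)
            base = (
                np.full(n, link.baseline) + link.slope * z
                + (link.noise_sd * rng.standard_normal(n) if link.noise_sd else 0.0)
            )
            noise_sd = 0.0  # linked dimensions carry their own noise term
        if noise_sd:
            base = base + noise_sd * rng.standard_normal(n)
        return np.clip(np.rint(base), 0, None)

    truth_values: dict[str, np.ndarray] = {}
    patients = cohort.records_of(patient_group)
    sans = {d: dim_scores("sans", d) for d in SANS_DIMENSIONS}
    saps = {d: dim_scores("saps", d) for d in SAPS_DIMENSIONS}
    for i, rec in enumerate(patients):
        rec.sans = {d: float(sans[d][i]) for d in SANS_DIMENSIONS}
        rec.saps = {d: float(saps[d][i]) for d in SAPS_DIMENSIONS}
    truth_values["sans"] = np.column_stack([sans[d] for d in SANS_DIMENSIONS])
    truth_values["saps"] = np.column_stack([saps[d] for d in SAPS_DIMENSIONS])
    cohort.ground_truth["score_values"] = truth_values
    return cohort


def simulate_expression(
    cohort: SyntheticCohort,
    effect_vector: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticCohort:
    """Region x gene table with ``n_planted`` genes tracking an effect map.

    Planted genes are the (standardized) effect vector plus Gaussian noise
    of SD ``planted_noise_sd``; null genes combine a shared per-system
    random effect (spatial smoothness) with independent noise.
    """
    spec = cohort.spec
    g = spec.gene_spec
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    n_regions = spec.n_regions
    if effect_vector is None:
        effect_vector = rng.standard_normal(n_regions)
    effect_vector = np.asarray(effect_vector, dtype=float)
    if effect_vector.shape[0] != n_regions:
        raise ValueError("effect vector length must equal n_regions")
    z_eff = (effect_vector - effect_vector.mean()) / effect_vector.std()
    names = [f"G{i + 1:05d}" for i in range(g.n_genes)]
    planted = names[: g.n_planted]
    E = np.empty((n_regions, g.n_genes))
    for j in range(g.n_planted):
        E[:, j] = z_eff + g.planted_noise_sd * rng.standard_normal(n_regions)
    labels = cohort.atlas.labels_array()
    for j in range(g.n_planted, g.n_genes):
        sys_fx = {
            s: g.system_effect_sd * rng.standard_normal()
            for s in cohort.atlas.system_names
        }
        E[:, j] = (
            np.array([sys_fx[s] for s in labels])
            + rng.standard_normal(n_regions)
        )
    cohort.expression = pd.DataFrame(
        E, index=list(cohort.atlas.region_ids), columns=names
    )
    cohort.ground_truth["planted_genes"] = planted
    cohort.ground_truth["effect_vector"] = effect_vector
    return cohort
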