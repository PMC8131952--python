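"""Orchestration of the smoothing x parcellation condition grid.

Each condition smooths the cohort at the vertex level, optionally averages
into parcels, and then runs the full analysis stack: age-association and CV
maps, resel/effective-FWHM estimation on the (surface-projected) residual
field, PCA-regression brain-age prediction, and delta-age estimation. The
grid assembles one comparison row per condition and summarizes the
association-vs-prediction relationship across conditions with Spearman rank
correlations.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .association import (
    AssociationMap,
    VariabilityMap,
    ResidualField,
    compute_cv,
    fit_age_association,
    median_r2,
    residual_field,
)
from .brainage import (
    DeltaEstimates,
    PredictionResult,
    cv_predict_age,
    delta1,
    delta2,
    delta_condition_correlations,
)
from .mesh import SurfaceMesh
from .parcellation import macro_aggregate, parcel_average, parcel_to_vertex
from .resels import ReselReport, resels_surface
from .smoothing import smooth_cohort
from .synthetic import CohortThickness, Parcellation, make_macro_regions, make_parcellation

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionGrid",
    "ConditionResult",
    "GridResult",
    "condition_name",
    "default_scenario",
    "run_condition",
    "run_grid",
    "association_vs_prediction",
]

VERTEXWISE = None  # sentinel parcellation level

#: Default-scenario surface: an icosphere at subdivision 4 (2,562 vertices)
#: with radius 30 mm. The radius is a scaled-down geometry choice: with 12
#: latent aging components, a 30 mm sphere puts the component spacing
#: (~33 mm) and component width (~13 mm FWHM) in the same ratio to the
#: 0-40 mm kernel grid that fine cortical aging structure has on a real
#: hemisphere, so small kernels are harmless and large kernels merge
#: neighbouring components.
DEFAULT_SUBDIVISIONS = 4
DEFAULT_RADIUS_MM = 30.0


def default_scenario(seed: int = 1):
    """The package's reference synthetic scenario: mesh, cohort, ground truth.

    An icosphere (subdivision 4, radius 30 mm) carrying a 300-subject cohort
    with 12 latent aging components, generated with the default
    :class:`~surfage.synthetic.CohortSpec` noise levels.
    """
    from .synthetic import CohortSpec, make_icosphere, simulate_cohort

    mesh = make_icosphere(DEFAULT_SUBDIVISIONS, DEFAULT_RADIUS_MM)
    cohort, truth = simulate_cohort(mesh, CohortSpec(seed=seed))
    return mesh, cohort, truth


@dataclass
class ConditionGrid:
    """The grid of analysis conditions and shared analysis settings."""

    smoothing_levels: tuple = (0.0, 5.0, 10.0, 20.0, 30.0, 40.0)
    parcellation_levels: tuple = (VERTEXWISE, 300, 100)
    seed: int = 0
    ks: tuple = tuple(range(1, 61))
    reference_k: int = 30
    folds: int = 10
    repetitions: int = 5
    pca_policy: str = "global"
    n_macro: int = 7
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.smoothing_levels or not self.parcellation_levels:
            raise ValueError("grid axes must be non-empty")
        if any(f < 0 for f in self.smoothing_levels):
            raise ValueError("smoothing FWHM must be >= 0")
        if any(p is not VERTEXWISE and p < 1 for p in self.parcellation_levels):
            raise ValueError("parcel counts must be >= 1 or vertexwise")

    @classmethod
    def from_yaml(cls, path: str) -> "ConditionGrid":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "parcellation_levels" in raw:
            raw["parcellation_levels"] = tuple(
                None if p in (None, "vertexwise") else int(p)
                for p in raw["parcellation_levels"]
            )
        for key in ("smoothing_levels", "ks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def condition_name(fwhm: float, parcellation_level) -> str:
    p = "vertexwise" if parcellation_level is VERTEXWISE else f"parc{parcellation_level}"
    return f"fwhm{fwhm:g}_{p}"


@dataclass
class ConditionResult:
    """All per-condition artifacts for one smoothing/parcellation pair."""

    condition: str
    fwhm: float
    parcellation_level: int | None
    association: AssociationMap
    variability: VariabilityMap
    resels: ReselReport
    prediction: PredictionResult
    deltas: DeltaEstimates
    macro_cv: np.ndarray | None = None


@dataclass
class GridResult:
    table: pd.DataFrame
    conditions: dict = field(default_factory=dict)  # name -> ConditionResult
    failures: dict = field(default_factory=dict)  # name -> error message
    manifest: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _condition_seed(base_seed: int, fwhm: float, level) -> int:
    ss = np.random.SeedSequence(
        [int(base_seed), int(round(fwhm * 10)), 0 if level is None else int(level)]
    )
    return int(ss.generate_state(1)[0] % 2**31)


def run_condition(
    mesh: SurfaceMesh,
    cohort: CohortThickness,
    fwhm: float,
    parcellation: Parcellation | None,
    grid: ConditionGrid | None = None,
    macro_reference: Parcellation | None = None,
    smoothed: CohortThickness | None = None,
) -> ConditionResult:
    """Run the full analysis stack for one condition.

    Smoothing is applied at the vertex level first, then parcel averaging
    (when a parcellation is given), then association/CV/prediction on the
    resulting units. Resels are always computed on a vertex-level field; for
    parcel conditions the parcel values are projected back to the surface
    first. ``smoothed`` lets a grid driver reuse one smoothing pass across
    parcellation levels.
    """
    grid = grid or ConditionGrid()
    level = None if parcellation is None else parcellation.n_parcels
    name = condition_name(fwhm, level)
    if smoothed is None:
        smoothed = smooth_cohort(mesh, cohort, fwhm)

    if parcellation is None:
        unit_values = smoothed.thickness
        vertex_values = smoothed.thickness
    else:
        pc = parcel_average(smoothed, parcellation)
        unit_values = pc.values
        vertex_values = parcel_to_vertex(pc.values, parcellation)

    assoc = fit_age_association(unit_values, cohort.ages, alpha=grid.alpha)
    varmap = compute_cv(unit_values)
    rfield = residual_field(vertex_values, cohort.ages)
    resels = resels_surface(mesh, rfield, condition=name)

    pred = cv_predict_age(
        unit_values,
        cohort.ages,
        ks=grid.ks,
        folds=grid.folds,
        repetitions=grid.repetitions,
        seed=_condition_seed(grid.seed, fwhm, level),
        pca_policy=grid.pca_policy,
        subject_ids=cohort.subject_ids,
        condition=name,
    )
    best_k = pred.best_k
    d1 = delta1(pred.mean_predicted(best_k), cohort.ages)
    deltas = DeltaEstimates(
        delta1=d1,
        delta2=delta2(d1, cohort.ages),
        condition=name,
        k=best_k,
        subject_ids=cohort.subject_ids,
    )

    macro_cv = None
    macro_parc = macro_reference
    if macro_parc is None and parcellation is not None and parcellation.macro_labels is not None:
        macro_parc = parcellation
    if macro_parc is not None and macro_parc.macro_labels is not None:
        # mean of per-unit CVs over macro regions, computed on the surface
        cv_vertex = (
            varmap.cv
            if parcellation is None
            else parcel_to_vertex(varmap.cv, parcellation)
        )
        macro_cv = macro_aggregate(cv_vertex, macro_parc)

    return ConditionResult(
        condition=name,
        fwhm=fwhm,
        parcellation_level=level,
        association=assoc,
        variability=varmap,
        resels=resels,
        prediction=pred,
        deltas=deltas,
        macro_cv=macro_cv,
    )


def _table_row(res: ConditionResult, reference_k: int) -> dict:
    metr = res.prediction.metrics
    ref_k = reference_k if reference_k in metr.index else int(metr.index.max())
    row = {
        "condition": res.condition,
        "fwhm": res.fwhm,
        "parcellation": 0 if res.parcellation_level is None else res.parcellation_level,
        "median_r2": median_r2(res.association),
        "resels2": res.resels.resels2,
        "effective_fwhm": res.resels.effective_fwhm,
        "adj_r2_ref": metr.loc[ref_k, "adj_r2"],
        "cv_r2_ref": metr.loc[ref_k, "cv_r2"],
        "best_k": res.prediction.best_k,
        "best_rmse": metr["rmse"].min(),
    }
    if res.macro_cv is not None:
        for i, v in enumerate(res.macro_cv, start=1):
            row[f"cv_macro{i}"] = v
    return row


def run_grid(
    mesh: SurfaceMesh,
    cohort: CohortThickness,
    grid: ConditionGrid | None = None,
    out_dir: str | None = None,
) -> GridResult:
    """Execute every smoothing x parcellation condition and assemble the
    comparison table.

    Failures in one condition are recorded and the remaining conditions still
    run. With ``out_dir``, per-condition tables and a JSON run manifest are
    written as delimited text.
    """
    grid = grid or ConditionGrid()
    parcellations: dict = {}
    macro_ref = None
    for level in grid.parcellation_levels:
        if level is VERTEXWISE:
            parcellations[level] = None
        else:
            parc = make_parcellation(mesh, level, seed=grid.seed)
            parc = make_macro_regions(mesh, parc, n_macro=grid.n_macro, seed=grid.seed)
            parcellations[level] = parc
    finite = [p for p in grid.parcellation_levels if p is not VERTEXWISE]
    if finite:
        macro_ref = parcellations[min(finite)]

    rows = []
    results: dict = {}
    failures: dict = {}
    timings: dict = {}
    for fwhm in grid.smoothing_levels:
        smoothed = smooth_cohort(mesh, cohort, fwhm)
        for level in grid.parcellation_levels:
            name = condition_name(fwhm, level)
            t0 = time.perf_counter()
            try:
                res = run_condition(
                    mesh,
                    cohort,
                    fwhm,
                    parcellations[level],
                    grid=grid,
                    macro_reference=macro_ref,
                    smoothed=smoothed,
                )
            except Exception as exc:  # keep running the remaining conditions
                logger.exception("condition %s failed", name)
                failures[name] = f"{type(exc).__name__}: {exc}"
                continue
            timings[name] = time.perf_counter() - t0
            logger.info("condition %s done in %.1fs", name, timings[name])
            results[name] = res
            rows.append(_table_row(res, grid.reference_k))

    table = pd.DataFrame(rows)
    manifest = {
        "seed": grid.seed,
        "grid": {
            "smoothing_levels": list(grid.smoothing_levels),
            "parcellation_levels": [
                "vertexwise" if p is VERTEXWISE else p
                for p in grid.parcellation_levels
            ],
            "ks": [int(k) for k in grid.ks],
            "reference_k": grid.reference_k,
            "folds": grid.folds,
            "repetitions": grid.repetitions,
            "pca_policy": grid.pca_policy,
        },
        "n_subjects": cohort.n_subjects,
        "n_vertices": cohort.n_vertices,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "failures": failures,
    }
    out = GridResult(table=table, conditions=results, failures=failures,
                     manifest=manifest)
    if out_dir is not None:
        _write_grid_outputs(out, out_dir)
    return out


def _write_grid_outputs(result: GridResult, out_dir: str) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    result.table.to_csv(os.path.join(out_dir, "comparison_table.tsv"),
                        sep="\t", index=False)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    for name, res in result.conditions.items():
        cdir = os.path.join(out_dir, name)
        os.makedirs(cdir, exist_ok=True)
        pd.DataFrame(
            {
                "unit": np.arange(res.association.m),
                "r": res.association.r,
                "r2": res.association.r2,
                "t": res.association.t,
                "p": res.association.p,
                "significant": res.association.significant.astype(int),
                "mu": res.variability.mu,
                "sigma": res.variability.sigma,
                "cv": res.variability.cv,
            }
        ).to_csv(os.path.join(cdir, "association.tsv"), sep="\t", index=False)
        res.prediction.metrics.to_csv(os.path.join(cdir, "prediction.tsv"), sep="\t")
        pd.DataFrame(
            {
                "subject_id": res.deltas.subject_ids,
                "delta1": res.deltas.delta1,
                "delta2": res.deltas.delta2,
            }
        ).to_csv(os.path.join(cdir, "deltas.tsv"), sep="\t", index=False)
        with open(os.path.join(cdir, "resels.json"), "w") as fh:
            json.dump(asdict(res.resels), fh, indent=2)


def association_vs_prediction(table: pd.DataFrame) -> dict:
    """Spearman rank correlations across conditions for the three headline
    association-vs-prediction relationships.

    Returns rho for (median_r2, resels2), (adj_r2_ref, resels2) and
    (cv_r2_ref, median_r2), with the raw column pairs for plotting. A
    constant column yields a NaN (flagged undefined) correlation.
    """
    if len(table) < 4:
        raise ValueError("need at least 4 conditions")

    def rho(x, y):
        if np.ptp(table[x]) == 0 or np.ptp(table[y]) == 0:
            return float("nan")
        return float(stats.spearmanr(table[x], table[y]).statistic)

    pairs = {
        "median_r2_vs_resels2": ("median_r2", "resels2"),
        "adj_r2_vs_resels2": ("adj_r2_ref", "resels2"),
        "cv_r2_vs_median_r2": ("cv_r2_ref", "median_r2"),
    }
    out = {}
    for key, (x, y) in pairs.items():
        out[key] = {
            "spearman_rho": rho(x, y),
            "x": table[x].tolist(),
            "y": table[y].tolist(),
        }
    return out


def delta2_condition_matrix(result: GridResult) -> pd.DataFrame:
    """Cross-condition correlation matrix of delta2 vectors (all conditions)."""
    deltas = {name: res.deltas.delta2 for name, res in result.conditions.items()}
    return delta_condition_correlations(deltas)
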