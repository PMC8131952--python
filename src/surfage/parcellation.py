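"""Parcel averaging, parcel-to-vertex projection, and macro-region summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import CohortThickness, Parcellation

__all__ = [
    "ParcelCohort",
    "parcel_average",
    "parcel_to_vertex",
    "macro_aggregate",
    "parcel_membership_matrix",
]


@dataclass
class ParcelCohort:
    """Subjects x parcels matrix of parcel-mean thickness, with ages carried."""

    values: np.ndarray  # (n_subjects, P), mm
    parcellation: Parcellation
    ages: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.parcellation.n_parcels:
            raise ValueError("value columns must match parcel count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def parcel_membership_matrix(parc: Parcellation, area_weights=None) -> np.ndarray:
    """(P, V) row-stochastic averaging matrix: row p averages parcel p's vertices.

    With ``area_weights`` (per-vertex, e.g. one third of incident triangle
    area) the average is area-weighted instead of unweighted.
    """
    V = parc.labels.size
    P = parc.n_parcels
    w = np.ones(V) if area_weights is None else np.asarray(area_weights, float)
    M = np.zeros((P, V))
    M[parc.labels - 1, np.arange(V)] = w
    return M / M.sum(axis=1, keepdims=True)


def parcel_average(
    cohort: CohortThickness, parc: Parcellation, area_weights=None
) -> ParcelCohort:
    """Average each subject's thickness over every parcel.

    Unweighted vertex means by default (the usual convention on quasi-uniform
    surface meshes); pass per-vertex ``area_weights`` for area weighting.
    """
    if parc.labels.size != cohort.n_vertices:
        raise ValueError("parcellation does not match cohort vertices")
    M = parcel_membership_matrix(parc, area_weights)
    return ParcelCohort(
        values=cohort.thickness @ M.T,
        parcellation=parc,
        ages=cohort.ages,
        subject_ids=cohort.subject_ids,
    )


def parcel_to_vertex(parcel_values: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Project per-parcel values back to the surface (piecewise constant).

    Works on a (P,) vector or an (n, P) matrix; returns (V,) or (n, V).
    """
    parcel_values = np.asarray(parcel_values, dtype=np.float64)
    if parcel_values.shape[-1] != parc.n_parcels:
        raise ValueError("last axis must match the parcel count")
    return parcel_values[..., parc.labels - 1]


def macro_aggregate(unit_values: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Unweighted mean of per-vertex or per-parcel values over macro regions.

    Accepts values of length V (vertexwise) or P (parcelwise); returns one
    mean per macro region, ordered by region label.
    """
    if parc.macro_labels is None:
        raise ValueError("parcellation has no macro-region map")
    unit_values = np.asarray(unit_values, dtype=np.float64)
    if unit_values.shape[-1] == parc.labels.size:
        region_of_unit = parc.vertex_macro_labels()
    elif unit_values.shape[-1] == parc.n_parcels:
        region_of_unit = parc.macro_labels
    else:
        raise ValueError("values must be per-vertex or per-parcel")
    n_macro = int(parc.macro_labels.max())
    out = np.empty(unit_values.shape[:-1] + (n_macro,))
    for r in range(1, n_macro + 1):
        out[..., r - 1] = unit_values[..., region_of_unit == r].mean(axis=-1)
    return out
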