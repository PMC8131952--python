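"""Synthetic cortical cohorts with known ground truth.

The generator emulates the statistical structure of a cross-sectional aging
cohort measured on a cortical surface: a smooth baseline thickness map, a
small number of spatially localized latent aging components with subject-level
heterogeneity, a global per-subject offset, and fine-grained per-vertex
measurement noise. Ages are near-uniform over the adult lifespan, matching
the age structure of large population-based imaging cohorts (N around 600,
ages 18-88, mean about 53).

The latent components are geodesic Gaussian bumps placed by farthest-point
sampling, so age-informative structure is spatially fine relative to the
smoothing kernels under study: surface smoothing merges components (raising
regional correlations with age) while destroying the independent modes that
drive individual-level age prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import SurfaceMesh, edge_list, mean_edge_length
from .smoothing import fwhm_to_sigma

__all__ = [
    "CohortSpec",
    "CohortThickness",
    "GroundTruth",
    "Parcellation",
    "make_icosphere",
    "make_parcellation",
    "make_macro_regions",
    "sample_ages",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "write_parcellation",
    "read_parcellation",
]


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects : int
        Cohort size (>= 10).
    age_low, age_high : float
        Age range in years; ages are sampled uniformly.
    n_components : int
        Number K of latent aging components.
    pattern_scale : float or None
        Spatial extent (geodesic FWHM, mm) of each component map; None means
        6x the mesh mean edge length.
    component_age_loading : array or None
        Per-component age slopes at bump peak, mm/year. None samples
        magnitudes uniformly in [0.008, 0.02] mm/year, all negative:
        adult-lifespan cortical thinning is near-universal across the
        cortex, with regionally varying rates, and the shared direction
        makes the leading principal component of thickness age-informative
        as in real cohorts.
    latent_noise_sd : float
        SD of per-subject component-score noise (mm at bump peak).
    global_offset_sd : float
        SD of the per-subject global thickness offset (mm).
    vertex_noise_sd : float
        SD of i.i.d. per-vertex measurement noise (mm).
    baseline_mean_range : (float, float)
        Range (mm) the smooth baseline map must stay within.
    seed : int
        Generator seed; identical seeds give bit-identical cohorts.
    """

    n_subjects: int = 300
    age_low: float = 18.0
    age_high: float = 88.0
    n_components: int = 12
    pattern_scale: float | None = None
    component_age_loading: np.ndarray | None = None
    latent_noise_sd: float = 0.5
    global_offset_sd: float = 0.15
    vertex_noise_sd: float = 0.35
    baseline_mean_range: tuple[float, float] = (1.5, 4.5)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if not self.age_high > self.age_low:
            raise ValueError("age_high must exceed age_low")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        for name in ("latent_noise_sd", "global_offset_sd", "vertex_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.baseline_mean_range
        if not (0 < lo < hi):
            raise ValueError("baseline_mean_range must satisfy 0 < low < high")


@dataclass
class CohortThickness:
    """Subjects x vertices thickness matrix with ages, on a reference mesh."""

    thickness: np.ndarray  # (n_subjects, V), mm
    ages: np.ndarray  # (n_subjects,), years
    subject_ids: np.ndarray  # (n_subjects,) str labels
    mesh: SurfaceMesh | None = None

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=np.float64)
        self.ages = np.asarray(self.ages, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.thickness.shape[0] != self.ages.shape[0]:
            raise ValueError("thickness rows must match number of ages")
        if self.subject_ids.shape[0] != self.ages.shape[0]:
            raise ValueError("subject_ids must match number of ages")
        if self.mesh is not None and self.thickness.shape[1] != self.mesh.n_vertices:
            raise ValueError("thickness columns must match mesh vertices")

    @property
    def n_subjects(self) -> int:
        return self.thickness.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.thickness.shape[1]

    def with_thickness(self, thickness: np.ndarray) -> "CohortThickness":
        return CohortThickness(thickness, self.ages, self.subject_ids, self.mesh)


@dataclass
class GroundTruth:
    """Generator internals enabling parameter-recovery tests.

    ``expected_slope`` is the analytic derivative of the mean thickness with
    respect to age: expected_slope(v) = sum_k component_maps[v, k] *
    age_loadings[k], in mm/year.
    """

    component_maps: np.ndarray  # (V, K), unit peak
    age_loadings: np.ndarray  # (K,), mm/year at bump peak
    baseline: np.ndarray  # (V,), mm
    component_centers: np.ndarray = field(default=None)  # (K,) vertex indices

    @property
    def expected_slope(self) -> np.ndarray:
        return self.component_maps @ self.age_loadings


@dataclass
class Parcellation:
    """Per-vertex parcel labels in [1, P], optionally grouped into macro regions."""

    labels: np.ndarray  # (V,), int in [1, P]
    n_parcels: int
    macro_labels: np.ndarray | None = None  # (P,), int in [1, n_macro]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        counts = np.bincount(self.labels, minlength=self.n_parcels + 1)[1:]
        if (counts == 0).any():
            empty = np.where(counts == 0)[0] + 1
            raise ValueError(f"empty parcels: {empty.tolist()}")
        if self.labels.min() < 1 or self.labels.max() > self.n_parcels:
            raise ValueError("labels must lie in [1, n_parcels]")

    @property
    def n_macro(self) -> int | None:
        if self.macro_labels is None:
            return None
        return int(self.macro_labels.max())

    def vertex_macro_labels(self) -> np.ndarray:
        """Macro-region label per vertex."""
        if self.macro_labels is None:
            raise ValueError("parcellation has no macro-region map")
        return self.macro_labels[self.labels - 1]


# ---------------------------------------------------------------------------
# Icosphere

_PHI = (1.0 + np.sqrt(5.0)) / 2.0

_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=np.float64,
)

_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(subdivisions: int, radius: float = 1.0) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times and projected to a sphere.

    V = 10 * 4**s + 2 vertices, all at distance ``radius`` from the origin.
    """
    if not 0 <= subdivisions <= 7:
        raise ValueError("subdivisions must be in [0, 7]")
    verts = _ICO_VERTS.copy()
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        edges = np.unique(
            np.sort(
                np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]]),
                axis=1,
            ),
            axis=0,
        )
        mid_index = {
            (int(a), int(b)): len(verts) + i for i, (a, b) in enumerate(edges)
        }
        midpoints = 0.5 * (verts[edges[:, 0]] + verts[edges[:, 1]])
        verts = np.vstack([verts, midpoints])

        new_faces = []
        for a, b, c in faces:
            ab = mid_index[tuple(sorted((int(a), int(b))))]
            bc = mid_index[tuple(sorted((int(b), int(c))))]
            ca = mid_index[tuple(sorted((int(a), int(c))))]
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        faces = np.array(new_faces, dtype=np.int64)

    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return SurfaceMesh(verts, faces, name=f"icosphere_s{subdivisions}_r{radius:g}")


# ---------------------------------------------------------------------------
# Geodesic machinery (graph shortest paths over edge lengths)

def _edge_graph(mesh: SurfaceMesh) -> csr_matrix:
    edges = edge_list(mesh)
    w = np.linalg.norm(
        mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1
    )
    V = mesh.n_vertices
    row = np.concatenate([edges[:, 0], edges[:, 1]])
    col = np.concatenate([edges[:, 1], edges[:, 0]])
    return csr_matrix((np.concatenate([w, w]), (row, col)), shape=(V, V))


def geodesic_distances(mesh: SurfaceMesh, sources: np.ndarray) -> np.ndarray:
    """Graph-geodesic distance from each source vertex to every vertex.

    Returns an (len(sources), V) array. Approximates true surface geodesics
    by shortest paths along mesh edges.
    """
    graph = _edge_graph(mesh)
    return dijkstra(graph, directed=False, indices=np.asarray(sources))


def farthest_point_sample(
    mesh: SurfaceMesh, n_points: int, seed: int, graph: csr_matrix | None = None
) -> np.ndarray:
    """Greedy farthest-point sampling of vertices under graph-geodesic distance."""
    V = mesh.n_vertices
    if not 1 <= n_points <= V:
        raise ValueError("n_points must be in [1, V]")
    if graph is None:
        graph = _edge_graph(mesh)
    rng = np.random.default_rng(seed)
    seeds = [int(rng.integers(V))]
    dist = dijkstra(graph, directed=False, indices=seeds[0])
    for _ in range(n_points - 1):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, dijkstra(graph, directed=False, indices=nxt))
    return np.array(seeds, dtype=np.int64)


def make_parcellation(mesh: SurfaceMesh, n_parcels: int, seed: int) -> Parcellation:
    """Geodesic Voronoi parcellation from farthest-point-sampled seeds.

    Every parcel is non-empty and connected in the mesh graph (a shortest-path
    Voronoi cell is connected by construction). Deterministic given ``seed``.
    """
    V = mesh.n_vertices
    if n_parcels > V:
        raise ValueError("n_parcels cannot exceed the number of vertices")
    graph = _edge_graph(mesh)
    seeds = farthest_point_sample(mesh, n_parcels, seed, graph=graph)
    _, _, sources = dijkstra(
        graph, directed=False, indices=seeds, min_only=True,
        return_predecessors=True,
    )
    seed_to_label = {int(s): i + 1 for i, s in enumerate(seeds)}
    labels = np.array([seed_to_label[int(s)] for s in sources], dtype=np.int64)
    return Parcellation(labels=labels, n_parcels=n_parcels)


def make_macro_regions(
    mesh: SurfaceMesh, parc: Parcellation, n_macro: int = 7, seed: int = 0
) -> Parcellation:
    """Group parcels into ``n_macro`` contiguous macro regions.

    Parcel centroids are clustered by farthest-point seeding followed by
    nearest-seed assignment (Euclidean between centroids; adequate on
    quasi-uniform closed surfaces). With n_macro = P this is the identity
    grouping.
    """
    P = parc.n_parcels
    if n_macro > P:
        raise ValueError("n_macro cannot exceed the number of parcels")
    centroids = np.empty((P, 3))
    for p in range(P):
        centroids[p] = mesh.vertices[parc.labels == p + 1].mean(axis=0)
    if n_macro == P:
        macro = np.arange(1, P + 1, dtype=np.int64)
    else:
        rng = np.random.default_rng(seed)
        seeds = [int(rng.integers(P))]
        d = np.linalg.norm(centroids - centroids[seeds[0]], axis=1)
        for _ in range(n_macro - 1):
            nxt = int(np.argmax(d))
            seeds.append(nxt)
            d = np.minimum(d, np.linalg.norm(centroids - centroids[nxt], axis=1))
        seed_pts = centroids[seeds]
        dists = np.linalg.norm(
            centroids[:, None, :] - seed_pts[None, :, :], axis=2
        )
        macro = np.argmin(dists, axis=1).astype(np.int64) + 1
    return Parcellation(labels=parc.labels, n_parcels=P, macro_labels=macro)


# ---------------------------------------------------------------------------
# Cohort generation

def sample_ages(n: int, low: float, high: float, seed: int) -> np.ndarray:
    """I.i.d. uniform ages on [low, high]; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n)


def _baseline_map(mesh: SurfaceMesh, mean_range: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Smooth baseline thickness filling the central 60% of the allowed range."""
    lo, hi = mean_range
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    a = rng.standard_normal(3)
    b = rng.standard_normal(3)
    raw = u @ a + (u @ b) ** 2
    raw = raw - raw.min()
    span = raw.max()
    if span < 1e-12:
        return np.full(mesh.n_vertices, 0.5 * (lo + hi))
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    return mid - 0.6 * half + 1.2 * half * raw / span


def simulate_cohort(
    mesh: SurfaceMesh, spec: CohortSpec
) -> tuple[CohortThickness, GroundTruth]:
    """Generate a thickness cohort with known per-vertex aging structure.

    Model per subject i and vertex v, with z the age standardized by the spec
    midpoint and half-range (so ground-truth slopes do not depend on the
    realized sample)::

        T_i(v) = mu(v) + sum_k p_k(v) * (beta_k * z_i + eta_ik) + gamma_i + eps_iv

    where p_k are geodesic Gaussian bumps of FWHM ``pattern_scale`` centred at
    farthest-point-spread vertices, eta ~ N(0, latent_noise_sd^2),
    gamma ~ N(0, global_offset_sd^2), eps ~ N(0, vertex_noise_sd^2). beta_k in
    mm per z-unit corresponds to an age slope of beta_k / half_range mm/year
    at the bump peak.

    Thickness is strictly positive: cortex has a hard physical lower bound,
    so values are floored at 0.1 mm. With the default parameters the floor
    is essentially never active (zero to a handful of cells per cohort). If
    more than 1% of cells would be floored, the noise is redrawn with tails
    truncated at 3 SD; a spec that still floors more than 1% of cells is
    rejected with an error.
    """
    _FLOOR_MM = 0.1
    _MAX_FLOOR_FRACTION = 0.01
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    V = mesh.n_vertices
    K = spec.n_components
    half_range = 0.5 * (spec.age_high - spec.age_low)
    mid = 0.5 * (spec.age_high + spec.age_low)

    pattern_fwhm = spec.pattern_scale
    if pattern_fwhm is None:
        pattern_fwhm = 6.0 * mean_edge_length(mesh)
    sigma_p = fwhm_to_sigma(pattern_fwhm)

    centers = farthest_point_sample(mesh, K, seed=int(rng.integers(2**31)))
    dists = geodesic_distances(mesh, centers)  # (K, V)
    if sigma_p > 0:
        component_maps = np.exp(-0.5 * (dists.T / sigma_p) ** 2)  # (V, K)
    else:
        component_maps = (dists.T == 0).astype(np.float64)

    if spec.component_age_loading is not None:
        loadings_per_year = np.asarray(spec.component_age_loading, dtype=np.float64)
        if loadings_per_year.shape != (K,):
            raise ValueError("component_age_loading must have length n_components")
    else:
        loadings_per_year = -rng.uniform(0.008, 0.02, size=K)
    beta_z = loadings_per_year * half_range  # mm per z-unit

    baseline = _baseline_map(mesh, spec.baseline_mean_range, rng)
    ages = rng.uniform(spec.age_low, spec.age_high, size=spec.n_subjects)
    z = (ages - mid) / half_range

    def draw(clip: float | None) -> np.ndarray:
        # child streams keep the redraw independent of array shapes
        r = np.random.default_rng(rng.integers(2**31))
        eta = r.standard_normal((spec.n_subjects, K))
        gamma = r.standard_normal(spec.n_subjects)
        eps = r.standard_normal((spec.n_subjects, V))
        if clip is not None:
            eta = np.clip(eta, -clip, clip)
            gamma = np.clip(gamma, -clip, clip)
            eps = np.clip(eps, -clip, clip)
        scores = beta_z[None, :] * z[:, None] + spec.latent_noise_sd * eta
        return (
            baseline[None, :]
            + scores @ component_maps.T
            + spec.global_offset_sd * gamma[:, None]
            + spec.vertex_noise_sd * eps
        )

    thickness = draw(clip=None)
    frac_low = (thickness < _FLOOR_MM).mean()
    if frac_low > _MAX_FLOOR_FRACTION:
        thickness = draw(clip=3.0)
        frac_low = (thickness < _FLOOR_MM).mean()
        if frac_low > _MAX_FLOOR_FRACTION:
            raise ValueError(
                "cohort spec drives thickness to the physical floor on "
                f"{100 * frac_low:.1f}% of cells even with truncated noise"
            )
    thickness = np.maximum(thickness, _FLOOR_MM)

    subject_ids = np.array([f"sub-{i:04d}" for i in range(spec.n_subjects)])
    cohort = CohortThickness(thickness, ages, subject_ids, mesh)
    truth = GroundTruth(
        component_maps=component_maps,
        age_loadings=loadings_per_year,
        baseline=baseline,
        component_centers=centers,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Delimited-text I/O

def write_cohort(cohort: CohortThickness, thickness_path: str, ages_path: str) -> None:
    """Write thickness (subjects x vertices, vertex-id header) and ages tables."""
    tdf = pd.DataFrame(
        cohort.thickness,
        index=pd.Index(cohort.subject_ids, name="subject_id"),
        columns=[f"v{j}" for j in range(cohort.n_vertices)],
    )
    tdf.to_csv(thickness_path, sep="\t", float_format="%.6f")
    adf = pd.DataFrame({"subject_id": cohort.subject_ids, "age": cohort.ages})
    adf.to_csv(ages_path, sep="\t", index=False, float_format="%.4f")


def read_cohort(
    thickness_path: str, ages_path: str, mesh: SurfaceMesh | None = None
) -> CohortThickness:
    tdf = pd.read_csv(thickness_path, sep="\t", index_col=0)
    adf = pd.read_csv(ages_path, sep="\t").set_index("subject_id")
    ages = adf.loc[tdf.index, "age"].to_numpy()
    return CohortThickness(tdf.to_numpy(), ages, tdf.index.to_numpy(), mesh)


def write_parcellation(parc: Parcellation, path: str) -> None:
    df = pd.DataFrame(
        {"vertex_id": np.arange(parc.labels.size), "label": parc.labels}
    )
    if parc.macro_labels is not None:
        df["macro_label"] = parc.vertex_macro_labels()
    df.to_csv(path, sep="\t", index=False)


def read_parcellation(path: str) -> Parcellation:
    df = pd.read_csv(path, sep="\t").sort_values("vertex_id")
    labels = df["label"].to_numpy()
    P = int(labels.max())
    macro = None
    if "macro_label" in df.columns:
        vm = df["macro_label"].to_numpy()
        macro = np.zeros(P, dtype=np.int64)
        macro[labels - 1] = vm
    return Parcellation(labels=labels, n_parcels=P, macro_labels=macro)
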