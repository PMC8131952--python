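import numpy as np
import pytest

import surfage as sa
from surfage.synthetic import (
    farthest_point_sample,
    geodesic_distances,
    read_cohort,
    read_parcellation,
    write_cohort,
    write_parcellation,
)


@pytest.mark.parametrize("s, expected_v", [(0, 12), (2, 162), (4, 2562)])
def test_icosphere_vertex_count_closed_form(s, expected_v):
    mesh = sa.make_icosphere(s)
    assert mesh.n_vertices == expected_v
    assert mesh.euler_characteristic() == 2


def test_icosphere_vertices_on_sphere():
    mesh = sa.make_icosphere(3, 42.0)
    radii = np.linalg.norm(mesh.vertices, axis=1)
    assert np.abs(radii - 42.0).max() < 1e-9


def test_icosphere_rejects_excessive_subdivision():
    with pytest.raises(ValueError):
        sa.make_icosphere(8)


class TestParcellation:
    def test_single_parcel_covers_everything(self, sphere_s3):
        parc = sa.make_parcellation(sphere_s3, 1, seed=0)
        assert (parc.labels == 1).all()

    def test_one_parcel_per_vertex_is_a_permutation(self):
        mesh = sa.make_icosphere(1)
        parc = sa.make_parcellation(mesh, mesh.n_vertices, seed=0)
        assert sorted(parc.labels) == list(range(1, mesh.n_vertices + 1))

    def test_parcels_nonempty_connected_and_deterministic(self, sphere_s3):
        parc = sa.make_parcellation(sphere_s3, 40, seed=3)
        again = sa.make_parcellation(sphere_s3, 40, seed=3)
        assert np.array_equal(parc.labels, again.labels)
        counts = np.bincount(parc.labels, minlength=41)[1:]
        assert (counts > 0).all()
        # connectivity: BFS within each parcel reaches all its vertices
        from surfage.mesh import vertex_neighbors

        neigh = vertex_neighbors(sphere_s3)
        for p in range(1, 41):
            members = set(np.where(parc.labels == p)[0])
            start = next(iter(members))
            seen, stack = {start}, [start]
            while stack:
                v = stack.pop()
                for u in neigh[v]:
                    if u in members and u not in seen:
                        seen.add(u)
                        stack.append(u)
            assert seen == members, f"parcel {p} is disconnected"

    def test_too_many_parcels_rejected(self, icosahedron):
        with pytest.raises(ValueError):
            sa.make_parcellation(icosahedron, 13, seed=0)


class TestMacroRegions:
    def test_identity_grouping_when_n_macro_equals_p(self, sphere_s3):
        parc = sa.make_parcellation(sphere_s3, 10, seed=1)
        macro = sa.make_macro_regions(sphere_s3, parc, n_macro=10, seed=1)
        assert np.array_equal(macro.macro_labels, np.arange(1, 11))

    def test_seven_regions_each_nonempty_and_reproducible(self, sphere_s3):
        parc = sa.make_parcellation(sphere_s3, 40, seed=2)
        m1 = sa.make_macro_regions(sphere_s3, parc, n_macro=7, seed=5)
        m2 = sa.make_macro_regions(sphere_s3, parc, n_macro=7, seed=5)
        assert np.array_equal(m1.macro_labels, m2.macro_labels)
        counts = np.bincount(m1.macro_labels, minlength=8)[1:]
        assert (counts >= 1).all()
        assert m1.n_macro == 7


class TestAges:
    def test_degenerate_range_gives_constant_ages(self):
        ages = sa.sample_ages(20, 50, 50, seed=0)
        assert (ages == 50).all()

    def test_uniform_moments_and_bounds(self):
        ages = sa.sample_ages(608, 18, 88, seed=0)
        assert ages.min() >= 18 and ages.max() <= 88
        # population mean of U(18, 88) is 53; n=608 keeps the sample close
        assert abs(ages.mean() - 53.0) < 3.0

    def test_deterministic_given_seed(self):
        assert np.array_equal(sa.sample_ages(50, 18, 88, 7), sa.sample_ages(50, 18, 88, 7))


class TestSimulateCohort:
    def test_noiseless_zero_loading_reproduces_baseline(self, sphere_s3):
        spec = sa.CohortSpec(
            n_subjects=20, n_components=1, component_age_loading=np.array([0.0]),
            latent_noise_sd=0, global_offset_sd=0, vertex_noise_sd=0, seed=0,
        )
        cohort, truth = sa.simulate_cohort(sphere_s3, spec)
        assert np.allclose(cohort.thickness, truth.baseline[None, :])
        assert cohort.thickness.std(axis=0).max() < 1e-12

    def test_noiseless_linear_model_gives_unit_correlation_on_support(self, sphere_s3):
        spec = sa.CohortSpec(
            n_subjects=30, n_components=1, component_age_loading=np.array([-0.01]),
            latent_noise_sd=0, global_offset_sd=0, vertex_noise_sd=0, seed=0,
        )
        cohort, truth = sa.simulate_cohort(sphere_s3, spec)
        support = truth.component_maps[:, 0] > 0.05
        am = sa.fit_age_association(cohort.thickness[:, support], cohort.ages)
        assert np.abs(am.r).min() > 1 - 1e-9

    def test_expected_slope_is_analytic_derivative(self, sphere_s3):
        """Ground-truth slope equals the finite difference of the mean model."""
        spec = sa.CohortSpec(
            n_subjects=10, n_components=3, latent_noise_sd=0,
            global_offset_sd=0, vertex_noise_sd=0, seed=4,
        )
        _, truth = sa.simulate_cohort(sphere_s3, spec)
        half = 0.5 * (spec.age_high - spec.age_low)
        beta_z = truth.age_loadings * half

        def mean_thickness(age):
            z = (age - 0.5 * (spec.age_high + spec.age_low)) / half
            return truth.baseline + truth.component_maps @ (beta_z * z)

        fd = (mean_thickness(60.0) - mean_thickness(50.0)) / 10.0
        assert np.abs(fd - truth.expected_slope).max() < 1e-12

    def test_same_seed_bit_identical(self, sphere_s3):
        a, _ = sa.simulate_cohort(sphere_s3, sa.CohortSpec(n_subjects=30, seed=9))
        b, _ = sa.simulate_cohort(sphere_s3, sa.CohortSpec(n_subjects=30, seed=9))
        assert np.array_equal(a.thickness, b.thickness)
        assert np.array_equal(a.ages, b.ages)

    def test_thickness_strictly_positive(self, default_cohort):
        cohort, _ = default_cohort
        assert cohort.thickness.min() > 0

    def test_invalid_spec_rejected(self, sphere_s3):
        with pytest.raises(ValueError):
            sa.CohortSpec(n_subjects=5).validate()
        with pytest.raises(ValueError):
            sa.CohortSpec(age_low=88, age_high=18).validate()


def test_geodesic_distance_matches_arc_on_sphere(sphere_s3):
    """Graph geodesics approximate great-circle arcs (within a few %)."""
    d = geodesic_distances(sphere_s3, np.array([0]))[0]
    u = sphere_s3.vertices / 30.0
    arc = 30.0 * np.arccos(np.clip(u @ u[0], -1, 1))
    far = arc > 10
    ratio = d[far] / arc[far]
    assert ratio.min() > 0.999  # graph paths can only be longer
    # lattice-direction overhead on a triangulated sphere stays below ~2/sqrt(3)
    assert ratio.max() < 1.20


def test_farthest_point_sample_is_spread_out(sphere_s3):
    seeds = farthest_point_sample(sphere_s3, 10, seed=0)
    assert len(set(seeds.tolist())) == 10
    pairwise = geodesic_distances(sphere_s3, seeds)[:, seeds].copy()
    np.fill_diagonal(pairwise, np.inf)
    # every pair of seeds is farther apart than one edge
    assert pairwise.min() > 5.0


def test_cohort_and_parcellation_text_roundtrip(tmp_path, sphere_s3):
    cohort, _ = sa.simulate_cohort(sphere_s3, sa.CohortSpec(n_subjects=12, seed=2))
    write_cohort(cohort, tmp_path / "t.tsv", tmp_path / "a.tsv")
    back = read_cohort(tmp_path / "t.tsv", tmp_path / "a.tsv", sphere_s3)
    assert np.abs(back.thickness - cohort.thickness).max() < 1e-5
    assert np.abs(back.ages - cohort.ages).max() < 1e-3
    assert list(back.subject_ids) == list(cohort.subject_ids)

    parc = sa.make_macro_regions(
        sphere_s3, sa.make_parcellation(sphere_s3, 20, seed=1), seed=1
    )
    write_parcellation(parc, tmp_path / "p.tsv")
    pback = read_parcellation(tmp_path / "p.tsv")
    assert np.array_equal(pback.labels, parc.labels)
    assert np.array_equal(pback.macro_labels, parc.macro_labels)
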