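"""K-means pixel classifier and the classification-based index (TIC)."""

import numpy as np
import pytest
from sklearn.cluster import KMeans as SKKMeans

from spherotrack import (
    BorderPixelError,
    ChannelImage,
    ClassMap,
    DegenerateInputError,
    LayoutError,
    PixelClassifier,
    RoleAssignmentError,
    SyntheticParams,
    assign_roles,
    build_training_sample,
    classify_pixels,
    compute_tic,
    kmeans_train,
    neighborhood_majority,
    write_synthetic_experiment,
)
from spherotrack.tic import BACKGROUND, IMMUNE, ROLES, SATURATED, TUMOUR

from .conftest import tic_oracle


def four_clouds(seed=0, spread=3.0, n=200):
    """Well-separated clouds at the four canonical colour corners."""
    rng = np.random.default_rng(seed)
    centers = np.array([(10, 10), (20, 200), (200, 20), (250, 250)], float)
    pts = np.concatenate(
        [c + rng.uniform(-spread, spread, size=(n, 2)) for c in centers]
    )
    return pts, centers


class TestKMeansTrain:
    def test_k1_recovers_coordinatewise_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 255, size=(100, 2))
        clf = kmeans_train(pts, k=1, seed=0)
        np.testing.assert_allclose(clf.centroids[0], pts.mean(axis=0), atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 7])
    def test_recovers_generating_centres_of_four_clouds(self, seed):
        pts, centers = four_clouds(seed=seed)
        clf = kmeans_train(pts, k=4, seed=seed)
        ordered = centers[np.lexsort((centers[:, 1], centers[:, 0]))]
        assert np.max(np.abs(clf.centroids - ordered)) <= 3.0

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 255, size=(500, 2))
        clf = kmeans_train(pts, k=4, seed=2, n_init=1)
        hist = np.asarray(clf.objective_history)
        assert (np.diff(hist) <= 1e-6).all()

    def test_matches_sklearn_on_separated_clouds(self):
        """Independent cross-check: sklearn's k-means lands on the same
        centroids for well-separated data."""
        pts, _ = four_clouds(seed=3)
        ours = kmeans_train(pts, k=4, seed=3)
        sk = SKKMeans(n_clusters=4, n_init=10, tol=1e-9, random_state=3).fit(pts)
        theirs = sk.cluster_centers_
        theirs = theirs[np.lexsort((theirs[:, 1], theirs[:, 0]))]
        np.testing.assert_allclose(ours.centroids, theirs, atol=0.5)

    def test_too_few_distinct_points_rejected(self):
        pts = np.tile([[5.0, 5.0], [9.0, 9.0]], (10, 1))
        with pytest.raises(DegenerateInputError):
            kmeans_train(pts, k=4)

    def test_deterministic_under_seed(self):
        pts, _ = four_clouds(seed=4)
        a = kmeans_train(pts, k=4, seed=11)
        b = kmeans_train(pts, k=4, seed=11)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.n_iterations_run == b.n_iterations_run


class TestAssignRoles:
    def test_rule_on_canonical_centroids(self):
        clf = PixelClassifier(
            centroids=np.array([(5, 6), (30, 210), (215, 35), (252, 251)], float)
        )
        named = assign_roles(clf)
        roles = dict(zip(map(tuple, named.centroids), named.roles))
        assert roles[(5.0, 6.0)] == "background"
        assert roles[(30.0, 210.0)] == "tumour"
        assert roles[(215.0, 35.0)] == "immune"
        assert roles[(252.0, 251.0)] == "saturated"

    def test_invariant_to_input_order(self):
        base = np.array([(5, 6), (30, 210), (215, 35), (252, 251)], float)
        a = assign_roles(PixelClassifier(centroids=base))
        b = assign_roles(PixelClassifier(centroids=base[::-1]))
        assert dict(zip(map(tuple, a.centroids), a.roles)) == dict(
            zip(map(tuple, b.centroids), b.roles)
        )

    def test_no_truly_saturated_centroid_falls_back_to_brightest(self):
        # two red-dominant centroids, none near the ceiling: the brightest
        # becomes the saturated class, the other red-dominant one immune
        clf = PixelClassifier(
            centroids=np.array([(5, 5), (40, 180), (180, 40), (220, 120)], float)
        )
        named = assign_roles(clf)
        roles = dict(zip(map(tuple, named.centroids), named.roles))
        assert roles[(220.0, 120.0)] == "saturated"
        assert roles[(180.0, 40.0)] == "immune"
        assert roles[(40.0, 180.0)] == "tumour"

    def test_roles_must_be_bijection(self):
        with pytest.raises(RoleAssignmentError):
            PixelClassifier(
                centroids=np.zeros((4, 2)),
                roles=("immune", "immune", "tumour", "background"),
            )


class TestClassifyPixels:
    def _named(self):
        return assign_roles(
            PixelClassifier(
                centroids=np.array(
                    [(10, 10), (60, 180), (220, 30), (255, 255)], float
                )
            )
        )

    def test_uniform_image_fully_one_class(self):
        clf = self._named()
        red = ChannelImage(np.full((5, 5), 60, np.uint8), "red")
        green = ChannelImage(np.full((5, 5), 180, np.uint8), "green")
        cmap = classify_pixels(clf, red, green)
        assert cmap.counts["tumour"] == 25

    def test_counts_conserve_total(self):
        clf = self._named()
        rng = np.random.default_rng(0)
        red = ChannelImage(rng.integers(0, 256, (30, 20), dtype=np.uint8), "red")
        green = ChannelImage(rng.integers(0, 256, (30, 20), dtype=np.uint8), "green")
        cmap = classify_pixels(clf, red, green)
        assert sum(cmap.counts.values()) == 600

    def test_equidistant_pixel_goes_to_lower_sorted_centroid(self):
        clf = assign_roles(
            PixelClassifier(centroids=np.array(
                [(0, 0), (0, 100), (100, 0), (255, 255)], float
            ))
        )
        # (0, 50) is equidistant from (0, 0) and (0, 100); (0, 0) sorts first
        red = ChannelImage(np.array([[0]], np.uint8), "red")
        green = ChannelImage(np.array([[50]], np.uint8), "green")
        cmap = classify_pixels(clf, red, green)
        assert ROLES[cmap.classes[0, 0]] == clf.roles[0]

    def test_unassigned_roles_rejected(self):
        clf = PixelClassifier(centroids=np.zeros((4, 2)) + [[0, 0], [1, 1], [2, 2], [3, 3]])
        red = ChannelImage(np.zeros((2, 2), np.uint8), "red")
        with pytest.raises(RoleAssignmentError):
            classify_pixels(clf, red, ChannelImage(np.zeros((2, 2), np.uint8), "green"))


class TestNeighborhoodMajority:
    def test_uniform_window(self):
        cmap = ClassMap(np.full((15, 15), TUMOUR, np.uint8))
        assert neighborhood_majority(cmap, (7, 7)) == "tumour"

    def test_immune_centre_surrounded_by_tumour(self):
        classes = np.full((15, 15), TUMOUR, np.uint8)
        classes[7, 7] = IMMUNE
        assert neighborhood_majority(ClassMap(classes), (7, 7)) == "tumour"

    def test_exact_tie_is_none_majority(self):
        # 60 tumour / 60 immune around the centre of an 11x11 window
        classes = np.full((11, 11), TUMOUR, np.uint8)
        classes[: 5, :] = IMMUNE           # 55 immune
        classes[5, :5] = IMMUNE            # 5 more -> 60, centre row
        classes[5, 5] = BACKGROUND         # centre excluded anyway
        counts = np.bincount(classes.ravel(), minlength=4)
        assert counts[IMMUNE] == 60 and counts[TUMOUR] == 60
        assert neighborhood_majority(ClassMap(classes), (5, 5), window=11) is None

    def test_border_pixel_raises(self):
        cmap = ClassMap(np.zeros((12, 12), np.uint8))
        with pytest.raises(BorderPixelError):
            neighborhood_majority(cmap, (2, 6), window=11)


class TestComputeTIC:
    def test_all_tumour_has_no_immune_hence_zero(self):
        res = compute_tic(ClassMap(np.full((20, 20), TUMOUR, np.uint8)))
        assert res.tic == 0.0
        assert res.immune_in_tumour == 0
        assert res.cancer_in_tumour > 0

    def test_all_background_is_degenerate_zero(self):
        res = compute_tic(ClassMap(np.full((20, 20), BACKGROUND, np.uint8)))
        assert res.tic == 0.0 and res.degenerate

    def test_single_immune_pixel_matches_bruteforce(self):
        classes = np.full((25, 25), TUMOUR, np.uint8)
        classes[12, 12] = IMMUNE
        res = compute_tic(ClassMap(classes))
        immune_in, cancer_in = tic_oracle(classes)
        assert (res.immune_in_tumour, res.cancer_in_tumour) == (immune_in, cancer_in)
        assert res.tic == pytest.approx(1 / (1 + cancer_in))

    @pytest.mark.parametrize("seed", range(4))
    def test_random_class_maps_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        classes = rng.integers(0, 4, size=(30, 30), dtype=np.uint8)
        res = compute_tic(ClassMap(classes))
        immune_in, cancer_in = tic_oracle(classes)
        assert (res.immune_in_tumour, res.cancer_in_tumour) == (immune_in, cancer_in)
        assert 0.0 <= res.tic <= 1.0
        assert res.excluded_border == 30 * 30 - 20 * 20

    def test_saturated_patch_pixels_enter_no_count(self):
        """A (255,255) patch inside the tumour: its own pixels contribute to
        neither the immune nor the cancer count."""
        base = np.full((31, 31), TUMOUR, np.uint8)
        base[14, 14] = IMMUNE
        with_patch = base.copy()
        with_patch[20:23, 20:23] = SATURATED
        r0 = compute_tic(ClassMap(base))
        r1 = compute_tic(ClassMap(with_patch))
        # patch pixels leave the cancer count (they are no longer tumour) but
        # never join either count as saturated pixels
        immune_in, cancer_in = tic_oracle(with_patch)
        assert (r1.immune_in_tumour, r1.cancer_in_tumour) == (immune_in, cancer_in)
        assert r1.immune_in_tumour == r0.immune_in_tumour
        assert r1.cancer_in_tumour <= r0.cancer_in_tumour

    def test_image_smaller_than_window_all_border(self):
        res = compute_tic(ClassMap(np.full((8, 8), TUMOUR, np.uint8)), window=11)
        assert res.degenerate and res.excluded_border == 64


class TestTrainingSample:
    def test_sample_shape_and_determinism(self, tmp_path):
        layout, _ = write_synthetic_experiment(
            tmp_path, ["a", "b"], [24, 48],
            SyntheticParams(image_size=64, spheroid_radius=15,
                            n_immune_cells=6, immune_cell_radius=2),
            seed=5,
        )
        s1 = build_training_sample(layout, pixels_per_image=100, seed=9)
        s2 = build_training_sample(layout, pixels_per_image=100, seed=9)
        assert s1.shape == (400, 2)  # 4 cells x 100 pixels
        np.testing.assert_array_equal(s1, s2)
        s3 = build_training_sample(layout, pixels_per_image=100, seed=10)
        assert not np.array_equal(s1, s3)

    def test_tiny_image_returns_every_pixel(self, tmp_path):
        import imageio.v3 as iio

        from spherotrack import resolve_layout

        px = np.zeros((2, 2, 3), np.uint8)
        px[:, :, 0] = [[1, 2], [3, 4]]
        iio.imwrite(tmp_path / "g_t24.png", px)
        layout = resolve_layout({
            "groups": ["g"], "times_h": [24],
            "path_pattern": str(tmp_path / "{group}_t{time}.png"),
        })
        s = build_training_sample(layout, pixels_per_image=4, seed=0)
        assert sorted(s[:, 0].tolist()) == [1, 2, 3, 4]

    def test_empty_layout_rejected(self):
        from spherotrack import ExperimentLayout

        with pytest.raises(LayoutError):
            build_training_sample(ExperimentLayout(entries=()), 10)


class TestPersistence:
    def test_json_roundtrip(self, tmp_path):
        clf = assign_roles(
            PixelClassifier(
                centroids=np.array([(10, 10), (60, 180), (220, 30), (255, 255)], float),
                tol=1e-6, seed=3, n_iterations_run=12,
            )
        )
        path = tmp_path / "clf.json"
        clf.to_json(path)
        back = PixelClassifier.from_json(path)
        np.testing.assert_array_equal(back.centroids, clf.centroids)
        assert back.roles == clf.roles
        assert back.tol == clf.tol
        assert back.n_iterations_run == 12
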