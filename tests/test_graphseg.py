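"""Energy maps, minimum-cost path search, labelling policy and grading."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

from bowmetrics.graphseg import (
    EPS,
    SegmentationPolicy,
    build_energy,
    find_path,
    grade_segmentation,
    segment_interfaces,
)
from bowmetrics.phantom_sim import PhantomSpec, generate_stack
from bowmetrics.preprocess import AveragedBScan, preprocess_stack


def _avg_of(spec):
    stack, truth = generate_stack(spec)
    return preprocess_stack(stack), truth


class TestBuildEnergy:
    def test_bright_line_cheap_at_its_rising_edge(self):
        img = np.zeros((9, 7))
        img[4, :] = 1.0
        cost = build_energy(img, polarity="dark_bright").cost
        # steepest dark->bright transition sits just above the line
        assert np.all(np.argmin(cost, axis=0) == 3)

    def test_inverted_image_with_flipped_polarity_is_identical(self, rng):
        img = rng.random((12, 9))
        a = build_energy(img, polarity="dark_bright").cost
        b = build_energy(img.max() - img, polarity="bright_dark").cost
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_matches_hand_computed_five_by_five(self):
        img = np.array(
            [
                [0.0, 1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, 4.0, 5.0],
                [4.0, 5.0, 6.0, 7.0, 8.0],
                [2.0, 2.0, 2.0, 2.0, 2.0],
                [0.0, 0.0, 0.0, 0.0, 0.0],
            ]
        )
        # central differences inside, one-sided at the borders, by hand
        grad = np.array(
            [
                [1.0, 1.0, 1.0, 1.0, 1.0],
                [2.0, 2.0, 2.0, 2.0, 2.0],
                [0.5, 0.0, -0.5, -1.0, -1.5],
                [-2.0, -2.5, -3.0, -3.5, -4.0],
                [-2.0, -2.0, -2.0, -2.0, -2.0],
            ]
        )
        raw = -grad
        expected = (raw - raw.min()) / (raw.max() - raw.min()) + EPS
        got = build_energy(img, polarity="dark_bright").cost
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_constant_image_warns_and_is_uniform(self):
        with pytest.warns(UserWarning, match="constant"):
            cost = build_energy(np.ones((5, 5)), polarity="ridge").cost
        np.testing.assert_array_equal(cost, np.full((5, 5), EPS))

    def test_unknown_polarity_rejected(self):
        with pytest.raises(ValueError):
            build_energy(np.zeros((3, 3)), polarity="sideways")


def _enumerate_min_cost(cost, max_step=2, blocked=None):
    """Brute-force oracle: enumerate every step-constrained path."""
    n_rows, n_cols = cost.shape
    best = np.inf
    for path in itertools.product(range(n_rows), repeat=n_cols):
        if any(abs(path[i + 1] - path[i]) > max_step for i in range(n_cols - 1)):
            continue
        if blocked is not None and any(blocked[z, x] for x, z in enumerate(path)):
            continue
        best = min(best, sum(cost[z, x] for x, z in enumerate(path)))
    return best


class TestFindPath:
    def test_prefers_the_stronger_of_two_lines(self):
        img = np.zeros((12, 10))
        img[3, :] = 1.0
        img[8, :] = 0.4
        path = find_path(build_energy(img, polarity="ridge"))
        np.testing.assert_allclose(path.z, 3.0, atol=0.5)

    def test_blocking_the_stronger_line_selects_the_weaker(self):
        img = np.zeros((12, 10))
        img[3, :] = 1.0
        img[8, :] = 0.4
        blocked = np.zeros_like(img, dtype=bool)
        blocked[2:5, :] = True
        path = find_path(build_energy(img, polarity="ridge"), blocked=blocked)
        np.testing.assert_allclose(path.z, 8.0, atol=0.5)
        # enumeration oracle agrees on a 6x6 crop of the same scene
        crop = img[4:10, :6]
        bl = blocked[4:10, :6]
        e = build_energy(crop, polarity="ridge")
        assert find_path(e, blocked=bl).cost == pytest.approx(
            _enumerate_min_cost(e.cost, blocked=bl)
        )

    def test_dp_cost_matches_enumeration_on_random_grids(self, rng):
        for _ in range(20):
            cost = rng.random((6, 6))
            e = build_energy(-cost, polarity="ridge")  # arbitrary positive map
            assert find_path(e).cost == pytest.approx(_enumerate_min_cost(e.cost))

    def test_dp_cost_matches_dijkstra_oracle(self, rng):
        import networkx as nx

        for _ in range(25):
            cost = rng.random((8, 8))
            e = build_energy(-cost, polarity="ridge")
            G = nx.DiGraph()
            for x in range(8):
                for z in range(8):
                    if x == 0:
                        G.add_edge("src", (z, 0), weight=e.cost[z, 0])
                    else:
                        for dz in range(-2, 3):
                            zp = z - dz
                            if 0 <= zp < 8:
                                G.add_edge((zp, x - 1), (z, x), weight=e.cost[z, x])
                    if x == 7:
                        G.add_edge((z, 7), "snk", weight=0.0)
            oracle = nx.dijkstra_path_length(G, "src", "snk")
            assert find_path(e).cost == pytest.approx(oracle)

    def test_blocked_nodes_never_on_returned_path(self, rng):
        cost = rng.random((10, 12))
        blocked = rng.random((10, 12)) < 0.2
        blocked[5, :] = False  # guarantee feasibility
        e = build_energy(-cost, polarity="ridge")
        path = find_path(e, blocked=blocked)
        assert not any(blocked[z, x] for x, z in enumerate(path.z_int))

    def test_no_feasible_path_raises(self):
        e = build_energy(np.zeros((4, 4)) + 1.0, polarity="ridge")
        with pytest.raises(RuntimeError):
            find_path(e, blocked=np.ones((4, 4), dtype=bool))

    def test_subpixel_path_respects_step_constraint(self, rng):
        cost = rng.random((15, 20))
        path = find_path(build_energy(-cost, polarity="ridge"), max_step=2)
        assert np.all(np.abs(np.diff(path.z)) <= 3.0)  # 2 px + 2 * half-px refinement


class TestSegmentInterfaces:
    def test_clean_phantom_yields_three_ordered_interfaces(self, clean_capture):
        stack, truth = clean_capture
        avg = preprocess_stack(stack)
        seg = segment_interfaces(avg)
        assert not seg.failed
        assert set(seg.paths) == {"tear_film", "epi_bowman", "bowman_stroma"}
        tf, eb, bs = (seg.paths[k].z for k in ("tear_film", "epi_bowman", "bowman_stroma"))
        assert np.all(tf < eb) and np.all(eb < bs)

    def test_clean_phantom_boundaries_match_ground_truth(self, clean_capture):
        stack, truth = clean_capture
        seg = segment_interfaces(preprocess_stack(stack))
        for k, path in seg.paths.items():
            rmse = np.sqrt(np.mean((path.z - truth.interface_depths_px[k]) ** 2))
            assert rmse < 0.5, f"{k}: RMSE {rmse:.2f} px"

    def test_spurious_bright_line_extracted_but_unassigned(self, clean_spec):
        stack, truth = generate_stack(clean_spec)
        img = stack.frames[0].copy()
        spurious_z = int(truth.interface_depths_px["bowman_stroma"].mean()) + 100
        img[spurious_z, :] += 0.5
        avg = AveragedBScan(
            image=img,
            axial_px_um_optical=clean_spec.axial_px_um_optical,
            lateral_px_um=clean_spec.lateral_px_um,
            n_frames_used=1, n_frames_screened_out=0, shifts_px=np.zeros(1),
        )
        seg = segment_interfaces(avg)
        assert not seg.failed
        # the true interfaces are still the labelled ones
        for k, path in seg.paths.items():
            assert np.abs(path.z - truth.interface_depths_px[k]).max() < 2.0
        # and the decoy was found among the low-energy paths, unlabelled
        assert any(abs(p.mean_depth() - spurious_z) < 3 for p in seg.unassigned)

    def test_caller_blocking_emulates_supervisor(self, clean_capture):
        """Striking out the true posterior band forces a failed assignment."""
        stack, truth = clean_capture
        avg = preprocess_stack(stack)
        blocked = np.zeros_like(avg.image, dtype=bool)
        bs = truth.interface_depths_px["bowman_stroma"]
        for x, z in enumerate(bs.astype(int)):
            blocked[z - 4 : z + 5, x] = True
        seg = segment_interfaces(avg, blocked=blocked)
        assert seg.failed and seg.quality_score <= 2


class TestGrading:
    def test_noise_free_phantom_scores_five(self, clean_capture):
        stack, _ = clean_capture
        seg = segment_interfaces(preprocess_stack(stack))
        assert seg.quality_score == 5

    def test_failed_segmentation_scores_at_most_two(self):
        avg = AveragedBScan(
            image=np.zeros((60, 240)), axial_px_um_optical=0.5, lateral_px_um=2.0,
            n_frames_used=1, n_frames_screened_out=0, shifts_px=np.zeros(1),
        )
        seg = segment_interfaces(avg)
        assert seg.failed and seg.quality_score <= 2

    def test_score_never_increases_with_speckle(self):
        scores = []
        for c in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = PhantomSpec(
                speckle_contrast=c, n_frames=4, seed=55, lateral_extent_um=460.0
            )
            stack, _ = generate_stack(spec)
            seg = segment_interfaces(preprocess_stack(stack))
            scores.append(seg.quality_score)
        assert scores == sorted(scores, reverse=True) or all(
            a >= b for a, b in zip(scores, scores[1:])
        )

    def test_score_override_applies(self, clean_capture):
        stack, _ = clean_capture
        seg = segment_interfaces(
            preprocess_stack(stack), policy=SegmentationPolicy(min_score_override=3)
        )
        assert seg.quality_score == 3
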