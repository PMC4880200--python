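import numpy as np
import pytest
from scipy import optimize, stats

from tractdelta.bundle_processing import ProcessedBundle
from tractdelta.change_detection import (DetectionInterval, detect_change,
                                         iterate_on_changed_subset,
                                         label_fibers, mean_method_detect,
                                         mean_method_profile,
                                         run_longitudinal_analysis)
from tractdelta.cross_section_model import (MixtureModel, mixture_cdf,
                                            mixture_quantile)


def _model(weights, means, variances, sample_count=100):
    return MixtureModel(np.asarray(weights, float), np.asarray(means, float),
                        np.asarray(variances, float), loglik=0.0,
                        sample_count=sample_count)


class TestDetectChange:
    def test_identical_models_infeasible(self):
        m = _model([1.0], [0.5], [0.0025])
        interval = detect_change(m, m, zeta=0.12)
        assert not interval.feasible
        assert np.isnan(interval.beta) and np.isnan(interval.gamma)

    def test_gamma_is_zeta_quantile_analytic(self):
        ref = _model([1.0], [0.5], [0.05 ** 2])
        new = _model([1.0], [0.35], [0.05 ** 2])
        interval = detect_change(ref, new, zeta=0.12)
        expect = 0.5 + 0.05 * stats.norm.ppf(0.12)
        assert interval.feasible
        assert abs(interval.gamma - expect) < 1e-6
        assert interval.beta == 0.0

    @pytest.mark.parametrize("zeta", [0.02, 0.05, 0.08, 0.10, 0.12, 0.14])
    def test_gamma_matches_root_finding_oracle(self, zeta):
        ref = _model([0.2, 0.5, 0.3], [0.3, 0.5, 0.65],
                     [0.003, 0.002, 0.004])
        new = _model([0.5, 0.5], [0.2, 0.55], [0.002, 0.002])
        interval = detect_change(ref, new, zeta=zeta, margin_z=0.0)
        oracle = optimize.brentq(
            lambda x: mixture_cdf(ref, x) - zeta, -2.0, 3.0, xtol=1e-12)
        assert abs(interval.gamma - oracle) < 1e-6
        assert interval.p_f <= zeta + 1e-12

    def test_widening_zeta_grows_interval_and_pd(self):
        ref = _model([1.0], [0.5], [0.05 ** 2])
        new = _model([1.0], [0.3], [0.05 ** 2])
        gammas, pds = [], []
        for zeta in (0.02, 0.05, 0.08, 0.10, 0.12, 0.14):
            iv = detect_change(ref, new, zeta=zeta)
            assert iv.feasible
            gammas.append(iv.gamma)
            pds.append(iv.p_d)
        assert np.all(np.diff(gammas) >= 0)
        assert np.all(np.diff(pds) >= 0)

    def test_invalid_zeta_rejected(self):
        m = _model([1.0], [0.5], [0.0025])
        for zeta in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                detect_change(m, m, zeta=zeta)

    def test_pf_never_exceeds_zeta_property(self, rng):
        for _ in range(20):
            k = rng.integers(1, 4)
            w = rng.dirichlet(np.ones(k))
            ref = _model(w, rng.uniform(0.2, 0.8, k),
                         rng.uniform(0.001, 0.01, k))
            new = _model([1.0], [rng.uniform(0.1, 0.4)], [0.003])
            zeta = float(rng.uniform(0.02, 0.2))
            iv = detect_change(ref, new, zeta=zeta, margin_z=0.0)
            if iv.feasible:
                assert iv.p_f <= zeta + 1e-9

    def test_free_mode_matches_brute_force_oracle(self, rng):
        """Grid search over (beta, gamma) must equal a plain double-loop
        brute force over the same grid, including tie-breaks."""
        step = 0.005
        grid = np.arange(0.0, 1.0 + step / 2, step)
        for trial in range(20):
            k_r, k_n = rng.integers(1, 4), rng.integers(1, 4)
            ref = _model(rng.dirichlet(np.ones(k_r)),
                         rng.uniform(0.15, 0.85, k_r),
                         rng.uniform(0.0005, 0.01, k_r))
            new = _model(rng.dirichlet(np.ones(k_n)),
                         rng.uniform(0.15, 0.85, k_n),
                         rng.uniform(0.0005, 0.01, k_n))
            zeta = float(rng.uniform(0.03, 0.2))
            iv = detect_change(ref, new, zeta=zeta, beta_mode="free",
                               margin_z=0.0, grid_step=step)
            f_ref = mixture_cdf(ref, grid)
            f_new = mixture_cdf(new, grid)
            best = None   # (p_d, -(width), -beta_index)
            for i in range(len(grid)):
                for j in range(i, len(grid)):
                    p_f = f_ref[j] - f_ref[i]
                    p_d = f_new[j] - f_new[i]
                    if p_f <= zeta and p_d > p_f:
                        key = (p_d, -(j - i), -i)
                        if best is None or key > best[0]:
                            best = (key, i, j)
            if best is None:
                assert not iv.feasible
            else:
                assert iv.feasible
                assert iv.beta == grid[best[1]]
                assert iv.gamma == grid[best[2]]


class TestPairedGuard:
    def _samples(self, rng, n=80, lesioned=0):
        ref = rng.normal(0.55, 0.05, n)
        new = ref + rng.normal(0, 0.01, n)
        if lesioned:
            new[:lesioned] = ref[:lesioned] * 0.5
        return ref, new

    def test_null_samples_block_detection(self, rng):
        spurious = 0
        for _ in range(50):
            ref, new = self._samples(rng)
            m_ref = _model([1.0], [float(ref.mean())], [float(ref.var())])
            m_new = _model([1.0], [float(new.mean()) - 0.01],
                           [float(new.var())])
            iv = detect_change(m_ref, m_new, zeta=0.12, samples=(ref, new))
            spurious += iv.feasible
        assert spurious <= 2

    def test_lesioned_samples_detected(self, rng):
        ref, new = self._samples(rng, lesioned=20)
        m_ref = _model([1.0], [float(ref.mean())], [float(ref.var())])
        m_new = _model([0.75, 0.25], [0.55, 0.275], [0.0025, 0.001])
        iv = detect_change(m_ref, m_new, zeta=0.12, samples=(ref, new))
        assert iv.feasible
        assert iv.pair_pvalue < 0.01


class TestLabelFibers:
    def test_membership(self):
        interval = DetectionInterval(beta=0.0, gamma=0.40, p_d=0.5,
                                     p_f=0.1, feasible=True, zeta=0.12)
        labels = label_fibers(np.array([0.30, 0.50]), interval)
        assert list(labels) == ["changed", "unchanged"]

    def test_gamma_boundary_inclusive(self):
        interval = DetectionInterval(beta=0.0, gamma=0.40, p_d=0.5,
                                     p_f=0.1, feasible=True, zeta=0.12)
        assert label_fibers(np.array([0.40]), interval)[0] == "changed"

    def test_infeasible_interval_labels_all_unchanged(self):
        interval = DetectionInterval.infeasible(0.12)
        labels = label_fibers(np.array([0.1, 0.2, 0.9]), interval)
        assert set(labels) == {"unchanged"}

    def test_nan_excluded(self):
        interval = DetectionInterval(beta=0.0, gamma=0.40, p_d=0.5,
                                     p_f=0.1, feasible=True, zeta=0.12)
        labels = label_fibers(np.array([np.nan, 0.2]), interval)
        assert list(labels) == ["excluded", "changed"]


class TestMeanMethod:
    def test_identical_values_zero_sd(self):
        values = np.full((10, 7), 0.5)
        prof = mean_method_profile(values)
        np.testing.assert_allclose(prof.sd, 0.0, atol=1e-15)

    def test_matches_loop_oracle(self, rng):
        values = rng.uniform(0, 1, (15, 9))
        prof = mean_method_profile(values)
        for i in range(9):
            col = values[:, i]
            np.testing.assert_allclose(prof.mean[i], col.mean(), atol=1e-12)
            np.testing.assert_allclose(prof.sd[i], col.std(ddof=1),
                                       atol=1e-12)

    def test_nan_reduces_count(self, rng):
        values = rng.uniform(0, 1, (15, 4))
        values[3, 2] = np.nan
        prof = mean_method_profile(values)
        assert prof.count[2] == 14 and prof.count[0] == 15

    def test_single_valid_value_marks_sd_undefined(self):
        values = np.full((3, 2), np.nan)
        values[0, 0] = 0.5
        values[:, 1] = 0.4
        prof = mean_method_profile(values)
        assert np.isnan(prof.sd[0])
        assert prof.sd[1] == pytest.approx(0.0, abs=1e-12)

    def test_detect_disjoint_and_overlapping_bands(self):
        p1 = mean_method_profile(np.full((5, 2), 0.5))
        p1.sd[:] = 0.05
        flagged = mean_method_detect(
            p1, _profile(mean=[0.3, 0.42], sd=[0.05, 0.05]))
        assert list(flagged) == [0]   # [0.45,0.55] vs [0.25,0.35] disjoint
        # means 0.5 vs 0.42: bands [0.45,0.55] and [0.37,0.47] overlap

    def test_identical_profiles_no_detection(self):
        p = _profile(mean=[0.5, 0.6], sd=[0.02, 0.02])
        assert len(mean_method_detect(p, p)) == 0


def _profile(mean, sd):
    from tractdelta.change_detection import MeanProfile
    mean = np.asarray(mean, float)
    return MeanProfile(mean=mean, sd=np.asarray(sd, float),
                       count=np.full(len(mean), 5))


def _synthetic_series(rng, m=100, c=40):
    """Processed bundle with synthetic per-node values: a 40-fiber subset
    carries a lesion at nodes 10-15 at both follow-ups, and at the second
    follow-up 20 of those fibers drop subtly (to 0.515) at nodes 28-32 —
    hidden from the full-bundle test by the wide unchanged-fiber spread,
    visible within the changed subset."""
    positions = np.zeros((m, c, 3))
    positions[:, :, 0] = np.arange(c)
    positions += rng.normal(0, 0.01, positions.shape)
    subset = np.arange(40)
    others = np.arange(40, m)
    ref = np.empty((m, c))
    ref[subset] = 0.55 + rng.normal(0, 0.008, (40, c))
    ref[others] = 0.55 + rng.normal(0, 0.08, (60, c))
    w2 = ref + rng.normal(0, 0.005, (m, c))
    w2[np.ix_(subset, range(10, 16))] = 0.30 + rng.normal(0, 0.005, (40, 6))
    w3 = ref + rng.normal(0, 0.005, (m, c))
    w3[np.ix_(subset, range(10, 16))] = 0.30 + rng.normal(0, 0.005, (40, 6))
    w3[np.ix_(subset[:20], range(28, 33))] = (0.515
                                              + rng.normal(0, 0.003, (20, 5)))
    return ProcessedBundle(positions=positions, ids=np.arange(m),
                           values={"w1": ref, "w2": w2, "w3": w3})


class TestLongitudinalRuns:
    def test_identical_timepoints_no_detection(self, rng):
        values = 0.5 + rng.normal(0, 0.05, (30, 20))
        pb = ProcessedBundle(positions=np.zeros((30, 20, 3)),
                             ids=np.arange(30),
                             values={"w1": values, "w2": values.copy()})
        res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=0)
        assert len(res.detected_nodes("w2")) == 0

    def test_record_cardinality_k_timepoints(self, rng):
        c, k = 15, 5
        values = {f"w{t}": 0.5 + rng.normal(0, 0.05, (30, c))
                  for t in range(1, k + 1)}
        pb = ProcessedBundle(positions=np.zeros((30, c, 3)),
                             ids=np.arange(30), values=values)
        res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=0)
        total = sum(len(res.intervals[tp]) for tp in res.timepoints)
        assert total == (k - 1) * c

    def test_planted_lesion_detections_concentrate_at_lesion(self):
        from tractdelta.bundle_processing import process_bundle
        from tractdelta.lesion_simulation import (LesionSpec, PhantomSpec,
                                                  generate_phantom,
                                                  insert_lesions,
                                                  make_followup)
        spec = PhantomSpec(seed=10)
        bundle, w1 = generate_phantom(spec)
        line = w1.meta["centerline"]
        center = tuple(int(v) for v in
                       np.floor(line[len(line) // 2] / spec.voxel_size + 0.5))
        w2 = make_followup(w1, spec.noise_sd, seed=77)
        w2, mask = insert_lesions(w2, [LesionSpec(center=center, radius=2,
                                                  alpha=0.5)])
        pb = process_bundle(bundle, {"w1": w1, "w2": w2}, seed=10)
        res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=10)
        detected = res.detected_nodes("w2")
        assert len(detected) >= 1
        # which nodes actually traverse the lesion
        idx = w2.nearest_voxel(pb.positions.reshape(-1, 3))
        labels = mask[idx[:, 0], idx[:, 1], idx[:, 2]].reshape(
            pb.n_fibers, pb.node_count)
        lesion_nodes = np.nonzero((labels > 0).any(axis=0))[0]
        near = set(range(lesion_nodes.min() - 2, lesion_nodes.max() + 3))
        spurious = [i for i in detected if i not in near]
        assert len(spurious) <= 1
        assert any(i in near for i in detected)

    def test_two_stage_lesion_found_only_in_iterated_pass(self):
        rng = np.random.default_rng(17)
        pb = _synthetic_series(rng)
        res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=3,
                                        min_changed_nodes=3)
        full_w3 = set(res.detected_nodes("w3"))
        assert full_w3 and full_w3 <= set(range(9, 17))
        sub = iterate_on_changed_subset(pb, res, seed=3,
                                        min_changed_nodes=3)
        assert sub is not None
        assert 30 <= len(sub.fiber_ids) <= 50
        sub_w3 = set(sub.detected_nodes("w3"))
        assert sub_w3 & set(range(27, 34))
        # the first event is still visible inside the subset at w2
        assert set(sub.detected_nodes("w2")) <= set(range(9, 17))

    def test_unchanged_subset_yields_no_new_detections(self, rng):
        values = 0.5 + rng.normal(0, 0.05, (40, 15))
        pb = ProcessedBundle(positions=np.zeros((40, 15, 3)),
                             ids=np.arange(40),
                             values={"w1": values, "w2": values.copy()})
        res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=0)
        assert iterate_on_changed_subset(pb, res, seed=0) is None

    def test_null_phantom_feasible_fraction_below_15_percent(self):
        """Across 20 seeds, two independent noise realizations of the same
        phantom must rarely admit a detection interval."""
        from tractdelta.bundle_processing import process_bundle
        from tractdelta.lesion_simulation import (PhantomSpec,
                                                  generate_phantom,
                                                  make_followup)
        rates = []
        for seed in range(20):
            spec = PhantomSpec(seed=seed, n_fibers=60, points_per_fiber=40)
            bundle, w1 = generate_phantom(spec)
            w2 = make_followup(w1, spec.noise_sd, seed=1000 + seed)
            pb = process_bundle(bundle, {"w1": w1, "w2": w2}, c=50,
                                seed=seed)
            res = run_longitudinal_analysis(pb, "w1", zeta=0.12, seed=seed)
            rates.append(len(res.detected_nodes("w2")) / pb.node_count)
        assert float(np.mean(rates)) < 0.15


class TestDetectionProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(0, 2**31 - 1), st.floats(0.02, 0.4))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_widening_zeta_never_shrinks_interval(self, seed, zeta):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 4))
        w = rng.uniform(0.1, 1.0, k)
        ref = _model(w / w.sum(), rng.uniform(0.2, 0.8, k),
                     rng.uniform(1e-3, 1e-2, k))
        new = _model([1.0], [0.05], [4e-4])
        narrow = detect_change(ref, new, zeta=zeta, margin_z=0.0)
        wide = detect_change(ref, new, zeta=min(2 * zeta, 0.9),
                             margin_z=0.0)
        if narrow.feasible and wide.feasible:
            assert wide.gamma >= narrow.gamma - 1e-12
            assert wide.p_d >= narrow.p_d - 1e-12
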