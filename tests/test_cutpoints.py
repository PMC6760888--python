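"""Cutpoint estimators versus exhaustive enumeration and closed forms."""

import math

import numpy as np
import pandas as pd
import pytest

from pdcthresh.cutpoints import (
    CandidateGrid,
    RocPoint,
    contal_oquigley_scan,
    make_candidate_grid,
    min_distance_threshold,
    roc_points,
    youden_threshold,
)

from _oracles import (
    contal_threshold_oracle,
    logrank_numerator_oracle,
    min_distance_oracle,
    roc_oracle,
    youden_oracle,
)
from conftest import random_survival_dataset


def frame(pdc, time, event):
    return pd.DataFrame({"pdc": pdc, "time_days": time, "event": event})


class TestCandidateGrid:
    def test_observed_mode_returns_distinct_values(self):
        g = make_candidate_grid([0.2, 0.5, 0.8, 0.5], "observed", trim_fraction=0.0)
        assert g.candidates == (0.2, 0.5, 0.8)

    def test_resolution_mode_respects_trim(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.3, 0.9, 500)
        g = make_candidate_grid(x, "resolution", 0.01, 0.05)
        n = len(x)
        xs = np.sort(x)
        for c in g.candidates:
            assert round(c * 100) == pytest.approx(c * 100)  # 0.01 multiples
            n_low = np.searchsorted(xs, c, side="left")
            assert n_low >= 0.05 * n and n - n_low >= 0.05 * n

    def test_constant_input_is_an_error(self):
        with pytest.raises(ValueError):
            make_candidate_grid([0.5, 0.5, 0.5], "observed")

    def test_everything_trimmed_is_an_error(self):
        with pytest.raises(ValueError, match="admissible"):
            make_candidate_grid([0.401, 0.402], "resolution", 0.01, 0.49)


class TestContalOQuigley:
    # six subjects from a worked risk-set enumeration: argmax at c = 0.6
    SIX = (
        np.array([0.2, 0.3, 0.6, 0.7, 0.8, 0.9]),
        np.array([100.0, 200.0, 300.0, 400.0, 500.0, 600.0]),
        np.array([True, True, False, True, False, False]),
    )

    def test_worked_example_u_and_argmax(self):
        pdc, time, event = self.SIX
        grid = make_candidate_grid(pdc, "observed", trim_fraction=0.0)
        result, scan = contal_oquigley_scan(frame(pdc, time, event), grid)
        assert result.threshold == 0.6
        u_at = dict(zip(scan.candidates, scan.u))
        assert u_at[0.6] == pytest.approx(22 / 15)
        # oracle agrees candidate by candidate
        for c in scan.candidates:
            u, v = logrank_numerator_oracle(pdc, time, event, c)
            assert u_at[c] == pytest.approx(u, abs=1e-12)

    def test_variance_constant_matches_direct_sum(self):
        pdc, time, event = self.SIX
        grid = make_candidate_grid(pdc, "observed", trim_fraction=0.0)
        _, scan = contal_oquigley_scan(frame(pdc, time, event), grid)
        d = scan.n_event_times
        assert d == 3
        a = [1 - sum(1 / (d - j + 1) for j in range(1, i + 1)) for i in range(1, d + 1)]
        assert scan.s2 == pytest.approx(sum(x * x for x in a) / (d - 1))

    def test_sign_antisymmetry_under_label_swap(self):
        pdc, time, event = self.SIX
        grid = make_candidate_grid(pdc, "observed", trim_fraction=0.0)
        _, scan = contal_oquigley_scan(frame(pdc, time, event), grid)
        reflected = 1 - pdc + 1e-9
        grid_r = make_candidate_grid(reflected, "observed", trim_fraction=0.0)
        _, scan_r = contal_oquigley_scan(frame(reflected, time, event), grid_r)
        # reflecting the covariate flips the group labels: |U| is preserved
        assert sorted(np.round(np.abs(scan.u), 9)) == pytest.approx(
            sorted(np.round(np.abs(scan_r.u), 9))
        )

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError, match="no events"):
            contal_oquigley_scan(
                frame([0.2, 0.8], [10, 20], [False, False]),
                CandidateGrid((0.5,), "observed", 0.0),
            )

    def test_single_event_time_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            contal_oquigley_scan(
                frame([0.2, 0.5, 0.8], [10, 10, 20], [True, True, False]),
                CandidateGrid((0.5,), "observed", 0.0),
            )

    def test_threshold_equals_enumeration_on_random_data(self, rng):
        for _ in range(20):
            pdc, time, event = random_survival_dataset(rng)
            if event.sum() < 2 or np.unique(time[event]).size < 2:
                continue
            grid = make_candidate_grid(pdc, "resolution", 0.01, 0.05)
            result, _ = contal_oquigley_scan(frame(pdc, time, event), grid)
            assert result.threshold == contal_threshold_oracle(
                pdc, time, event, grid.candidates
            )


class TestRoc:
    def test_perfectly_separated(self):
        df = frame([0.3, 0.4, 0.7, 0.9], [1, 2, 3, 4], [True, True, False, False])
        (pt,) = roc_points(df, CandidateGrid((0.5,), "observed", 0.0))
        assert (pt.sensitivity, pt.specificity) == (1.0, 1.0)

    def test_half_sensitivity(self):
        df = frame([0.3, 0.4, 0.7, 0.9], [1, 2, 3, 4], [True, True, False, False])
        (pt,) = roc_points(df, CandidateGrid((0.35,), "observed", 0.0))
        assert (pt.sensitivity, pt.specificity) == (0.5, 1.0)

    def test_threshold_above_all_values(self):
        df = frame([0.3, 0.4, 0.7, 0.9], [1, 2, 3, 4], [True, True, False, False])
        (pt,) = roc_points(df, CandidateGrid((0.95,), "observed", 0.0))
        assert (pt.sensitivity, pt.specificity) == (1.0, 0.0)

    def test_all_event_input_is_an_error(self):
        with pytest.raises(ValueError):
            roc_points(
                frame([0.1, 0.9], [1, 2], [True, True]),
                CandidateGrid((0.5,), "observed", 0.0),
            )

    def test_monotone_in_threshold_and_matches_counting_oracle(self, rng):
        for _ in range(10):
            pdc, time, event = random_survival_dataset(rng, n=150)
            if event.all() or not event.any():
                continue
            grid = make_candidate_grid(pdc, "resolution", 0.01, 0.0)
            pts = roc_points(frame(pdc, time, event), grid)
            sn = [p.sensitivity for p in pts]
            sp = [p.specificity for p in pts]
            assert all(a <= b + 1e-12 for a, b in zip(sn, sn[1:]))
            assert all(a >= b - 1e-12 for a, b in zip(sp, sp[1:]))
            for p in pts[::7]:
                assert (p.sensitivity, p.specificity) == pytest.approx(
                    roc_oracle(pdc, event, p.c)
                )

    def test_curve_agrees_with_sklearn_auc(self, rng):
        """Area under our (1−Sp, Sn) points matches sklearn's ROC AUC."""
        from sklearn.metrics import roc_auc_score

        pdc, time, event = random_survival_dataset(rng, n=300)
        grid = make_candidate_grid(pdc, "observed", trim_fraction=0.0)
        pts = roc_points(frame(pdc, time, event), grid)
        ours = np.trapezoid(
            [0.0] + [p.sensitivity for p in pts] + [1.0],
            [0.0] + [1 - p.specificity for p in pts] + [1.0],
        )
        assert ours == pytest.approx(roc_auc_score(event, -pdc), abs=0.02)


class TestRocIndices:
    def test_youden_value(self):
        pt = RocPoint(0.5, 0.7, 0.6)
        assert youden_threshold([pt]).statistic == pytest.approx(0.3)

    def test_perfect_point(self):
        pt = RocPoint(0.5, 1.0, 1.0)
        assert youden_threshold([pt]).statistic == pytest.approx(1.0)
        assert min_distance_threshold([pt]).statistic == pytest.approx(0.0)

    def test_min_distance_value(self):
        pt = RocPoint(0.5, 0.8, 0.9)
        assert min_distance_threshold([pt]).statistic == pytest.approx(
            math.sqrt(0.05)
        )

    def test_bounds_and_duality(self, rng):
        pdc, time, event = random_survival_dataset(rng)
        grid = make_candidate_grid(pdc, "resolution", 0.01, 0.05)
        pts = roc_points(frame(pdc, time, event), grid)
        for p in pts:
            j = p.sensitivity + p.specificity - 1
            d = math.hypot(1 - p.sensitivity, 1 - p.specificity)
            assert -1 <= j <= 1 and 0 <= d <= math.sqrt(2)
            assert (j == 1) == (d == 0)

    def test_argmax_equals_enumeration_on_random_data(self, rng):
        for _ in range(20):
            pdc, time, event = random_survival_dataset(rng)
            if event.all() or not event.any():
                continue
            grid = make_candidate_grid(pdc, "resolution", 0.01, 0.05)
            pts = roc_points(frame(pdc, time, event), grid)
            assert youden_threshold(pts).threshold == youden_oracle(
                pdc, event, grid.candidates
            )
            assert min_distance_threshold(pts).threshold == min_distance_oracle(
                pdc, event, grid.candidates
            )
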