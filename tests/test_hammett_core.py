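"""Core Hammett fitting: Theil-Sen slopes, global rho, sigma/offsets,
the sequential reference-based procedure, prediction and scoring."""

import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hammettfit as hf
from hammettfit.errors import (
    ConfigurationError,
    ConnectivityError,
    DegenerateInputError,
    EvaluationError,
    UnknownLabelError,
)
def brute_force_theil_sen(points):
    """Independent oracle: enumerate every pairwise slope, take the median."""
    slopes = [
        (yb - ya) / (xb - xa)
        for (xa, ya), (xb, yb) in itertools.combinations(points, 2)
        if xb != xa
    ]
    return statistics.median(slopes)


class TestTheilSen:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0), (1, 2), (2, 4)], 2.0),
            ([(0, 5), (1, 5), (2, 5)], 0.0),
            ([(0, 0), (1, 1)], 1.0),
        ],
    )
    def test_exact_cases(self, points, expected):
        assert hf.theil_sen_slope(points) == pytest.approx(expected, abs=0)

    def test_enumerated_median(self):
        pts = [(0, 0), (1, 1), (2, 2), (3, 10)]
        # slopes {1, 1, 10/3, 1, 9/2, 8}; even count -> midpoint of central two
        assert brute_force_theil_sen(pts) == pytest.approx((1 + 10 / 3) / 2)
        assert hf.theil_sen_slope(pts) == pytest.approx(brute_force_theil_sen(pts), abs=1e-14)

    @settings(derandomize=True, max_examples=150)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-50, max_value=50),
                st.floats(min_value=-100, max_value=100, allow_nan=False),
            ),
            min_size=2,
            max_size=8,
        )
    )
    def test_matches_exhaustive_oracle(self, points):
        xs = {x for x, _ in points}
        if len(xs) < 2:
            with pytest.raises(DegenerateInputError):
                hf.theil_sen_slope(points)
        else:
            assert hf.theil_sen_slope(points) == pytest.approx(
                brute_force_theil_sen(points), rel=1e-12, abs=1e-12
            )

    def test_matches_scipy(self):
        from scipy.stats import theilslopes

        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        y = 1.7 * x + rng.normal(scale=0.3, size=40)
        ours = hf.theil_sen_slope(np.column_stack([x, y]))
        assert ours == pytest.approx(theilslopes(y, x).slope, abs=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateInputError):
            hf.theil_sen_slope([(1.0, 0.0), (1.0, 5.0)])


def _one_pos_table(series, response_type="log10_k"):
    """Build a table from {reaction: {group: y}} with one position."""
    recs = [
        hf.make_record(j, {"R1": g}, y, response_type)
        for j, d in series.items()
        for g, y in d.items()
    ]
    return hf.build_table(recs, reference_substituent_set=("H",))


class TestPairwiseSlopes:
    def test_exact_proportionality(self):
        base = {"H": 0.0, "a": 1.0, "b": 2.0, "c": -1.0, "d": 0.5}
        table = _one_pos_table({"A": base, "B": {g: 3 * y for g, y in base.items()}})
        slopes = hf.pairwise_reaction_slopes(table)
        assert slopes[("A", "B")] == (pytest.approx(3.0), 5)
        assert slopes[("B", "A")] == (pytest.approx(1 / 3), 5)

    def test_disjoint_sets_empty(self):
        table = _one_pos_table({"A": {"H": 0.0, "a": 1.0}, "B": {"b": 2.0, "c": 3.0}})
        assert hf.pairwise_reaction_slopes(table) == {}

    def test_recovers_rho_ratios(self, sn2_table, sn2_truth):
        slopes = hf.pairwise_reaction_slopes(sn2_table)
        for (i, j), (m, support) in slopes.items():
            assert support == 625
            assert m == pytest.approx(sn2_truth.rho[j] / sn2_truth.rho[i], abs=1e-10)


class TestGlobalRho:
    def test_single_reaction(self):
        assert hf.fit_global_rho({}, anchor="A") == {"A": 1.0}

    def test_consistent_cycle(self):
        slopes = {
            ("A", "B"): (2.0, 5), ("B", "A"): (0.5, 5),
            ("A", "C"): (4.0, 5), ("C", "A"): (0.25, 5),
            ("B", "C"): (2.0, 5), ("C", "B"): (0.5, 5),
        }
        rho = hf.fit_global_rho(slopes, anchor="A")
        assert rho["A"] == 1.0
        assert rho["B"] == pytest.approx(2.0, abs=1e-12)
        assert rho["C"] == pytest.approx(4.0, abs=1e-12)

    def test_perturbed_triangle_matches_normal_equations(self):
        # inconsistent slopes: solve the weighted LSQ by hand and compare
        slopes = {
            ("A", "B"): (2.1, 4), ("B", "A"): (1 / 2.1, 4),
            ("A", "C"): (3.9, 9), ("C", "A"): (1 / 3.9, 9),
            ("B", "C"): (2.05, 16), ("C", "B"): (1 / 2.05, 16),
        }
        rho = hf.fit_global_rho(slopes, anchor="A")
        # unknowns (log rho_B, log rho_C); rows for all 6 ordered edges
        rows, rhs, w = [], [], []
        for (i, j), (m, sup) in sorted(slopes.items()):
            coef = {"B": 0.0, "C": 0.0}
            if j != "A":
                coef[j] += 1.0
            if i != "A":
                coef[i] -= 1.0
            rows.append([coef["B"], coef["C"]])
            rhs.append(math.log(m))
            w.append(sup)
        a = np.array(rows) * np.sqrt(np.array(w))[:, None]
        b = np.array(rhs) * np.sqrt(np.array(w))
        sol = np.linalg.solve(a.T @ a, a.T @ b)
        assert rho["B"] == pytest.approx(math.exp(sol[0]), rel=1e-12)
        assert rho["C"] == pytest.approx(math.exp(sol[1]), rel=1e-12)

    def test_disconnected_graph_reports_components(self):
        slopes = {("A", "B"): (2.0, 3), ("B", "A"): (0.5, 3),
                  ("C", "D"): (1.5, 3), ("D", "C"): (1 / 1.5, 3)}
        with pytest.raises(ConnectivityError) as exc:
            hf.fit_global_rho(slopes, anchor="A")
        assert sorted(map(sorted, exc.value.components)) == [["A", "B"], ["C", "D"]]

    def test_negative_slope_strict_vs_propagated(self):
        slopes = {("A", "B"): (-2.0, 5), ("B", "A"): (-0.5, 5)}
        with pytest.raises(hf.errors.SignError):
            hf.fit_global_rho(slopes, anchor="A")
        rho = hf.fit_global_rho(slopes, anchor="A", allow_negative=True)
        assert rho["A"] == 1.0
        assert rho["B"] == pytest.approx(-2.0, abs=1e-12)


class TestSigmaOffsets:
    def test_single_reaction_closed_form(self):
        table = _one_pos_table({"A": {"H": 1.0, "a": 1.5, "b": 0.2}})
        sigma, offsets = hf.fit_sigma_offsets(table, {"A": 1.0})
        assert sigma[("H",)] == 0.0
        assert sigma[("a",)] == pytest.approx(0.5, abs=1e-10)
        assert sigma[("b",)] == pytest.approx(-0.8, abs=1e-10)
        assert offsets["A"] == pytest.approx(1.0, abs=1e-10)

    def test_reference_gauge_exact(self, sn2_table, sn2_params):
        assert sn2_params.sigma[sn2_table.reference_substituent_set] == 0.0
        assert sn2_params.rho[sn2_params.anchor_reaction] == 1.0

    def test_noiseless_recovery(self, sn2_table, sn2_truth):
        slopes = hf.pairwise_reaction_slopes(sn2_table)
        rho = hf.fit_global_rho(slopes, anchor=sn2_table.reactions[0])
        sigma, offsets = hf.fit_sigma_offsets(sn2_table, rho)
        scale = sn2_truth.rho[sn2_table.reactions[0]]
        for s, v in sn2_truth.sigma.items():
            assert sigma[s] / scale == pytest.approx(v, abs=1e-8)
        for j, c in sn2_truth.offsets.items():
            assert offsets[j] == pytest.approx(c, abs=1e-8)


class TestSigmaHammettFit:
    def test_noiseless_recovery_after_gauge(self, sn2_params, sn2_truth, gauge_scale):
        for j in sn2_truth.rho:
            assert sn2_params.rho[j] * gauge_scale == pytest.approx(
                sn2_truth.rho[j], abs=1e-8
            )
        for s in sn2_truth.sigma:
            assert sn2_params.sigma[s] / gauge_scale == pytest.approx(
                sn2_truth.sigma[s], abs=1e-8
            )
        for j in sn2_truth.offsets:
            assert sn2_params.offsets[j] == pytest.approx(sn2_truth.offsets[j], abs=1e-8)

    def test_row_order_invariance(self, single_world):
        table, _ = single_world
        params = hf.fit_sigma_hammett(table)
        rng = np.random.default_rng(0)
        recs = list(table.records)
        rng.shuffle(recs)
        shuffled = hf.build_table(
            recs, reference_substituent_set=table.reference_substituent_set
        )
        p2 = hf.fit_sigma_hammett(shuffled)
        assert p2.rho == params.rho
        assert p2.sigma == params.sigma
        assert p2.offsets == params.offsets

    def test_gauge_invariance_of_generator_scaling(self, sn2_params, sn2_truth):
        # the generated world is unchanged under (rho*c, sigma/c); the fit
        # must therefore align with the rescaled truth equally well
        c = 2.0
        scaled_rho = {j: v * c for j, v in sn2_truth.rho.items()}
        scaled_sigma = {s: v / c for s, v in sn2_truth.sigma.items()}
        scale = scaled_rho[sn2_params.anchor_reaction]
        for j in scaled_rho:
            assert sn2_params.rho[j] * scale == pytest.approx(scaled_rho[j], abs=1e-8)
        for s in scaled_sigma:
            assert sn2_params.sigma[s] / scale == pytest.approx(scaled_sigma[s], abs=1e-8)

    def test_sigma_ordering_robust_to_series_outliers(self):
        # whole-series contaminants must not reorder the sigma scale
        cfg = hf.SyntheticConfig(
            n_reactions=10,
            groups={"H": 0.0, "A": -2.0, "B": -1.2, "C": -0.5, "D": 0.6, "E": 1.4},
            positions={"R1": 1.5},
            decay=("none", None),
            rho_range=(0.5, 3.0),
            offset_range=(-2.0, 2.0),
            noise_sd=0.05,
            outlier_fraction=0.15,
            outlier_shift=0.5,
            outlier_unit="set",
            response_type="log10_k",
            seed=21,
        )
        table, truth = hf.generate(cfg)
        params = hf.fit_sigma_hammett(table)
        keys = sorted(truth.sigma)
        true_order = np.argsort([truth.sigma[k] for k in keys])
        fit_order = np.argsort([params.sigma[k] for k in keys])
        assert list(true_order) == list(fit_order)


class TestOriginalHammett:
    def test_noiseless_equivalence_to_global(self, sn2_table, sn2_params):
        ref = sn2_table.reactions[0]
        orig = hf.original_hammett_fit(sn2_table, ref)
        for r in sn2_table.records[::97]:
            key = r.set_key(sn2_table.positions)
            assert hf.predict(orig, r.reaction_id, key) == pytest.approx(
                r.response, abs=1e-8
            )
            assert hf.predict(sn2_params, r.reaction_id, key) == pytest.approx(
                r.response, abs=1e-8
            )

    def test_expansion_order_changes_noisy_result(self):
        # order only matters when later reactions introduce new sets, so
        # the table must be partially observed
        cfg = hf.SyntheticConfig(
            n_reactions=6,
            groups={"H": 0.0, "A": -2.0, "B": -1.2, "C": -0.5, "D": 0.6,
                    "E": 1.4, "F": 0.9, "G": -0.3},
            positions={"R1": 1.5},
            decay=("none", None),
            rho_range=(0.5, 3.0),
            offset_range=(-2.0, 2.0),
            noise_sd=0.3,
            missing_fraction=0.35,
            response_type="log10_k",
            seed=29,
        )
        table, _ = hf.generate(cfg)
        per = table.by_reaction()
        ref = next(
            j for j in table.reactions
            if table.reference_substituent_set in per[j]
        )
        rest = [j for j in table.reactions if j != ref]
        pa = hf.original_hammett_fit(table, ref, expansion_order=rest)
        pb = hf.original_hammett_fit(table, ref, expansion_order=rest[::-1])
        diff = max(abs(pa.sigma[s] - pb.sigma[s]) for s in set(pa.sigma) & set(pb.sigma))
        assert diff > 1e-6

    def test_unreachable_reported(self):
        table = _one_pos_table(
            {
                "A": {"H": 0.0, "a": 1.0, "b": 2.0},
                "B": {"H": 0.1, "a": 1.2, "c": 2.2},
                "C": {"d": 5.0, "e": 6.0},  # shares nothing with A/B
            }
        )
        params = hf.original_hammett_fit(table, "A")
        assert params.diagnostics["unassigned_reactions"] == ["C"]
        assert [tuple(s) for s in params.diagnostics["unassigned_sets"]] == [
            ("d",), ("e",)
        ]

    def test_reference_must_observe_reference_set(self):
        table = _one_pos_table(
            {"A": {"a": 1.0, "b": 2.0}, "B": {"a": 1.1, "b": 2.1, "H": 0.0}}
        )
        with pytest.raises(ConfigurationError, match="reference"):
            hf.original_hammett_fit(table, "A")


class TestPredictEvaluate:
    def test_reference_set_predicts_offset(self, sn2_params, sn2_table, sn2_truth):
        ref = sn2_table.reference_substituent_set
        for j in sn2_table.reactions:
            assert hf.predict(sn2_params, j, ref) == sn2_params.offsets[j]

    def test_anchor_arithmetic(self):
        params = hf.HammettParameters(
            rho={"A": 1.0}, sigma={("x",): 0.5}, offsets={"A": 1.0},
            anchor_reaction="A", method="sigma_hammett_global",
            positions=["R1"], reference_substituent_set=("H",),
        )
        assert hf.predict(params, "A", ("x",)) == pytest.approx(1.5)

    def test_unknown_lookups(self, sn2_params):
        with pytest.raises(UnknownLabelError):
            hf.predict(sn2_params, "nope", ("H", "H", "H", "H"))
        with pytest.raises(UnknownLabelError):
            hf.predict(sn2_params, sn2_params.anchor_reaction, ("Z", "Z", "Z", "Z"))

    def test_self_mae_zero(self, sn2_params, sn2_table):
        assert hf.evaluate_mae(sn2_params, sn2_table) == pytest.approx(0.0, abs=1e-8)
        per = hf.evaluate_mae(sn2_params, sn2_table, per="reaction")
        assert set(per) == set(sn2_table.reactions)
        assert all(v == pytest.approx(0.0, abs=1e-8) for v in per.values())

    def test_constant_offset_mae_exact(self, sn2_params, sn2_table):
        shifted = hf.HammettParameters(
            rho=sn2_params.rho,
            sigma=sn2_params.sigma,
            offsets={j: c + 1.0 for j, c in sn2_params.offsets.items()},
            anchor_reaction=sn2_params.anchor_reaction,
            method=sn2_params.method,
            positions=sn2_params.positions,
            reference_substituent_set=sn2_params.reference_substituent_set,
        )
        assert hf.evaluate_mae(shifted, sn2_table) == pytest.approx(1.0, abs=1e-8)

    def test_gaussian_noise_mae_half_normal(self, sn2_params, sn2_table):
        # MAE of params fitted on clean data, evaluated on noisy responses,
        # approaches E|N(0, sd)| = sd*sqrt(2/pi)
        sd = 0.5
        rng = np.random.default_rng(17)
        noisy_records = [
            hf.make_record(
                r.reaction_id, r.substituent_map,
                r.response + rng.normal(0, sd), r.response_type,
            )
            for r in sn2_table.records
        ]
        noisy = hf.build_table(
            noisy_records, reference_substituent_set=sn2_table.reference_substituent_set
        )
        mae = hf.evaluate_mae(sn2_params, noisy)
        expected = sd * math.sqrt(2 / math.pi)
        # se of the mean of |N| over 7500 draws is ~0.0035
        assert mae == pytest.approx(expected, abs=0.02)

    def test_empty_overlap(self, sn2_params):
        other = _one_pos_table({"Z": {"H": 0.0, "q": 1.0}})
        with pytest.raises(EvaluationError):
            hf.evaluate_mae(sn2_params, other)


class TestRobustness:
    def test_theil_sen_beats_ols_under_series_outliers(self):
        """Whole-series contamination distorts Theil-Sen slope ratios far
        less than the OLS control (the qualitative robustness claim)."""
        wins = 0
        for seed in range(6):
            table, truth = hf.make_sn2_like(seed=seed, noise_sd=0.3)
            cfg = hf.SyntheticConfig(
                n_reactions=6,
                groups=dict(hf.synthetic_data.SN2_ALPHA),
                positions=dict(hf.synthetic_data.SN2_DISTANCES),
                coordinates=dict(hf.synthetic_data.SN2_COORDINATES),
                decay=("power", 2.0),
                rho_range=(0.5, 3.0),
                offset_range=(12.0, 30.0),
                noise_sd=0.3,
                outlier_fraction=0.2,
                outlier_shift=3.0,
                outlier_unit="set",
                max_sets=1000,
                seed=seed,
            )
            table, truth = hf.generate(cfg)
            ts = hf.pairwise_reaction_slopes(table, "theil_sen")
            ols = hf.pairwise_reaction_slopes(table, "ols")
            dev_ts = np.median(
                [abs(m / (truth.rho[j] / truth.rho[i]) - 1) for (i, j), (m, _) in ts.items()]
            )
            dev_ols = np.median(
                [abs(m / (truth.rho[j] / truth.rho[i]) - 1) for (i, j), (m, _) in ols.items()]
            )
            wins += dev_ts < 0.5 * dev_ols
        assert wins >= 5


def test_enumeration_bound():
    assert hf.enumeration_bound(1) == 1
    prod = 1
    for k in range(1, 13):
        prod *= k
    assert hf.enumeration_bound(12) == prod
    assert hf.enumeration_bound(12) >= 10**8
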