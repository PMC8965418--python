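"""Dispersal summaries, binomial/Poisson GLMs and worm-fate accounting."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from foidecomp import dispersal_summary, fit_binomial_glm, fit_poisson_glm, worm_accounting
from foidecomp.transmission import model_replicates


def _cells(replicate_factory, spec):
    """spec: {(treatment, source): [(on_receiver, on_donor), ...]}"""
    reps, i = [], 0
    for (treatment, source), pairs in spec.items():
        for recv, donor in pairs:
            reps.append(
                replicate_factory(
                    replicate_id=f"r{i}", treatment=treatment, source=source,
                    on_receiver=recv, on_donor=donor,
                )
            )
            i += 1
    return reps


ALL_CELLS = [
    ("intraspecific", "focal_sourced"),
    ("interspecific", "focal_sourced"),
    ("intraspecific", "alternative_sourced"),
    ("interspecific", "alternative_sourced"),
]


class TestDispersalSummary:
    def test_even_split_is_half(self, replicate_factory):
        reps = [replicate_factory(on_donor=5, on_receiver=5)]
        summ = dispersal_summary(reps)
        row = summ[(summ.treatment == "intraspecific") & (summ.source == "focal_sourced")].iloc[0]
        assert row.proportion == 0.5

    def test_zero_dispersal_boundary(self, replicate_factory):
        reps = [replicate_factory(replicate_id=f"r{i}", on_donor=8) for i in range(3)]
        row = dispersal_summary(reps).dropna(subset=["proportion"]).iloc[0]
        assert row.proportion == 0.0 and row.ci_lower == 0.0

    def test_unattached_replicates_reported_excluded(self, replicate_factory):
        reps = [
            replicate_factory(replicate_id="a", on_donor=4, on_receiver=4),
            replicate_factory(replicate_id="b", in_donor_cup=10),  # no attached worms
        ]
        row = dispersal_summary(reps).dropna(subset=["proportion"]).iloc[0]
        assert row.n_excluded == 1 and row.attached == 8

    def test_empty_cells_flagged_not_raised(self, replicate_factory):
        summ = dispersal_summary([replicate_factory(on_donor=3, on_receiver=1)])
        assert summ["empty"].sum() == 3

    def test_invariant_to_order_and_merging(self, replicate_factory):
        a = [
            replicate_factory(replicate_id="a", on_donor=3, on_receiver=1),
            replicate_factory(replicate_id="b", on_donor=5, on_receiver=2),
        ]
        merged = [replicate_factory(replicate_id="m", on_donor=8, on_receiver=3)]
        col = ["dispersed", "attached", "proportion"]
        assert dispersal_summary(a[::-1])[col].equals(dispersal_summary(a)[col])
        assert dispersal_summary(merged)[col].equals(dispersal_summary(a)[col])


def _binom_nll(beta, x, y, m):
    eta = x @ beta
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return -np.sum(y * np.log(p) + (m - y) * np.log1p(-p))


class TestBinomialGLM:
    def test_two_group_log_odds_ratio(self, replicate_factory):
        # 10/100 vs 30/100 without interaction: coef = log[(30/70)/(10/90)]
        spec = {
            ("intraspecific", "alternative_sourced"): [(10, 90)],
            ("interspecific", "alternative_sourced"): [(30, 70)],
            ("intraspecific", "focal_sourced"): [(10, 90)],
            ("interspecific", "focal_sourced"): [(30, 70)],
        }
        fit = fit_binomial_glm(_cells(replicate_factory, spec), include_interaction=False)
        expected = math.log((30 / 70) / (10 / 90))
        assert fit.coefficients["treatment[interspecific]"] == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(1.3499, abs=5e-5)

    def test_identical_cells_give_null_model(self, replicate_factory):
        spec = {cell: [(4, 12)] for cell in ALL_CELLS}
        fit = fit_binomial_glm(_cells(replicate_factory, spec))
        for term, coef in fit.coefficients.items():
            if term != "intercept":
                assert coef == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_mle(self, replicate_factory, rng):
        for trial in range(5):
            spec = {
                cell: [(int(r), int(d)) for r, d in zip(rng.integers(0, 6, 4), rng.integers(1, 9, 4))]
                for cell in ALL_CELLS
            }
            reps = _cells(replicate_factory, spec)
            fit = fit_binomial_glm(reps)
            if fit.diverged:
                continue  # separation: MLE at infinity, oracle comparison meaningless
            kept = model_replicates(reps)
            x = np.column_stack(
                [
                    np.ones(len(kept)),
                    [r.treatment == "interspecific" for r in kept],
                    [r.source == "focal_sourced" for r in kept],
                    [
                        (r.treatment == "interspecific") and (r.source == "focal_sourced")
                        for r in kept
                    ],
                ]
            ).astype(float)
            y = np.array([r.on_receiver for r in kept], float)
            m = np.array([r.attached_total for r in kept], float)
            res = minimize(_binom_nll, np.zeros(4), args=(x, y, m), method="BFGS",
                           options={"gtol": 1e-10})
            assert np.allclose(list(fit.coefficients.values()), res.x, atol=1e-6)

    def test_standard_errors_match_observed_information(self, replicate_factory, rng):
        spec = {
            cell: [(int(r), int(d) + 1) for r, d in zip(rng.integers(0, 5, 6), rng.integers(2, 9, 6))]
            for cell in ALL_CELLS
        }
        reps = _cells(replicate_factory, spec)
        fit = fit_binomial_glm(reps)
        x = np.column_stack(
            [
                np.ones(len(reps)),
                [r.treatment == "interspecific" for r in reps],
                [r.source == "focal_sourced" for r in reps],
                [(r.treatment == "interspecific") and (r.source == "focal_sourced") for r in reps],
            ]
        ).astype(float)
        m = np.array([r.attached_total for r in reps], float)
        beta = np.array(list(fit.coefficients.values()))
        p = expit(x @ beta)
        info = x.T @ (x * (m * p * (1 - p))[:, None])
        se_oracle = np.sqrt(np.diag(np.linalg.inv(info)))
        assert np.allclose(list(fit.standard_errors.values()), se_oracle, atol=1e-6)

    def test_aggregated_equals_per_replicate(self, replicate_factory):
        per_rep = {
            cell: [(1, 4), (2, 3), (0, 5)] for cell in ALL_CELLS
        }
        agg = {cell: [(3, 12)] for cell in ALL_CELLS}
        f1 = fit_binomial_glm(_cells(replicate_factory, per_rep))
        f2 = fit_binomial_glm(_cells(replicate_factory, agg))
        assert np.allclose(
            list(f1.coefficients.values()), list(f2.coefficients.values()), atol=1e-8
        )

    def test_source_reference_flip_reparameterizes(self, replicate_factory):
        spec = {
            ("intraspecific", "focal_sourced"): [(3, 7)],
            ("interspecific", "focal_sourced"): [(8, 2)],
            ("intraspecific", "alternative_sourced"): [(1, 9)],
            ("interspecific", "alternative_sourced"): [(1, 19)],
        }
        reps = _cells(replicate_factory, spec)
        alt_ref = fit_binomial_glm(reps, source_reference="alternative_sourced")
        focal_ref = fit_binomial_glm(reps, source_reference="focal_sourced")
        # interaction magnitude is reference-invariant, sign flips
        int_alt = alt_ref.coefficients["treatment[interspecific]:source[focal_sourced]"]
        int_focal = focal_ref.coefficients["treatment[interspecific]:source[alternative_sourced]"]
        assert int_alt == pytest.approx(-int_focal, abs=1e-8)

    def test_complete_separation_flagged(self, replicate_factory):
        spec = {
            ("intraspecific", "focal_sourced"): [(0, 10)],
            ("interspecific", "focal_sourced"): [(10, 0)],
            ("intraspecific", "alternative_sourced"): [(0, 10)],
            ("interspecific", "alternative_sourced"): [(10, 0)],
        }
        fit = fit_binomial_glm(_cells(replicate_factory, spec))
        assert fit.diverged

    def test_short_replicates_excluded_from_fit(self, replicate_factory):
        long_reps = _cells(replicate_factory, {cell: [(2, 6), (3, 5)] for cell in ALL_CELLS})
        short = [
            replicate_factory(replicate_id=f"s{i}", on_receiver=6, on_donor=0, duration_hours=1.0)
            for i in range(8)
        ]
        with_short = fit_binomial_glm(long_reps + short)
        without = fit_binomial_glm(long_reps)
        assert np.allclose(
            list(with_short.coefficients.values()), list(without.coefficients.values())
        )


class TestPoissonGLM:
    def _reps(self, replicate_factory, intra_counts, inter_counts):
        reps = []
        for i, c in enumerate(intra_counts):
            reps.append(replicate_factory(replicate_id=f"a{i}", treatment="intraspecific", on_donor=c))
        for i, c in enumerate(inter_counts):
            reps.append(replicate_factory(replicate_id=f"b{i}", treatment="interspecific", on_donor=c))
        return reps

    def test_closed_form_group_mean_ratio(self, replicate_factory):
        # means 4 vs 8: treatment coefficient ln 2, intercept ln 4
        fit = fit_poisson_glm(self._reps(replicate_factory, [3, 4, 5, 4], [7, 8, 9, 8]))
        assert fit.coefficients["intercept"] == pytest.approx(math.log(4), abs=1e-8)
        assert fit.coefficients["treatment[interspecific]"] == pytest.approx(math.log(2), abs=1e-8)

    def test_identical_groups_null(self, replicate_factory):
        fit = fit_poisson_glm(self._reps(replicate_factory, [5, 7], [5, 7]))
        assert fit.coefficients["treatment[interspecific]"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_mle(self, replicate_factory, rng):
        for _ in range(5):
            intra = rng.poisson(4, size=6) + 1
            inter = rng.poisson(8, size=6) + 1
            reps = self._reps(replicate_factory, intra.tolist(), inter.tolist())
            fit = fit_poisson_glm(reps)
            y = np.array([r.recovered_total for r in reps], float)
            x = np.column_stack([np.ones(len(reps)), [r.treatment == "interspecific" for r in reps]]).astype(float)
            nll = lambda b: np.sum(np.exp(x @ b)) - y @ (x @ b)
            res = minimize(nll, np.zeros(2), method="BFGS", options={"gtol": 1e-12})
            assert np.allclose(list(fit.coefficients.values()), res.x, atol=1e-6)

    def test_all_zero_group_flagged(self, replicate_factory):
        fit = fit_poisson_glm(self._reps(replicate_factory, [0, 0, 0], [5, 6, 7]))
        assert fit.diverged


class TestWormAccounting:
    def test_conservation_no_missing(self, replicate_factory):
        reps = [replicate_factory(on_donor=6, on_receiver=4)]
        assert worm_accounting(reps).iloc[0].missing == 0

    def test_cup_breakdown_percentages(self, replicate_factory):
        reps = [
            replicate_factory(
                on_donor=100, on_receiver=20, in_donor_cup=33,
                in_experimental_cup=3, in_receiver_cup=2,
            )
        ]
        row = worm_accounting(reps).iloc[0]
        assert row.pct_donor_cup == pytest.approx(100 * 33 / 38, abs=0.05)
        assert row.pct_experimental_cup == pytest.approx(100 * 3 / 38, abs=0.05)
        assert row.pct_receiver_cup == pytest.approx(100 * 2 / 38, abs=0.05)
        assert (row.pct_donor_cup, row.pct_experimental_cup, row.pct_receiver_cup) == (
            pytest.approx(86.8, abs=0.05),
            pytest.approx(7.9, abs=0.05),
            pytest.approx(5.3, abs=0.05),
        )

    def test_reproduction_excess_floors_missing_at_zero(self, replicate_factory):
        reps = [replicate_factory(worms_added=10, on_donor=9, on_receiver=5)]
        row = worm_accounting(reps).iloc[0]
        assert row.missing == 0 and row.excess == 4

    def test_missing_summed_per_replicate(self, replicate_factory):
        reps = [
            replicate_factory(replicate_id="a", on_donor=2),  # 8 missing
            replicate_factory(replicate_id="b", on_donor=12, on_receiver=3),  # 5 excess
        ]
        row = worm_accounting(reps).iloc[0]
        assert row.missing == 8 and row.excess == 5
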