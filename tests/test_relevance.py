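"""Occlusion relevance profiles, enrichment, and domain coverage."""

import math

import numpy as np
import pytest

from thermoseq.records import ProteinRecord
from thermoseq.relevance import (
    DomainCoverage,
    domain_coverage,
    enrich,
    occlusion_profile,
    profile_from_scores,
    select_domains,
    stability_check,
)


class ConstantModel:
    """Predicts the same temperature for any input."""

    def __init__(self, value=50.0):
        self.value = value

    def predict(self, records):
        return np.full(len(records), self.value)


class ResidueCountModel:
    """Surrogate: prediction = base + coef * count of a residue outside the
    occluded window; lets occlusion effects be evaluated in closed form."""

    def __init__(self, residue="W", base=100.0, coef=10.0):
        self.residue, self.base, self.coef = residue, base, coef

    def predict(self, records):
        out = []
        for r in records:
            seq = r.sequence
            masked = getattr(r, "occluded", None)
            if masked is not None:
                seq = seq[: masked[0]] + seq[masked[1] :]
            out.append(self.base + self.coef * seq.count(self.residue))
        return np.array(out)


class TestOcclusionProfile:
    def test_constant_model_gives_flat_profile(self, make_record):
        rec = make_record(length=60)
        prof = occlusion_profile(ConstantModel(), rec, width=5)
        assert np.all(prof.scores == 0)
        assert not prof.significant.any()
        assert np.all(prof.z == 0)

    def test_profile_length_matches_sequence(self, make_record):
        rec = make_record(length=73)
        prof = occlusion_profile(ConstantModel(), rec, width=5)
        assert len(prof.scores) == 73

    def test_single_tracked_residue_localizes_signal(self):
        width = 5
        seq = "A" * 30 + "W" + "A" * 29
        rec = ProteinRecord(id="w1", sequence=seq)
        model = ResidueCountModel("W")
        prof = occlusion_profile(model, rec, width=width)
        w_pos = 30
        # closed form: every window covering the W predicts base instead of
        # base + coef, so its score is -coef / (base + coef)
        per_window = -model.coef / (model.base + model.coef)
        assert prof.scores[w_pos] == pytest.approx(per_window)
        nonzero = np.flatnonzero(prof.scores)
        assert nonzero.min() >= w_pos - (width - 1)
        assert nonzero.max() <= w_pos + (width - 1)
        assert prof.scores.argmin() == w_pos

    def test_z_standardization(self, make_record):
        rec = make_record(length=80)
        prof = occlusion_profile(ResidueCountModel("A", coef=1.0), rec, width=5)
        if prof.scores.std() > 0:
            assert prof.z.mean() == pytest.approx(0.0, abs=1e-10)
            assert prof.z.std() == pytest.approx(1.0, abs=1e-10)

    def test_width_bounds(self, make_record):
        rec = make_record(length=10)
        with pytest.raises(ValueError):
            occlusion_profile(ConstantModel(), rec, width=10)
        with pytest.raises(ValueError):
            occlusion_profile(ConstantModel(), rec, width=0)

    def test_zero_baseline_prediction_rejected(self, make_record):
        with pytest.raises(ZeroDivisionError):
            occlusion_profile(ConstantModel(0.0), make_record(length=30), width=3)

    def test_significance_calibration_on_iid_normal_scores(self):
        """With i.i.d. normal raw scores the |z| > 2 rule flags about 4.55%."""
        scores = np.random.default_rng(99).normal(size=10_000)
        prof = profile_from_scores("sim", scores, width=5)
        frac = prof.significant.mean()
        assert 0.035 <= frac <= 0.06


class TestStabilityCheck:
    def test_constant_model_all_empty_sets_overlap_fully(self, make_record):
        rec = make_record(length=60)
        mat = stability_check(ConstantModel(), rec, widths=(2, 5, 10, 20))
        np.testing.assert_array_equal(mat, np.ones((4, 4)))

    def test_planted_position_shared_across_widths(self):
        seq = "A" * 30 + "W" + "A" * 29
        rec = ProteinRecord(id="w1", sequence=seq)
        model = ResidueCountModel("W")
        widths = (2, 5, 10)
        sig_sets = []
        for w in widths:
            prof = occlusion_profile(model, rec, width=w)
            sig_sets.append(set(np.flatnonzero(prof.significant)))
        for s in sig_sets:
            assert 30 in s
        mat = stability_check(model, rec, widths=widths)
        assert np.all(mat > 0)
        np.testing.assert_array_equal(np.diag(mat), 1.0)


def hypergeom_oracle(N, K, n, k):
    """Tail probabilities by direct summation of the urn pmf."""

    def pmf(j):
        return math.comb(K, j) * math.comb(N - K, n - j) / math.comb(N, n)

    lo, hi = max(0, n - (N - K)), min(n, K)
    p_over = sum(pmf(j) for j in range(k, hi + 1)) if k >= lo else 1.0
    p_under = sum(pmf(j) for j in range(lo, min(k, hi) + 1))
    return p_over, p_under


def profile_with_significant(length, sig_positions, rid="p"):
    z = np.zeros(length)
    z[list(sig_positions)] = 3.0
    scores = z.copy()
    prof = profile_from_scores(rid, scores, width=5)
    # construct deterministically: force the significance mask we want
    prof.significant = np.zeros(length, dtype=bool)
    prof.significant[list(sig_positions)] = True
    return prof


class TestEnrich:
    def test_matches_oracle_on_worked_urn(self):
        # urn N=100, K=20, n_sig=10, k=8 built from category strings
        ann = "B" * 20 + "A" * 80  # K=20 of category B
        sig = list(range(8)) + [50, 51]  # 8 of the B's, 2 A's
        prof = profile_with_significant(100, sig)
        res = {r.category: r for r in enrich([prof], {"p": ann}, alphabet="AB")}
        p_over, p_under = hypergeom_oracle(100, 20, 10, 8)
        assert res["B"].p_over == pytest.approx(p_over, rel=1e-12)
        assert res["B"].p_under == pytest.approx(p_under, rel=1e-12)
        assert res["B"].verdict == "enriched"

    def test_oracle_agreement_small_urns(self):
        """Exhaustive agreement with the urn pmf for all N <= 30 tails."""
        from scipy.stats import hypergeom

        for N in (5, 11, 18, 24, 30):
            for K in range(0, N + 1, max(1, N // 4)):
                for n in range(1, N + 1, max(1, N // 4)):
                    lo, hi = max(0, n - (N - K)), min(n, K)
                    for k in range(lo, hi + 1):
                        p_over, p_under = hypergeom_oracle(N, K, n, k)
                        assert float(hypergeom.sf(k - 1, N, K, n)) == pytest.approx(
                            p_over, abs=1e-12
                        )
                        assert float(hypergeom.cdf(k, N, K, n)) == pytest.approx(
                            p_under, abs=1e-12
                        )

    def test_extreme_depletion(self):
        # category B present in background but absent at significant positions
        ann = "B" * 20 + "A" * 80
        prof = profile_with_significant(100, range(50, 60))  # all in A
        res = {r.category: r for r in enrich([prof], {"p": ann}, alphabet="AB")}
        N, K, n = 100, 20, 10
        expected = math.comb(N - K, n) / math.comb(N, n)
        assert res["B"].p_under == pytest.approx(expected, rel=1e-10)
        assert res["B"].p_under < res["B"].p_over

    def test_depleted_verdict_when_lower_tail_significant(self):
        # stronger depletion: 40 B's in the background, none significant
        ann = "B" * 40 + "A" * 60
        prof = profile_with_significant(100, range(50, 60))
        res = {r.category: r for r in enrich([prof], {"p": ann}, alphabet="AB")}
        assert res["B"].p_under < 0.05
        assert res["B"].verdict == "depleted"

    def test_unannotated_positions_excluded(self):
        ann = "AB" * 10 + "." * 10  # 10 unannotated tail positions
        prof = profile_with_significant(30, [0, 1, 25])
        res = enrich([prof], {"p": ann}, alphabet="AB")
        assert all(r.N == 20 for r in res)
        assert all(r.n_sig == 2 for r in res)  # position 25 is unannotated

    def test_bh_adjustment_matches_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        from thermoseq.relevance import _bh_adjust

        pvals = rng.uniform(size=15)
        adj = _bh_adjust(pvals.tolist())
        _, ref, _, _ = multipletests(pvals, method="fdr_bh")
        np.testing.assert_allclose(adj, ref, atol=1e-12)

    def test_length_mismatch_names_record(self):
        prof = profile_with_significant(30, [0])
        with pytest.raises(ValueError, match="'p'"):
            enrich([prof], {"p": "AB"}, alphabet="AB")


class TestDomainCoverage:
    def test_hand_computed_instance(self):
        """L=20, domain [6,10], significant {6,7,13}: coverage 0.4 and
        control 1/35 from 7 sliding outside windows."""
        prof = profile_with_significant(20, [5, 6, 12])  # 0-based for 6,7,13
        (cov,) = domain_coverage(prof, [("D", 6, 10)])
        assert cov.eligible
        assert cov.coverage == pytest.approx(0.4)
        assert cov.control == pytest.approx((1 / 7) / 5)
        # oracle: enumerate all length-5 windows fully outside the domain
        outside = [(s, s + 5) for s in range(16) if s + 5 <= 5 or s >= 10]
        assert len(outside) == 7

    def test_fully_significant_domain(self):
        prof = profile_with_significant(40, range(10, 15))
        (cov,) = domain_coverage(prof, [("D", 11, 15)])
        assert cov.coverage == 1.0

    def test_long_domain_ineligible(self):
        prof = profile_with_significant(20, [0])
        (cov,) = domain_coverage(prof, [("D", 1, 11)])  # d=11 > 20/2
        assert not cov.eligible
        assert cov.control is None

    def test_no_outside_window_reports_missing_control(self):
        # domain of length 10 in a 20-residue protein leaves two segments of
        # length 5 each: no full window of length 10 fits outside
        prof = profile_with_significant(20, [0])
        (cov,) = domain_coverage(prof, [("D", 6, 15)])
        assert cov.eligible
        assert cov.control is None

    def test_random_placement_matches_analytic_expectation(self, rng):
        """Under uniform random significance, mean coverage approaches the
        marginal rate and mean control approaches its formula value."""
        L, d, rho, trials = 200, 10, 0.1, 1000
        start, end = 96, 105  # central domain, 1-based
        segments = [(0, start - 1), (end, L)]
        n_windows = sum(max(0, (e - s) - d + 1) for s, e in segments)
        covs, ctrls = [], []
        for _ in range(trials):
            sig = rng.random(L) < rho
            prof = profile_from_scores("r", np.zeros(L), width=5)
            prof.significant = sig
            (cov,) = domain_coverage(prof, [("D", start, end)])
            covs.append(cov.coverage)
            ctrls.append(cov.control)
        se_cov = np.std(covs) / np.sqrt(trials)
        assert np.mean(covs) == pytest.approx(rho, abs=3 * se_cov + 1e-9)
        expected_ctrl = rho * (L - d) / (n_windows * d)
        se_ctrl = np.std(ctrls) / np.sqrt(trials)
        assert np.mean(ctrls) == pytest.approx(expected_ctrl, abs=3 * se_ctrl + 1e-9)


class TestSelectDomains:
    def _cov(self, name, coverage, eligible=True):
        return DomainCoverage((name, 1, 5), coverage, 0.01, eligible)

    def test_threshold(self):
        covs = [self._cov("a", 0.4), self._cov("b", 0.29), self._cov("c", 0.31)]
        assert select_domains(covs, cutoff=0.30) == ["a", "c"]

    def test_empty(self):
        assert select_domains([]) == []

    def test_zero_cutoff_returns_all_eligible(self):
        covs = [self._cov("a", 0.0), self._cov("b", 0.5), self._cov("c", 0.2, False)]
        assert select_domains(covs, cutoff=0.0) == ["b", "a"]
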