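"""Scalar mixed ANOVA, permutation 1D RM-ANOVA, design balancing and the
rank/correlation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.stats import mannwhitneyu

from perturbalance.errors import DataError, DegenerateError, DesignError
from perturbalance.inference import (
    balance_design,
    mann_whitney_attempts,
    mixed_anova_scalar,
    pearson_cait,
    sensitivity_leave_one_out,
    spm_rm_anova_1d,
)


# ---------------------------------------------------------------------------
# brute-force sums-of-squares oracle for the balanced two-way mixed design
# ---------------------------------------------------------------------------

def anova_oracle(table: np.ndarray) -> dict:
    """Hand sums-of-squares for a (groups, subjects, sessions) table."""
    a, n, b = table.shape
    grand = table.mean()
    ss_a = ss_subj = ss_b = ss_ab = ss_err = 0.0
    m_g = table.mean(axis=(1, 2))
    m_s = table.mean(axis=(0, 1))
    m_gs = table.mean(axis=1)
    m_gi = table.mean(axis=2)
    for g in range(a):
        ss_a += n * b * (m_g[g] - grand) ** 2
        for i in range(n):
            ss_subj += b * (m_gi[g, i] - m_g[g]) ** 2
            for s in range(b):
                ss_err += (table[g, i, s] - m_gs[g, s] - m_gi[g, i] + m_g[g]) ** 2
    for s in range(b):
        ss_b += a * n * (m_s[s] - grand) ** 2
        for g in range(a):
            ss_ab += n * (m_gs[g, s] - m_g[g] - m_s[s] + grand) ** 2
    out = {}
    out["group"] = dict(
        F=(ss_a / (a - 1)) / (ss_subj / (a * (n - 1))),
        np2=ss_a / (ss_a + ss_subj))
    denom = ss_err / (a * (n - 1) * (b - 1))
    out["session"] = dict(F=(ss_b / (b - 1)) / denom, np2=ss_b / (ss_b + ss_err))
    out["interaction"] = dict(
        F=(ss_ab / ((a - 1) * (b - 1))) / denom, np2=ss_ab / (ss_ab + ss_err))
    return out


def _long_format(table: np.ndarray) -> pd.DataFrame:
    a, n, b = table.shape
    rows = []
    for g in range(a):
        for i in range(n):
            for s in range(b):
                rows.append(dict(subject=f"g{g}i{i}", group=f"G{g}",
                                 session=s + 1, value=table[g, i, s]))
    return pd.DataFrame(rows)


class TestMixedAnovaScalar:
    def test_matches_sums_of_squares_oracle_on_integer_table(self):
        table = np.array([  # 2 groups x 3 subjects x 3 sessions
            [[4, 6, 8], [5, 7, 6], [3, 5, 9]],
            [[7, 5, 4], [8, 6, 5], [6, 7, 3]]], dtype=float)
        oracle = anova_oracle(table)
        results = {r.effect: r for r in mixed_anova_scalar(_long_format(table))}
        for effect in ("group", "session", "interaction"):
            assert results[effect].F == pytest.approx(oracle[effect]["F"], abs=1e-10)
            assert results[effect].partial_eta_sq \
                == pytest.approx(oracle[effect]["np2"], abs=1e-10)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            table = rng.integers(0, 20, size=(2, 5, 3)).astype(float)
            oracle = anova_oracle(table)
            results = {r.effect: r for r in mixed_anova_scalar(_long_format(table))}
            for effect in ("group", "session", "interaction"):
                assert results[effect].F \
                    == pytest.approx(oracle[effect]["F"], abs=1e-10)

    def test_constant_data_yields_null_effects(self):
        table = np.full((2, 4, 3), 5.0)
        for r in mixed_anova_scalar(_long_format(table)):
            assert r.F == 0.0 and r.partial_eta_sq == 0.0

    def test_posthoc_attached_when_interaction_significant(self):
        rng = np.random.default_rng(3)
        table = rng.normal(size=(2, 10, 3))
        table[0] += np.array([0.0, 2.0, 4.0])  # strong session trend in group 0
        results = {r.effect: r for r in mixed_anova_scalar(_long_format(table))}
        inter = results["interaction"]
        assert inter.p < 0.05
        assert len(inter.posthoc) == 6  # 3 contrasts x 2 groups
        labels = [c for c, _ in inter.posthoc]
        assert any("G0" in lab for lab in labels)

    def test_incomplete_subject_dropped(self):
        df = _long_format(np.random.default_rng(0).normal(size=(2, 4, 3)))
        df = df[~((df.subject == "g0i0") & (df.session == 3))]
        results = mixed_anova_scalar(df)  # should not raise
        assert len(results) == 3


class TestSpmRmAnova:
    def _null_waveforms(self, seed, n=8, b=3, k=41):
        rng = np.random.default_rng(seed)
        return gaussian_filter1d(rng.standard_normal((n, b, k)), 4.0, axis=-1)

    def test_identical_waveforms_give_no_clusters(self):
        y = np.tile(np.sin(np.linspace(0, 3, 41)), (8, 3, 1))
        res = spm_rm_anova_1d(y, groups=["A"] * 4 + ["B"] * 4,
                              n_permutations=100, seed=0)
        for r in res.values():
            assert r.clusters == []
            assert np.allclose(r.f_trace, 0.0)

    def test_localized_effect_detected_where_injected(self):
        """A session effect injected into nodes 30-50 must produce a
        cluster overlapping that support in most replicates."""
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            y = gaussian_filter1d(rng.standard_normal((12, 3, 101)), 6.0, axis=-1)
            bump = np.zeros(101)
            bump[30:51] = 1.2
            y[:, 1, :] += bump
            y[:, 2, :] += 2 * bump
            res = spm_rm_anova_1d(y, design="one-way", n_permutations=200,
                                  seed=rep)["session"]
            for lo, hi in res.clusters:
                if lo <= 0.50 and hi >= 0.30:
                    hits += 1
                    break
        assert hits >= 9

    def test_unbalanced_two_way_rejected_with_guidance(self):
        y = self._null_waveforms(0, n=9)
        with pytest.raises(DesignError, match="balance_design"):
            spm_rm_anova_1d(y, groups=["A"] * 5 + ["B"] * 4, n_permutations=100)

    def test_reproducible_from_seed(self):
        y = self._null_waveforms(7)
        groups = ["A"] * 4 + ["B"] * 4
        r1 = spm_rm_anova_1d(y, groups=groups, n_permutations=150, seed=5)
        r2 = spm_rm_anova_1d(y, groups=groups, n_permutations=150, seed=5)
        for e in r1:
            assert r1[e].threshold == r2[e].threshold
            assert r1[e].p_max == r2[e].p_max

    def test_effects_subset(self):
        y = self._null_waveforms(1)
        res = spm_rm_anova_1d(y, groups=["A"] * 4 + ["B"] * 4,
                              n_permutations=100, effects=["interaction"])
        assert list(res) == ["interaction"]

    def test_min_permutations_enforced(self):
        with pytest.raises(DataError):
            spm_rm_anova_1d(self._null_waveforms(2), design="one-way",
                            n_permutations=50)


class TestBalanceDesign:
    def test_trims_surplus_group(self):
        groups = {f"C{i}": "CAI" for i in range(22)}
        groups.update({f"H{i}": "HC" for i in range(23)})
        kept, dropped, note = balance_design(groups, seed=1)
        assert len(kept) == 44 and len(dropped) == 1
        assert dropped[0].startswith("H")
        assert "HC" in note

    def test_balanced_input_is_noop(self):
        groups = {"a": "CAI", "b": "HC"}
        kept, dropped, note = balance_design(groups)
        assert kept == ["a", "b"] and dropped == []
        assert "already balanced" in note

    def test_pinned_drop(self):
        groups = {"c1": "CAI", "h1": "HC", "h2": "HC"}
        kept, dropped, _ = balance_design(groups, drop="h2")
        assert dropped == ["h2"]
        with pytest.raises(DesignError):
            balance_design(groups, drop="c1")

    def test_sensitivity_reports_all_exclusions(self):
        rng = np.random.default_rng(21)
        n_cai, n_hc = 5, 6
        ids = [f"C{i}" for i in range(n_cai)] + [f"H{i}" for i in range(n_hc)]
        groups = {s: ("CAI" if s.startswith("C") else "HC") for s in ids}
        y = gaussian_filter1d(rng.standard_normal((11, 3, 41)), 4.0, axis=-1)
        bump = np.zeros(41)
        bump[15:25] = 3.0
        y[:n_cai, 2, :] += bump  # strong CAI-only session-3 effect
        report = sensitivity_leave_one_out(
            y, ids, groups, effect="interaction", n_permutations=150, seed=3)
        assert len(report["replicates"]) == n_hc
        assert all(len(cl) > 0 for cl in report["replicates"].values())
        assert report["mean_jaccard"] > 0.3


class TestScalarTests:
    def test_perfect_negative_correlation(self):
        cait = np.array([16.0, 18, 20, 22])
        assert pearson_cait(cait, -2 * cait + 100)[0] == pytest.approx(-1.0)

    def test_hand_negative_case(self):
        cait = np.array([16.0, 18, 20, 22])
        cci = np.array([70.0, 68, 65, 60])
        r, p = pearson_cait(cait, cci)
        # hand Pearson: sum of dev products -33, ss 20 and 56.75,
        # r = -33 / sqrt(20 * 56.75)
        assert r == pytest.approx(-33.0 / np.sqrt(20.0 * 56.75), abs=1e-12)
        assert r < 0 and p < 0.05

    def test_degenerate_correlation(self):
        with pytest.raises(DegenerateError):
            pearson_cait(np.array([1.0, 1, 1]), np.array([2.0, 3, 4]))

    def test_mann_whitney_identical_samples(self):
        a = np.array([3.0, 3, 3, 3])
        u, z, p = mann_whitney_attempts(a, a)
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert z == 0.0 and p == 1.0

    def test_mann_whitney_complete_separation(self):
        u, z, p = mann_whitney_attempts([1, 2, 3], [4, 5, 6])
        assert u == 0.0  # smaller-U convention
        assert z < 0

    def test_mann_whitney_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        a = rng.integers(1, 8, 22)
        b = rng.integers(1, 8, 23)
        u, z, p = mann_whitney_attempts(a, b)
        ref = mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_mann_whitney_large_shift_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 20)
        b = rng.normal(4, 1, 20)
        _, _, p = mann_whitney_attempts(a, b)
        assert p < 0.001
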