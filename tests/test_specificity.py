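import itertools
import math

import numpy as np
import pytest
from scipy import stats

from secirc.circ_association import CircClass, SE_LABEL, TE_LABEL
from secirc.io_formats import ExpressionMatrix, Interval
from secirc.specificity import (
    ContingencyTable2x2,
    class_expression_summary,
    fisher_association,
    is_specific,
    mann_whitney,
    specificity_index,
    stage_specific_ses,
)

import pandas as pd


# --- independent oracles ----------------------------------------------------

def jsd2_oracle(p, q):
    """Jensen-Shannon divergence, log base 2, written from the definition."""
    p, q = np.asarray(p, float), np.asarray(q, float)
    p, q = p / p.sum(), q / q.sum()
    m = (p + q) / 2

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def js_spec_oracle(profile):
    p = np.asarray(profile, float)
    p = p / p.sum()
    e = np.zeros_like(p)
    e[int(np.argmax(p))] = 1.0
    return 1.0 - math.sqrt(jsd2_oracle(p, e))


def fisher_oracle(a, b, c, d):
    """Sum hypergeometric probabilities of tables at most as likely as
    observed, margins fixed — the textbook two-sided exact test."""
    r1, r2, c1 = a + b, c + d, a + c
    N = r1 + r2
    if N == 0:
        return 1.0
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(ks, N, r1, c1)
    pobs = float(pmf[ks == a][0])
    return float(min(pmf[pmf <= pobs * (1 + 1e-10)].sum(), 1.0))


def mw_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group splits."""
    n = len(x)
    pooled = list(x) + list(y)

    def ustat(xs, ys):
        return sum(
            1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in xs for yj in ys
        )

    u_obs = ustat(x, y)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(ustat(xs, ys))
    us = np.array(us)
    ple = np.mean(us <= u_obs + 1e-9)
    pge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(ple, pge))


# --- specificity index ------------------------------------------------------

class TestSpecificityIndex:
    def test_one_hot_scores_one(self):
        assert specificity_index([0, 0, 5, 0]).score == pytest.approx(1.0)

    def test_uniform_matches_formula(self):
        for k in (2, 5, 10):
            got = specificity_index([1.0] * k).score
            assert got == pytest.approx(js_spec_oracle([1.0] * k), abs=1e-12)

    def test_two_tissue_closed_form(self):
        # JSD2([1/2,1/2],[1,0]) = 1/2 KL(p||m) + 1/2 KL(q||m) with
        # m = [3/4, 1/4]: equals 3/2 - (3/4) log2 3 exactly
        expected = 1.0 - math.sqrt(1.5 - 0.75 * math.log2(3.0))
        assert specificity_index([1.0, 1.0]).score == pytest.approx(expected, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            specificity_index([0.0, 0.0])

    def test_argmax_tie_takes_first_tissue(self):
        s = specificity_index([2.0, 2.0, 1.0], tissues=["a", "b", "c"])
        assert s.argmax_tissue == "a"

    def test_scale_invariance_and_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.random(6) + 0.01
            base = specificity_index(p).score
            assert specificity_index(p * 37.5).score == pytest.approx(base, abs=1e-12)
            perm = rng.permutation(6)
            assert specificity_index(p[perm]).score == pytest.approx(base, abs=1e-12)

    def test_monotone_concentration(self):
        """Adding expression mass to the argmax tissue never lowers the score."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            p = rng.random(5) + 0.01
            k = int(np.argmax(p))
            before = specificity_index(p).score
            p2 = p.copy()
            p2[k] += rng.random() * 2
            assert specificity_index(p2).score >= before - 1e-12


class TestIsSpecific:
    @pytest.mark.parametrize(
        "score,tau,expected", [(1.0, 0.8, True), (0.0, 0.8, False), (0.8, 0.8, True)]
    )
    def test_closed_threshold(self, score, tau, expected):
        assert is_specific(score, tau) is expected


# --- stage-specific SEs -----------------------------------------------------

class TestStageSpecificSEs:
    def iv(self, start, end):
        return Interval("chr1", start, end, f"se_{start}")

    def test_identical_sets_all_shared(self):
        ses = {"embryonic": [self.iv(0, 100)], "adult": [self.iv(0, 100)]}
        split = stage_specific_ses(ses)
        assert split["embryonic"]["specific"] == []
        assert split["adult"]["specific"] == []

    def test_disjoint_sets_all_specific(self):
        ses = {"embryonic": [self.iv(0, 100)], "adult": [self.iv(500, 600)]}
        split = stage_specific_ses(ses)
        assert len(split["embryonic"]["specific"]) == 1
        assert len(split["adult"]["specific"]) == 1

    def test_sixty_percent_cover_is_shared_at_half_threshold(self):
        ses = {"embryonic": [self.iv(0, 100)], "adult": [self.iv(40, 200)]}
        split = stage_specific_ses(ses, max_other_cover=0.5)
        assert split["embryonic"]["shared"] and not split["embryonic"]["specific"]
        # coverage counts the union without double counting
        ses["adult"].append(self.iv(40, 120))
        assert stage_specific_ses(ses, 0.61)["embryonic"]["specific"]


# --- exact tests ------------------------------------------------------------

class TestFisher:
    def test_balanced_table(self):
        odds, p = fisher_association(ContingencyTable2x2(1, 1, 1, 1))
        assert odds == 1.0 and p == 1.0

    def test_odds_ratio_is_ad_over_bc(self):
        odds, _ = fisher_association(ContingencyTable2x2(4, 1, 2, 3))
        assert odds == 6.0

    def test_degenerate_odds(self):
        assert fisher_association(ContingencyTable2x2(5, 0, 0, 5))[0] == math.inf
        assert fisher_association(ContingencyTable2x2(0, 3, 4, 5))[0] == 0.0
        assert math.isnan(fisher_association(ContingencyTable2x2(0, 3, 0, 5))[0])

    def test_perfect_separation_p(self):
        _, p = fisher_association(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 8, 4))
            _, p = fisher_association(ContingencyTable2x2(a, b, c, d))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


class TestMannWhitney:
    def test_extreme_separation_matches_enumeration(self):
        x, y = [10.0, 11.0, 12.0, 13.0], [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(x, y)
        assert u == 16.0
        assert p == pytest.approx(mw_oracle(x, y), abs=1e-12)
        assert p == pytest.approx(2 / math.comb(8, 4), abs=1e-12)

    def test_random_configurations_match_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            vals = rng.permutation(40)[:8].astype(float)
            x, y = list(vals[:4]), list(vals[4:])
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(mw_oracle(x, y), abs=1e-9)


# --- class expression summary ----------------------------------------------

def _matrix(values_by_circ):
    cols = ["heart:adult:1", "heart:adult:2"]
    frame = pd.DataFrame(
        {c: [v, v] for c, v in values_by_circ.items()}, index=cols
    ).T.astype(float)
    return ExpressionMatrix(frame)


class TestClassExpression:
    def test_identical_distributions_equal_medians(self):
        matrix = _matrix({"a": 3.0, "b": 3.0, "c": 3.0, "d": 3.0})
        classes = [
            CircClass("a", SE_LABEL), CircClass("b", SE_LABEL),
            CircClass("c", TE_LABEL), CircClass("d", TE_LABEL),
        ]
        summary = class_expression_summary(matrix, classes)
        assert summary.median_rpm[SE_LABEL] == summary.median_rpm[TE_LABEL]

    def test_separated_classes_small_p(self):
        values = {f"s{i}": 10.0 + i for i in range(4)} | {f"t{i}": float(i) for i in range(4)}
        classes = [CircClass(f"s{i}", SE_LABEL) for i in range(4)] + [
            CircClass(f"t{i}", TE_LABEL) for i in range(4)
        ]
        summary = class_expression_summary(_matrix(values), classes)
        assert summary.p_value == pytest.approx(2 / math.comb(8, 4), abs=1e-12)

    def test_empty_class_skips_test_with_warning(self):
        matrix = _matrix({"a": 1.0})
        with pytest.warns(UserWarning):
            summary = class_expression_summary(matrix, [CircClass("a", SE_LABEL)])
        assert summary.p_value is None


def test_planted_se_circs_more_specific(default_dataset):
    """The generator plants tighter tissue profiles on SE-circRNAs; the JS
    index must separate the planted classes on average."""
    from secirc.io_formats import read_expression_matrix
    from secirc.specificity import tissue_specificity_scores

    _, paths, ledger = default_dataset
    matrix = read_expression_matrix(paths["expression"])
    scores = tissue_specificity_scores(matrix)
    se = {cid for cid in ledger.planted_SE_circ_ids}
    se_scores = [s.score for cid, s in scores.items() if cid in se]
    other_scores = [s.score for cid, s in scores.items() if cid not in se]
    assert np.mean(se_scores) > np.mean(other_scores)
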