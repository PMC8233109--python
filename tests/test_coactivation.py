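import numpy as np
import pandas as pd
import pytest
from scipy import stats

from targetcontrol import (
    DirectedNetwork,
    coactivation_screen,
    differential_coactivation,
    dysregulated_on_walk,
    simulate_expression,
    spearman_pair,
    gene_activation,
)
from targetcontrol.coactivation import (
    COACTIVATED,
    NO_WALK,
    UNTESTABLE,
    _exact_null_abs_rho,
)
from targetcontrol.stepwise import StepwiseResult
from targetcontrol.synthetic import CoactivationEffect, ExpressionEffects


def result(driver, controllable, ranked):
    return StepwiseResult(
        driver=driver,
        tau=len(controllable),
        controllable=tuple(controllable),
        ranked_targets=tuple(ranked),
        steps=(),
    )


def activation_table(columns, genes, groups):
    from targetcontrol import ActivationTable

    return ActivationTable(
        values=pd.DataFrame(columns, index=genes), groups=pd.Series(groups)
    )


class TestSpearmanPair:
    def test_perfect_monotone_association(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert spearman_pair(x, [v**2 for v in x])[0] == pytest.approx(1.0)
        assert spearman_pair(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_constant_vector_is_never_significant(self, caplog):
        with caplog.at_level("WARNING"):
            rho, p = spearman_pair([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and p == 1.0

    def test_exact_p_matches_independent_permutation_oracle(self):
        """Cross-check the cached enumeration against scipy's generic
        permutation machinery on a small untied sample."""
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=6)
        rho, p = spearman_pair(x, y, method="exact")

        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic

        ref = stats.permutation_test(
            (y,), statistic, permutation_type="pairings",
            n_resamples=np.inf, alternative="two-sided",
        )
        assert rho == pytest.approx(float(stats.spearmanr(x, y).statistic))
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_detection_equals_enumerated_critical_region(self):
        """p < alpha iff |rho| reaches the critical value of the exact null."""
        null = _exact_null_abs_rho(8)
        alpha = 0.05
        crit = min(
            v for v in np.unique(null)
            if (null >= v - 1e-12).sum() / null.size < alpha
        )
        rng = np.random.default_rng(11)
        for _ in range(40):
            x, y = rng.normal(size=8), rng.normal(size=8)
            rho, p = spearman_pair(x, y, method="exact")
            assert (p < alpha) == (abs(rho) >= crit - 1e-12)

    def test_invariant_under_strictly_monotone_transforms(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=9), rng.normal(size=9)
        base = spearman_pair(x, y)
        assert spearman_pair(np.exp(x), y) == pytest.approx(base)
        assert spearman_pair(x, y**3) == pytest.approx(base)

    def test_exact_refuses_ties_and_large_n(self):
        with pytest.raises(ValueError, match="tie"):
            spearman_pair([1, 1, 2, 3], [1, 2, 3, 4], method="exact")
        with pytest.raises(ValueError, match="exact"):
            spearman_pair(np.arange(12), np.arange(12.0) ** 2, method="exact")


class TestScreen:
    GENES = ["d1", "d2", "t1", "t2"]

    def base_activation(self):
        rng = np.random.default_rng(8)
        cols = {f"h{i}": rng.normal(size=4) ** 2 + 0.1 for i in range(6)}
        cols |= {f"m{i}": rng.normal(size=4) ** 2 + 0.1 for i in range(6)}
        groups = {f"h{i}": "HC" for i in range(6)} | {f"m{i}": "MS" for i in range(6)}
        return activation_table(cols, self.GENES, groups)

    def results(self):
        return {
            "d1": result("d1", ["t1", "t2"], ["t1", "t2"]),
            "d2": result("d2", [], ["t1", "t2"]),
        }

    def test_alpha_zero_marks_nothing(self):
        screens = coactivation_screen(self.base_activation(), self.results(), alpha=0.0)
        for mat in screens.values():
            assert not mat.coactivated_pairs()

    def test_identical_vectors_coactivate(self):
        act = self.base_activation()
        values = act.values.copy()
        values.loc["t1"] = values.loc["d1"]  # perfect rank correlation
        act = activation_table(values.to_dict("list"), self.GENES, act.groups.to_dict())
        screens = coactivation_screen(act, self.results())
        for mat in screens.values():
            assert ("d1", "t1") in mat.coactivated_pairs()

    def test_only_controllable_pairs_tested(self):
        screens = coactivation_screen(self.base_activation(), self.results())
        for mat in screens.values():
            assert mat.coactivated_pairs() <= mat.controllable_pairs()
            assert (mat.state.loc["d2"] == NO_WALK).all()
            assert np.isnan(mat.rho.loc["d2"]).all()

    def test_missing_gene_marked_untestable(self):
        act = self.base_activation()
        trimmed = activation_table(
            act.values.drop(index="t2").to_dict("list"),
            ["d1", "d2", "t1"],
            act.groups.to_dict(),
        )
        screens = coactivation_screen(trimmed, self.results())
        assert screens["HC"].state.loc["d1", "t2"] == UNTESTABLE

    def test_bh_correction_never_adds_calls(self):
        act = self.base_activation()
        raw = coactivation_screen(act, self.results())
        adj = coactivation_screen(act, self.results(), correction="bh")
        for g in raw:
            assert adj[g].coactivated_pairs() <= raw[g].coactivated_pairs()


class TestDifferential:
    def mat(self, coactivated):
        state = pd.DataFrame(
            "controllable-not-significant", index=["d"], columns=["t1", "t2"]
        )
        for t in coactivated:
            state.loc["d", t] = COACTIVATED
        from targetcontrol import CoactivationMatrix

        nan = pd.DataFrame(np.nan, index=["d"], columns=["t1", "t2"])
        return CoactivationMatrix(group="g", state=state, rho=nan, p=nan, alpha=0.05)

    def test_identical_matrices_no_difference(self):
        assert differential_coactivation(self.mat(["t1"]), self.mat(["t1"])) == set()

    def test_single_flip_detected_and_symmetric(self):
        a, b = self.mat(["t1", "t2"]), self.mat(["t1"])
        assert differential_coactivation(a, b) == {("d", "t2")}
        assert differential_coactivation(b, a) == {("d", "t2")}

    def test_planted_group_specific_coactivation_recovered(self):
        eff = ExpressionEffects(
            coactivated=(CoactivationEffect("d1", "t1", 0.98, groups=("HC",)),)
        )
        expr, _ = simulate_expression(
            ["d1", "t1", "t2"], n_per_group=9, effects=eff, seed=31
        )
        act = gene_activation(expr)
        results = {"d1": result("d1", ["t1", "t2"], ["t1", "t2"])}
        screens = coactivation_screen(act, results)
        diff = differential_coactivation(screens["HC"], screens["MS"])
        assert ("d1", "t1") in diff


class TestDysregulatedOnWalk:
    NET = DirectedNetwork.from_edges(
        [("d", "m"), ("m", "t"), ("d", "x"), ("x", "y")]
    )

    def test_no_dysregulation_no_witness(self):
        flag, witnesses = dysregulated_on_walk(self.NET, "d", "t", set())
        assert not flag and witnesses == ()

    def test_dysregulated_driver_counts(self):
        flag, witnesses = dysregulated_on_walk(self.NET, "d", "t", {"d"})
        assert flag and witnesses == ("d",)

    def test_intermediate_witness_found_and_off_walk_ignored(self):
        flag, witnesses = dysregulated_on_walk(self.NET, "d", "t", {"m", "y"})
        assert flag and witnesses == ("m",)
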