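import itertools

import numpy as np
import pandas as pd
import pytest

from frondscape.errors import InsufficientDataError, TransformFailureError
from frondscape.stats import (
    Branch,
    ancova_light_contrast,
    bonferroni,
    cascade,
    check_assumptions,
    light_contrasts,
    two_way_anova_omega,
)

CLONES = ["c1", "c2", "c3", "c4"]
LIGHTS = ["low", "high"]


def design(cell_values: dict, reps=None) -> pd.DataFrame:
    rows = []
    for (clone, light), vals in cell_values.items():
        for v in vals:
            rows.append({"clone": clone, "light": light, "response": float(v)})
    return pd.DataFrame(rows)


def random_design(rng, n_clone=4, n_light=2, reps=6, effects=(0, 0, 0), sd=1.0):
    rows = []
    clone_eff = rng.normal(0, effects[0], n_clone)
    light_eff = rng.normal(0, effects[1], n_light)
    int_eff = rng.normal(0, effects[2], (n_clone, n_light))
    for i in range(n_clone):
        for j in range(n_light):
            mu = 10 + clone_eff[i] + light_eff[j] + int_eff[i, j]
            for v in rng.normal(mu, sd, reps):
                rows.append({"clone": f"c{i}", "light": LIGHTS[j], "response": float(v)})
    return pd.DataFrame(rows)


def anova_oracle(df: pd.DataFrame):
    """Mean-decomposition oracle written with explicit loops, independent of
    the vectorised implementation."""
    y = df["response"].to_numpy(float)
    grand = y.mean()
    ss_total = sum((v - grand) ** 2 for v in y)
    ss_a = sum(len(g) * (g["response"].mean() - grand) ** 2
               for _, g in df.groupby("clone"))
    ss_b = sum(len(g) * (g["response"].mean() - grand) ** 2
               for _, g in df.groupby("light"))
    ss_cells = sum(len(g) * (g["response"].mean() - grand) ** 2
                   for _, g in df.groupby(["clone", "light"]))
    return ss_a, ss_b, ss_cells - ss_a - ss_b, ss_total - ss_cells, ss_total


class TestTwoWayAnova:
    def test_hand_computable_2x2(self):
        """cells (1,1):1,1 (1,2):2,2 (2,1):3,3 (2,2):4,4 -> SS 8, 2, 0, err 0."""
        df = design({("a", "low"): [1, 1], ("a", "high"): [2, 2],
                     ("b", "low"): [3, 3], ("b", "high"): [4, 4]})
        out = two_way_anova_omega(df)
        assert out.loc["clone", "ss"] == pytest.approx(8.0, abs=1e-12)
        assert out.loc["light", "ss"] == pytest.approx(2.0, abs=1e-12)
        assert out.loc["clone:light", "ss"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["error", "ss"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_loop_oracle_on_random_tables(self, rng):
        for _ in range(50):
            df = random_design(rng, reps=int(rng.integers(2, 7)),
                               effects=rng.uniform(0, 2, 3), sd=rng.uniform(0.5, 2))
            out = two_way_anova_omega(df)
            ss_a, ss_b, ss_ab, ss_err, ss_tot = anova_oracle(df)
            assert out.loc["clone", "ss"] == pytest.approx(ss_a, abs=1e-9)
            assert out.loc["light", "ss"] == pytest.approx(ss_b, abs=1e-9)
            assert out.loc["clone:light", "ss"] == pytest.approx(ss_ab, abs=1e-9)
            assert out.loc["error", "ss"] == pytest.approx(ss_err, abs=1e-9)
            # SS additivity on balanced designs
            terms = out.loc[["clone", "light", "clone:light", "error"], "ss"].sum()
            assert terms == pytest.approx(out.loc["total", "ss"], abs=1e-9)

    def test_matches_pingouin(self, rng):
        """Independent library cross-check of F and p."""
        pingouin = pytest.importorskip("pingouin")
        df = random_design(rng, reps=6, effects=(1.0, 0.5, 0.3), sd=1.0)
        ours = two_way_anova_omega(df)
        theirs = pingouin.anova(data=df, dv="response",
                                between=["clone", "light"]).set_index("Source")
        for ours_term, pg_term in [("clone", "clone"), ("light", "light"),
                                   ("clone:light", "clone * light")]:
            assert ours.loc[ours_term, "F"] == pytest.approx(
                float(theirs.loc[pg_term, "F"]), rel=1e-9)
            assert ours.loc[ours_term, "p"] == pytest.approx(
                float(theirs.loc[pg_term, "p_unc"]), rel=1e-9, abs=1e-12)

    def test_omega_squared_definition(self, rng):
        df = random_design(rng, reps=6, effects=(2.0, 1.0, 0.0), sd=1.0)
        out = two_way_anova_omega(df)
        ms_err = out.loc["error", "ms"]
        ss_tot = out.loc["total", "ss"]
        for term in ("clone", "light", "clone:light"):
            expected = (out.loc[term, "ss"] - out.loc[term, "df"] * ms_err) / (
                ss_tot + ms_err)
            assert out.loc[term, "omega_sq"] == pytest.approx(expected, abs=1e-12)
            assert out.loc[term, "omega_sq"] <= 1.0

    def test_null_omega_centered_on_zero(self, rng):
        """Over many null tables the mean omega^2 of each term stays near 0."""
        omegas = {"clone": [], "light": [], "clone:light": []}
        for _ in range(300):
            out = two_way_anova_omega(random_design(rng, reps=4, sd=1.0))
            for t in omegas:
                omegas[t].append(out.loc[t, "omega_sq"])
        for t, vals in omegas.items():
            assert abs(float(np.mean(vals))) <= 0.02

    def test_constant_responses_convention(self):
        df = design({(c, l): [5.0, 5.0] for c in CLONES[:2] for l in LIGHTS})
        out = two_way_anova_omega(df)
        assert (out.loc[["clone", "light", "clone:light"], "omega_sq"] == 0).all()
        assert (out.loc[["clone", "light", "clone:light"], "ss"] == 0).all()

    def test_single_replicate_rejected(self):
        df = design({(c, l): [1.0] for c in CLONES[:2] for l in LIGHTS})
        with pytest.raises(InsufficientDataError):
            two_way_anova_omega(df)


class TestAssumptionChecks:
    def test_well_behaved_data_passes_majority(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            flags.append(check_assumptions(random_design(rng, reps=6))
                         .log_transform_applied)
        assert sum(flags) < 10

    def test_lognormal_heteroscedastic_triggers_transform(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = []
            for i, clone in enumerate(CLONES):
                for light in LIGHTS:
                    mu = 1.0 + i * 1.5 + (light == "high") * 1.0
                    for v in np.exp(rng.normal(mu, 0.8, 6)):
                        rows.append({"clone": clone, "light": light, "response": v})
            flags.append(check_assumptions(pd.DataFrame(rows)).log_transform_applied)
        assert sum(flags) > 10

    def test_constant_data_degenerate_warning(self):
        df = design({(c, l): [5.0, 5.0] for c in CLONES[:2] for l in LIGHTS})
        checks = check_assumptions(df)
        assert not checks.log_transform_applied
        assert checks.warning is not None

    def test_transform_failure_on_nonpositive(self):
        rng = np.random.default_rng(0)
        df = random_design(rng, reps=6)
        df.loc[0, "response"] = -5.0
        df.loc[1, "response"] = 5000.0  # force a violation
        with pytest.raises(TransformFailureError):
            check_assumptions(df)


class TestBonferroni:
    def test_cap_monotone_idempotent(self):
        assert bonferroni(0.01, 6) == pytest.approx(0.06)
        assert bonferroni(0.4, 6) == 1.0
        assert bonferroni(bonferroni(0.4, 6), 1) == 1.0  # idempotent at cap
        ps = np.array([0.001, 0.01, 0.02, 0.5])
        adj = bonferroni(ps, 6)
        assert (np.diff(adj) >= 0).all()  # monotone


class TestCascade:
    def test_interaction_branch_fires(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = random_design(rng, reps=6, effects=(0, 0, 3.0), sd=1.0)
            res = cascade(df)
            if Branch.INTERACTION in res.branches_taken:
                hits += 1
                assert any(k.startswith("clones@") for k in res.posthoc)
        assert hits >= 11

    def test_null_data_mostly_no_branch(self):
        none_count = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = cascade(random_design(rng, reps=6))
            if res.branch_taken == Branch.NONE:
                none_count += 1
        assert none_count > 50  # ~86% expected at alpha 0.05 over three terms

    def test_clone_main_branch_pigment_mode_adjustment(self):
        rng = np.random.default_rng(1)
        df = random_design(rng, reps=6, effects=(4.0, 0, 0), sd=0.5)
        df["response"] += 20  # keep positive for a possible log branch
        res = cascade(df, mode="pigment")
        assert Branch.CLONE_MAIN in res.branches_taken
        ph = res.posthoc["clones_overall"]
        assert len(ph) == 6  # 4 choose 2 comparisons
        assert (ph.test == "mann-whitney").all()
        for r in ph.itertuples():
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * 6))

    def test_light_branch_runs_contrasts(self):
        rng = np.random.default_rng(2)
        df = random_design(rng, reps=6, effects=(0, 5.0, 0), sd=0.5)
        res = cascade(df)
        assert Branch.LIGHT_MAIN in res.branches_taken
        assert res.light_contrasts is not None
        assert set(res.light_contrasts.clone) == {"c0", "c1", "c2", "c3"}
        assert {"f_p", "t_p"} <= set(res.light_contrasts.columns)

    def test_cascade_is_pure(self):
        rng = np.random.default_rng(3)
        df = random_design(rng, reps=6, effects=(2.0, 2.0, 0), sd=1.0)
        a, b = cascade(df), cascade(df)
        assert a.branches_taken == b.branches_taken
        pd.testing.assert_frame_equal(a.two_way, b.two_way)


class TestLightContrasts:
    def test_identical_groups_zero_difference(self):
        df = design({("a", "low"): [1, 2, 3], ("a", "high"): [1, 2, 3]})
        out = light_contrasts(df)
        assert out.mean_diff.iloc[0] == pytest.approx(0.0)
        assert out.f_stat.iloc[0] == pytest.approx(1.0)


class TestAncova:
    def test_pure_offset_recovered(self):
        rng = np.random.default_rng(4)
        length = np.tile(np.linspace(1, 6, 30), 2)
        light = np.array(["low"] * 30 + ["high"] * 30)
        y = 0.4 + 0.03 * length + 0.1 * (light == "low") + rng.normal(0, 1e-6, 60)
        df = pd.DataFrame({"mean_yii": y, "frond_length_mm": length, "light": light})
        effect, p = ancova_light_contrast(df)
        assert effect == pytest.approx(0.1, abs=1e-4)
        assert p < 1e-10

    def test_identical_groups_null_effect(self):
        rng = np.random.default_rng(5)
        length = np.tile(np.linspace(1, 6, 30), 2)
        light = np.array(["low"] * 30 + ["high"] * 30)
        y = 0.4 + 0.03 * length + rng.normal(0, 0.01, 60)
        df = pd.DataFrame({"mean_yii": y, "frond_length_mm": length, "light": light})
        effect, _ = ancova_light_contrast(df)
        assert abs(effect) < 0.02

    def test_power_at_study_conditions(self):
        """Low/high offsets like the observed mature-frond Y(II) split are
        detected at p < 1e-4 in nearly every replicate."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            length = np.concatenate([rng.uniform(1, 6, 30), rng.uniform(1, 6, 30)])
            light = np.array(["low"] * 30 + ["high"] * 30)
            base = np.where(light == "low", 0.66, 0.55)
            y = base + 0.01 * length + rng.normal(0, 0.02, 60)
            df = pd.DataFrame({"mean_yii": y, "frond_length_mm": length, "light": light})
            _, p = ancova_light_contrast(df)
            if p < 1e-4:
                hits += 1
        assert hits >= 18

    def test_degenerate_rejected(self):
        df = pd.DataFrame({"mean_yii": [0.5, 0.6], "frond_length_mm": [1.0, 1.0],
                           "light": ["low", "low"]})
        with pytest.raises(InsufficientDataError):
            ancova_light_contrast(df)
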