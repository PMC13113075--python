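import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocpartition import (
    FeatureTable,
    GeneratorConfig,
    TraitParams,
    build_design,
    default_config,
    generate_dataset,
    simulate_traits,
)
from vocpartition import variance_partition as vp

from conftest import make_rows


def balanced_one_way(n_animals=25, n_per=9, s_animal=2.0, s_resid=1.2, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_animals):
        u = rng.normal(0, s_animal)
        for j in range(n_per):
            r = make_rows(n_animals=1, n_samples=1).iloc[0].to_dict()
            r.update(animal_id=f"{i:02d}", recording_id=f"{i:02d}-r{j}",
                     intensity=70 + u + rng.normal(0, s_resid))
            rows.append(r)
    return FeatureTable(pd.DataFrame(rows))


class TestICC:
    @pytest.mark.parametrize("comp, expected", [
        (vp.VarianceComponents(1.0, None, 3.0), 0.25),
        (vp.VarianceComponents(0.0, None, 5.0), 0.0),
        (vp.VarianceComponents(1.0, 1.0, 2.0), 0.25),
    ])
    def test_arithmetic(self, comp, expected):
        assert vp.icc(comp) == pytest.approx(expected)

    def test_zero_components_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            vp.icc(vp.VarianceComponents(0.0, None, 0.0))

    def test_icc_invariant_to_shift_and_scale(self):
        table = balanced_one_way(seed=3)
        base = vp.icc(vp.mom_variance_oracle(table, "intensity"))
        shifted = table.data.copy()
        shifted["intensity"] = 4.0 * shifted["intensity"] + 100.0
        other = vp.icc(vp.mom_variance_oracle(FeatureTable(shifted), "intensity"))
        assert other == pytest.approx(base, rel=1e-9)


class TestMomOracle:
    def test_hand_computed_two_by_two(self):
        # animals {0,0} and {2,2}: MS_within = 0, MS_between = 4, n0 = 2
        df = make_rows(n_animals=2, n_samples=2)
        df["intensity"] = [0.0, 0.0, 2.0, 2.0]
        comp = vp.mom_variance_oracle(FeatureTable(df), "intensity")
        assert comp.sigma2_resid == pytest.approx(0.0)
        assert comp.sigma2_animal == pytest.approx(2.0)

    def test_constant_values_zero_components(self):
        df = make_rows(n_animals=3, n_samples=2)
        df["intensity"] = 5.0
        comp = vp.mom_variance_oracle(FeatureTable(df), "intensity")
        assert comp.sigma2_animal == 0.0 and comp.sigma2_resid == 0.0

    def test_unbalanced_rejected(self):
        df = make_rows(n_animals=2, n_samples=3).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            vp.mom_variance_oracle(FeatureTable(df), "intensity")


class TestREMLAgainstOracle:
    def test_reml_equals_mom_on_balanced_one_way(self):
        table = balanced_one_way(seed=7)
        mom = vp.mom_variance_oracle(table, "intensity")
        fit = vp.fit_lmm(table, "intensity", fixed=(), random=("animal",))
        assert fit.components.sigma2_animal == pytest.approx(
            mom.sigma2_animal, rel=1e-6)
        assert fit.components.sigma2_resid == pytest.approx(
            mom.sigma2_resid, rel=1e-6)

    def test_zero_animal_effect_estimated_near_zero(self):
        # true sigma2_animal = 0: the REML estimate sits at or near the
        # boundary; the median over seeds stays below 5% of the residual
        ratios = []
        for seed in range(5):
            table = balanced_one_way(s_animal=0.0, s_resid=1.0, seed=seed)
            fit = vp.fit_lmm(table, "intensity", fixed=(), random=("animal",))
            ratios.append(fit.components.sigma2_animal / fit.components.sigma2_resid)
        assert np.median(ratios) < 0.05


class TestNakagawaR2:
    def test_no_fixed_effects_r2m_zero(self):
        table = balanced_one_way(seed=13)
        fit = vp.fit_lmm(table, "intensity", fixed=(), random=("animal",))
        r2m, r2c = vp.nakagawa_r2(fit)
        assert r2m == pytest.approx(0.0, abs=1e-12)
        assert 0 < r2c < 1

    def test_closed_form_recovery(self):
        # condition effects with population variance 2 over the design,
        # sigma2_animal = 1, sigma2_resid = 1 -> R2m = 0.5, R2c = 0.75
        conds = ("normal", "pain", "hunger", "thirst", "cold", "heat")
        effects = dict(zip(conds, [0.0, 2.0, -2.0, 2.0, -2.0, 0.0]))
        var_fixed = np.var(list(effects.values()))  # = 8/3
        cfg = GeneratorConfig(
            n_animals=60,
            availability={"farrowing": conds},
            recordings_per_cell=4,
            traits={"intensity": TraitParams(
                intercept=70.0, condition={k: v for k, v in effects.items() if v},
                sigma2_animal=var_fixed / 2, sigma2_recording=0.0,
                sigma2_resid=var_fixed / 2)},
            seed=5,
        )
        table = simulate_traits(build_design(cfg), cfg)
        fit = vp.fit_lmm(table, "intensity", fixed=("condition",), random=("animal",))
        r2m, r2c = vp.nakagawa_r2(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)

    def test_r2c_at_least_r2m_and_in_unit_interval(self, default_table):
        fit = vp.fit_lmm(default_table, "f2", random=("animal", "recording"))
        r2m, r2c = vp.nakagawa_r2(fit)
        assert 0.0 <= r2m <= r2c <= 1.0


class TestDropOne:
    def test_null_block_near_zero_and_ordering(self):
        cfg = default_config(seed=40)
        cfg.traits = {"intensity": cfg.traits["intensity"]}
        table = generate_dataset(cfg)
        deltas, clamped = vp.drop_one_delta_r2(table, "intensity",
                                               random=("animal",))
        assert deltas["distress"] > deltas["phase"]
        assert deltas["sex"] < 0.02
        assert all(v >= 0 for v in deltas.values())

    def test_distress_only_simulation(self):
        cfg = default_config(seed=41)
        tp = cfg.traits["intensity"]
        cfg.traits = {"intensity": TraitParams(
            intercept=tp.intercept, condition=tp.condition,
            sigma2_animal=tp.sigma2_animal, sigma2_recording=tp.sigma2_recording,
            sigma2_resid=tp.sigma2_resid)}
        table = generate_dataset(cfg)
        full = vp.fit_lmm(table, "intensity", random=("animal",))
        r2m_full, _ = vp.nakagawa_r2(full)
        deltas, _ = vp.drop_one_delta_r2(table, "intensity", random=("animal",),
                                         full_fit=full)
        assert deltas["distress"] == pytest.approx(r2m_full, abs=0.02)
        assert deltas["sex"] == pytest.approx(0.0, abs=0.01)

    def test_unknown_block_errors(self, default_table):
        with pytest.raises(ValueError, match="unknown block"):
            vp.drop_one_delta_r2(default_table, "intensity", blocks=("diet",))


class TestInteractionSelection:
    def test_identical_models_lrt_zero(self):
        # single-phase design: no estimable interaction columns, stat 0, p 1
        cfg = GeneratorConfig(
            n_animals=20,
            availability={"farrowing": ("normal", "pain")},
            traits={"intensity": TraitParams(intercept=70.0,
                                             condition={"pain": 3.0},
                                             sigma2_animal=1.0,
                                             sigma2_resid=1.0)},
            seed=50,
        )
        table = generate_dataset(cfg)
        sel = vp.select_interaction(table, "intensity",
                                    fixed=("sex", "condition"), random=("animal",))
        assert sel.df == 0
        assert sel.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert sel.p_value == 1.0
        assert not sel.kept

    def test_empty_cells_noted(self, default_table):
        sel = vp.select_interaction(default_table, "f2", random=("animal",))
        assert sel.design_warning is not None
        assert "nursery:heat" in sel.design_warning


class TestBH:
    def test_hand_computed_step_up(self):
        q = vp.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p, expected", [
        ([0.2], [0.2]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_edge_cases(self, p, expected):
        assert np.allclose(vp.bh_fdr(p), expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_q_at_least_p_and_monotone(self, pvals):
        q = vp.bh_fdr(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vp.bh_fdr([0.5, 1.5])


class TestResidualICC:
    def test_ordering_agrees_with_model_icc(self):
        # two traits with clearly different animal-identity shares
        cfg = default_config(seed=60)
        hi = TraitParams(intercept=70.0, condition={"pain": 5.0},
                        sigma2_animal=8.0, sigma2_recording=0.0, sigma2_resid=8.0)
        lo = TraitParams(intercept=1900.0, condition={"pain": 300.0},
                        sigma2_animal=500.0, sigma2_recording=0.0,
                        sigma2_resid=50000.0)
        cfg.traits = {"intensity": hi, "f2": lo}
        table = generate_dataset(cfg)
        model_icc = {
            t: vp.icc(vp.fit_lmm(table, t, random=("animal",)).components)
            for t in ("intensity", "f2")}
        resid_icc = {t: vp.residual_icc(table, t) for t in ("intensity", "f2")}
        assert model_icc["intensity"] > model_icc["f2"]
        assert resid_icc["intensity"] > resid_icc["f2"]


class TestErrors:
    def test_constant_factor_rejected(self):
        table = balanced_one_way()
        with pytest.raises(vp.SingularDesignError, match="condition"):
            vp.fit_lmm(table, "intensity", fixed=("condition",), random=("animal",))

    def test_single_animal_rejected(self):
        df = make_rows(n_animals=1)
        with pytest.raises(ValueError, match="2 animals"):
            vp.fit_lmm(FeatureTable(df), "intensity", fixed=(), random=("animal",))
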