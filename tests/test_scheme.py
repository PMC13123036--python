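import warnings

import numpy as np
import pytest

from upcycle import scheme as sc
from upcycle.genome_sim import FEMALE, MALE


class TestStrategyTable:
    def test_standard_rows_elite_dams(self):
        # 3/10/25 donors with four layers leave 388/360/300 elite sows
        for sid, d, elite in [(7, 3, 388), (8, 10, 360), (9, 25, 300)]:
            s = sc.STRATEGIES[sid]
            assert s.n_donors == d
            assert s.upcycling_sows == 4 * d
            assert s.elite_dams == elite

    def test_criteria_assignment(self):
        assert sc.STRATEGIES[1].donors[0].criterion == "beneficial"
        assert sc.STRATEGIES[4].donors[0].criterion == "unique"
        assert sc.STRATEGIES[7].donors[0].criterion == "kinship"

    def test_reduced_schemes(self):
        s10 = sc.STRATEGIES[10]
        assert s10.upcycling_sows == 30 and s10.elite_dams == 370
        assert s10.upcycling_fraction == pytest.approx(0.075)
        s11 = sc.STRATEGIES[11]
        assert s11.upcycling_sows == 20 and s11.elite_dams == 380
        assert s11.upcycling_fraction == pytest.approx(0.05)

    def test_mixed_strategy_12(self):
        s12 = sc.STRATEGIES[12]
        assert s12.n_donors == 17  # 8 kinship + 4 unique + 5 beneficial
        assert s12.upcycling_sows == 39 and s12.elite_dams == 361
        assert s12.upcycling_fraction == pytest.approx(0.0975)
        ben = [d for d in s12.donors if d.criterion == "beneficial"][0]
        assert ben.pool_depth == 5

    def test_control_has_no_layers(self):
        s13 = sc.STRATEGIES[13]
        assert s13.upcycling_sows == 0 and s13.elite_dams == 400 and not s13.donors

    def test_layer_one_sows_equal_donors_everywhere(self):
        for s in sc.STRATEGIES.values():
            if s.layers:
                assert s.layer_by_number(1).n_sows == s.n_donors

    def test_scaling_preserves_identities(self):
        for sid in range(1, 14):
            s = sc.strategy_config(sid, 100)
            assert s.n_dams_total == 100
            assert s.elite_dams + s.upcycling_sows == 100
            if s.layers:
                assert s.layer_by_number(1).n_sows == s.n_donors
        assert sc.strategy_config(8, 100).n_donors == 3  # 10 scaled by 1/4

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ValueError, match="one sow per donor"):
            sc.StrategyConfig(99, "bad", (sc.DonorSpec("kinship", 3),), (sc.LayerSpec(1, (("ebv", 5),)),))


class TestBurnin:
    def test_cohort_sizes_and_archive(self, tiny_config, burned_state):
        st = burned_state
        assert st.generation == 0
        assert len(st.cohort) == tiny_config.n_dams * tiny_config.litter_size
        gens = {a["generation"] for a in st.archive}
        assert gens == set(range(-tiny_config.n_burnin, 0))
        assert (st.cohort["component"] == "elite").all()

    def test_determinism(self, tiny_config):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = sc.run_burnin(tiny_config, seed=7).metrics_frame()
            b = sc.run_burnin(tiny_config, seed=7).metrics_frame()
        assert a.equals(b)

    def test_burnin_selection_gains(self, burned_state):
        df = burned_state.metrics_frame()
        assert df["mean_tbv"].iloc[-1] > df["mean_tbv"].iloc[0]

    def test_scaled_cohort_arithmetic(self):
        cfg = sc.SimConfig(n_dams=60)
        assert cfg.cohort_size == 360


class TestSelection:
    @pytest.fixture()
    def advanced(self, burned_state):
        st = burned_state.clone()
        strat = sc.strategy_config(9, st.config.n_dams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.advance_generation(st, strat)
            sc.advance_generation(st, strat)
        return st, strat

    def test_roles_disjoint_and_resources_conserved(self, advanced):
        st, strat = advanced
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st.selection = {}
            sc.select_cohort(st, "elite_dams", strat)
            sc.select_cohort(st, "elite_sires", strat)
            for role in ("L1_dams", "L4_dams", "L3_dams", "L2_dams"):
                sc.select_cohort(st, role, strat)
        dam_roles = [st.selection[r] for r in ("elite_dams", "L1_dams", "L4_dams", "L3_dams", "L2_dams")]
        flat = [i for role in dam_roles for i in role]
        assert len(flat) == len(set(flat)), "a female was selected for two roles"
        assert len(flat) == strat.n_dams_total
        sexes = st.cohort.set_index("id")["sex"]
        assert (sexes.loc[flat] == FEMALE).all()
        sol = st.selection["elite_sires"]
        sires = sol.candidate_ids[sol.contributions > 1e-12]
        assert (sexes.loc[sires] == MALE).all()

    def test_role_order_enforced(self, advanced):
        st, strat = advanced
        st.selection = {}
        with pytest.raises(ValueError, match="must be selected before"):
            sc.select_cohort(st, "donors", strat)

    def test_components_born_each_generation(self, advanced):
        st, strat = advanced
        counts = st.cohort["component"].value_counts()
        lit = st.config.litter_size
        d = strat.n_donors
        assert counts["layer1"] == d * lit
        assert counts["elite"] == strat.elite_dams * lit
        assert len(st.cohort) == st.config.cohort_size

    def test_donor_pool_is_archived_sires(self, advanced):
        st, strat = advanced
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st.selection = {}
            for role in sc.ROLE_ORDER:
                if role.startswith("L") and strat.layer_by_number(int(role[1])) is None:
                    continue
                sc.select_cohort(st, role, strat)
        donors = st.selection["donors"]
        archive_ids = {a["id"] for a in st.archive}
        assert set(donors) <= archive_ids
        assert len(donors) == strat.n_donors
        # donors lean old: all strictly older than the current generation
        gens = {a["id"]: a["generation"] for a in st.archive}
        assert all(gens[d] < st.generation for d in donors)

    def test_origin_counts_sum_to_selection_totals(self, advanced):
        st, strat = advanced
        row = st.metrics[-2]  # last generation with a selection record
        sire_total = sum(row[f"sires_{c}"] for c in sc.COMPONENTS)
        assert sire_total == row["n_ocs_sires"]
        dam_total = sum(row[f"elite_dams_{c}"] for c in sc.COMPONENTS)
        assert dam_total == strat.elite_dams

    def test_control_reduces_to_plain_ocs(self, burned_state):
        st = burned_state.clone()
        ctrl = sc.strategy_config(13, st.config.n_dams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.advance_generation(st, ctrl)
        assert (st.cohort["component"] == "elite").all()
        assert st.metrics[-2]["n_donors_used"] == 0


class TestAdvance:
    def test_total_births_constant(self, burned_state):
        for sid in (9, 10, 11, 12):
            st = burned_state.clone()
            strat = sc.strategy_config(sid, st.config.n_dams)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sc.advance_generation(st, strat)
            assert len(st.cohort) == st.config.cohort_size, f"strategy {sid}"

    def test_archive_rolls_forward(self, burned_state):
        st = burned_state.clone()
        strat = sc.strategy_config(13, st.config.n_dams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(2):
                sc.advance_generation(st, strat)
        gens = sorted({a["generation"] for a in st.archive})
        assert gens[-1] == st.generation - 1
        assert gens[0] >= st.generation - st.config.archive_depth

    def test_layer_males_can_enter_ocs(self, burned_state):
        """Males born in layers are OCS candidates next generation."""
        st = burned_state.clone()
        strat = sc.strategy_config(9, st.config.n_dams)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.advance_generation(st, strat)
            st.selection = {}
            sc._evaluate(st)
            sc.select_cohort(st, "elite_dams", strat)
            sol = sc.select_cohort(st, "elite_sires", strat)
        cand_comp = st.cohort.set_index("id")["component"].loc[sol.candidate_ids]
        assert set(cand_comp.unique()) > {"elite"}

    def test_run_scenario_zero_generations(self, tiny_config):
        tables = sc.run_scenario(13, 0, 1, master_seed=5, config=tiny_config)
        assert len(tables) == 1
        assert tables[0]["generation"].max() == 0

    def test_run_scenario_deterministic(self, tiny_config):
        a = sc.run_scenario(13, 1, 1, master_seed=6, config=tiny_config)[0]
        b = sc.run_scenario(13, 1, 1, master_seed=6, config=tiny_config)[0]
        assert a.equals(b)

    def test_paired_scenarios_share_burnin(self, tiny_config):
        out = sc.run_paired_scenarios([13, 11], 1, 1, master_seed=8, config=tiny_config)
        a, b = out[13][0], out[11][0]
        pre = a["generation"] <= 0
        assert np.allclose(a.loc[pre, "mean_tbv"], b.loc[pre, "mean_tbv"])
        assert a["generation"].max() == b["generation"].max() == 1


class TestBackcrossArithmetic:
    def test_backcross_halves_donor_genome_share(self, toy_map):
        """Backcrossing to elite halves the donor genome share each layer:
        50% in the F1, ~6.25% in layer-4-born animals (via founder labels)."""
        import pandas as pd

        from upcycle import diversity_metrics as dm
        from upcycle import genome_sim as gs

        L = toy_map.n_loci
        rng = np.random.default_rng(42)
        n = 10  # animal 0: donor male (labels 0,1); 1-4 elite males; 5-9 elite females
        alleles = rng.integers(0, 2, (2, n, L)).astype(np.uint8)
        labels = np.arange(2 * n, dtype=np.int32).reshape(2, n)[:, :, None] * np.ones(L, np.int32)
        panel = gs.HaplotypePanel(alleles, labels, np.arange(n))
        trait = gs.TraitArchitecture(
            np.zeros(0), np.zeros(0, np.uint8), 0.3, 0.0, 1.0, np.zeros(0, dtype=np.intp)
        )
        ped = gs.make_pedigree(
            [
                {"id": i, "sire": -1, "dam": -1, "sex": gs.MALE if i < 5 else gs.FEMALE,
                 "generation": 0, "component": "elite", "tbv": 0.0, "phenotype": 0.0, "gebv": np.nan}
                for i in range(n)
            ]
        )
        donor_labels = np.array([0, n])  # haplotype labels of animal 0
        w = toy_map.locus_weights()

        def donor_share(pnl):
            isin = np.isin(pnl.founder_label, donor_labels)
            return float(np.mean(isin.astype(float) @ w) )

        # F1: donor x 5 elite females
        panel1, recs = gs.breed_offspring(
            panel, ped, [(0, f) for f in range(5, 10)], 12, "layer1", toy_map, trait, rng, 1, 1000
        )
        assert donor_share(panel1) == pytest.approx(0.5, abs=1e-9)  # one haplotype straight from the donor
        shares = []
        prev_panel, prev_recs = panel1, recs
        for layer, sire in enumerate([1, 2, 3, 4], start=2):
            ped = pd.concat([ped, prev_recs], ignore_index=True)
            dams = prev_recs.loc[prev_recs["sex"] == gs.FEMALE, "id"].to_numpy()[:12]
            assert dams.size >= 5
            combined = gs.HaplotypePanel(
                np.concatenate([panel.alleles, prev_panel.alleles], axis=1),
                np.concatenate([panel.founder_label, prev_panel.founder_label], axis=1),
                np.concatenate([panel.ids, prev_panel.ids]),
            )
            prev_panel, prev_recs = gs.breed_offspring(
                combined, ped, [(sire, int(d)) for d in dams], 6, f"layer{min(layer, 4)}",
                toy_map, trait, rng, layer, 1000 * layer + 10_000,
            )
            shares.append(donor_share(prev_panel))
        assert shares[0] == pytest.approx(0.25, abs=0.05)   # layer-2-born
        assert shares[2] == pytest.approx(0.0625, abs=0.03)  # layer-4-born
        assert dm.elite_genome_fraction(4) == pytest.approx(0.9375)
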