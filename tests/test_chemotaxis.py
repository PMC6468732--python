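import numpy as np
import pandas as pd
import pytest

from opncircuit.chemotaxis import (FRAGMENT_OF, ChemotacticIndexSet,
                                   cell_type_comparison,
                                   ci_fragment_from_exposures,
                                   estimate_ci_fragments,
                                   estimate_ci_unprocessed,
                                   estimate_index_set, scenario_grid,
                                   substrate_fragment_exposure,
                                   total_chemotaxis)
from opncircuit.errors import SingularSystemError, UndefinedIndexError
from opncircuit.model import (OPN_OF_SUBSTRATE, SPECIES, RelapseSchedule,
                              Trajectory, equilibrium_state, simulate_circuit)
from opncircuit.synthetic import (TRUE_CI, GeneratorConfig, generate_migration)


def true_ci_map(cell_type="HUVEC"):
    out = {}
    for s, v in TRUE_CI[cell_type]["opn"].items():
        out[OPN_OF_SUBSTRATE[s]] = v
    for pair, v in TRUE_CI[cell_type]["frag"].items():
        out[FRAGMENT_OF[pair]] = v
    return out


class TestUnprocessedIndex:
    def test_null_stimulus_and_closed_form(self):
        assert estimate_ci_unprocessed(100.0, 5.0) == 0.0
        assert estimate_ci_unprocessed(150.0, 10.0) == pytest.approx(
            50.0 / (10.0 * 20.0))

    def test_zero_stimulus_rejected(self):
        with pytest.raises(UndefinedIndexError):
            estimate_ci_unprocessed(120.0, 0.0)


class TestFragmentIndex:
    def test_exponential_worked_example(self):
        """Analytic oracle: OPN(t) = 10 e^{-0.1 (t-2)} on [2, 22] gives
        int OPN = 100 (1 - e^-2) = 86.47, int F = 200 - 86.47 = 113.53;
        with net migration 100 and ci_opn = 0.25 the fragment index is
        (100 - 0.25*86.47)/113.53 = 0.6904."""
        opn_int = 100.0 * (1.0 - np.exp(-2.0))
        frag_int = 10.0 * 20.0 - opn_int
        assert opn_int == pytest.approx(86.4665, abs=5e-5)
        assert frag_int == pytest.approx(113.5335, abs=5e-5)
        ci = ci_fragment_from_exposures(200.0, 0.25, opn_int, frag_int)
        assert ci == pytest.approx(0.6904, abs=5e-5)

    def test_no_cutting_is_singular(self):
        with pytest.raises(SingularSystemError):
            estimate_ci_fragments(150.0, 0.1, 0.0, 100.0, 50.0, 10.0)

    def test_scale_consistency_first_order(self):
        """In the first-order regime exposures scale linearly with the
        stimulus, so doubling opn0 and the net response leaves ci_F fixed."""
        kcut, km, p = 0.5, 5000.0, 100.0
        ci1 = estimate_ci_fragments(140.0, 0.0, kcut, km, p, 5.0)
        ci2 = estimate_ci_fragments(180.0, 0.0, kcut, km, p, 10.0)
        assert ci2 == pytest.approx(ci1, rel=1e-3)

    def test_round_trip_recovery_with_noise(self, gen_config, true_kinetics):
        """Assays forward-generated from known indices: median recovered
        fragment index within 10% at 5-point migration noise."""
        cfg = GeneratorConfig(seed=31)
        mig = generate_migration(cfg)
        idx = estimate_index_set(mig[mig.substrate != "control"], "HUVEC",
                                 [true_kinetics])
        for pair, truth in TRUE_CI["HUVEC"]["frag"].items():
            rec = float(np.median(idx.ci_frag[pair]))
            assert rec == pytest.approx(truth, rel=0.10)


class TestTotalChemotaxis:
    def make_traj(self, states):
        return Trajectory(t=np.arange(len(states), dtype=float),
                          states=np.asarray(states, dtype=float),
                          params=None, schedule=None)

    def test_zero_state_and_single_species(self):
        ci = {name: 0.25 for name in SPECIES}
        tr = self.make_traj(np.zeros((3, 11)))
        assert np.all(total_chemotaxis(tr, ci)["total"] == 0.0)
        states = np.zeros((2, 11))
        states[:, 2] = 10.0  # opn_f only
        out = total_chemotaxis(self.make_traj(states), ci)
        assert np.allclose(out["total"], 2.5)
        assert np.allclose(out["opn_only"], 2.5)
        assert np.allclose(out["frag_immuno"], 0.0)

    def test_linearity_and_exact_decomposition(self):
        rng = np.random.default_rng(3)
        ci = {name: rng.uniform(0.1, 0.6) for name in SPECIES}
        a, b = rng.uniform(0, 1, (4, 11)), rng.uniform(0, 1, (4, 11))
        ca = total_chemotaxis(self.make_traj(a), ci)
        cb = total_chemotaxis(self.make_traj(b), ci)
        cab = total_chemotaxis(self.make_traj(a + b), ci)
        assert np.allclose(cab["total"], ca["total"] + cb["total"])
        recomposed = (cab["opn_only"] + cab["frag_standard"]
                      + cab["frag_immuno"])
        assert np.array_equal(recomposed, cab["total"])


class TestScenarioGrid:
    def test_single_cell_matches_direct_run(self, gen_config, true_kinetics):
        cfg = gen_config
        opn_rel, prot_rel = cfg.relapse_levels()
        ci = true_ci_map()
        sched = RelapseSchedule()
        g = scenario_grid([0.5], [0.5], cfg.opn_rem_nm, cfg.prot_rem_nm,
                          opn_rel, prot_rel, true_kinetics, ci, sched,
                          n_t=200)
        assert len(g) == 1 and bool(g["admissible"].iloc[0])
        from opncircuit.steady_state import derive_params
        params = derive_params(cfg.opn_rem_nm, cfg.prot_rem_nm, opn_rel,
                               prot_rel, true_kinetics, x_i=0.5, x_t=0.5)
        t = np.linspace(0, sched.total_span, 200)
        tr = simulate_circuit(params, equilibrium_state(params), sched, t)
        ct = total_chemotaxis(tr, ci)
        mask = (t >= sched.onset_time) & (t <= sched.end_time)
        peak = np.max(np.where(mask, ct["total"], -np.inf))
        assert g["total_diff"].iloc[0] == pytest.approx(
            peak - ct["total"][0], rel=1e-9)

    def test_fragment_difference_monotone_in_immuno_fraction(
            self, gen_config, true_kinetics):
        """More immunoproteasome -> larger relapse-remission fragment
        chemotaxis difference (immuno kcut >= standard kcut)."""
        opn_rel, prot_rel = gen_config.relapse_levels()
        grid = np.linspace(0.1, 0.9, 5)
        g = scenario_grid(grid, grid, gen_config.opn_rem_nm,
                          gen_config.prot_rem_nm, opn_rel, prot_rel,
                          true_kinetics, true_ci_map(), n_t=250)
        assert g["admissible"].all()
        piv = g.pivot(index="x_t", columns="x_i", values="frag_diff")
        assert (piv.diff(axis=1).iloc[:, 1:] >= -1e-12).all().all()

    def test_pure_fl_column_matches_fl_only_model(self, gen_config,
                                                  true_kinetics):
        """x_t = 1 removes the thrombin-cleaved species entirely."""
        opn_rel, prot_rel = gen_config.relapse_levels()
        ci = true_ci_map()
        g = scenario_grid([0.5], [1.0], gen_config.opn_rem_nm,
                          gen_config.prot_rem_nm, opn_rel, prot_rel,
                          true_kinetics, ci, n_t=200)
        assert bool(g["admissible"].iloc[0])
        from opncircuit.steady_state import derive_params
        params = derive_params(gen_config.opn_rem_nm, gen_config.prot_rem_nm,
                               opn_rel, prot_rel, true_kinetics,
                               x_i=0.5, x_t=1.0)
        eq = equilibrium_state(params)
        assert eq.opn_n == pytest.approx(0.0, abs=1e-12)
        assert eq.opn_c == pytest.approx(0.0, abs=1e-12)


class TestCellTypes:
    def test_identical_tables_identical_indices(self, gen_config,
                                                true_kinetics):
        mig = generate_migration(GeneratorConfig(seed=8))
        assays = mig[(mig.cell_type == "HUVEC") & (mig.substrate != "control")]
        clone = assays.assign(cell_type="clone")
        both = pd.concat([assays, clone], ignore_index=True)
        out = cell_type_comparison(both, [true_kinetics])
        a = out["HUVEC"]["indices"]
        b = out["clone"]["indices"]
        assert a.ci_opn == b.ci_opn
        for pair in a.ci_frag:
            assert np.array_equal(a.ci_frag[pair], b.ci_frag[pair])

    def test_monocyte_opnfl_ordering(self, true_kinetics):
        """Monocytes respond more to intact OPN-FL, so their OPN-FL index
        and no-thrombin chemotaxis exceed the HUVEC ones."""
        mig = generate_migration(GeneratorConfig(seed=8))
        out = cell_type_comparison(mig[mig.substrate != "control"],
                                   [true_kinetics])
        hv = out["HUVEC"]["indices"].ci_opn["FL"]
        mo = out["monocyte"]["indices"].ci_opn["FL"]
        assert mo > hv

    def test_missing_immuno_assays_leave_indices_absent(self, true_kinetics):
        mig = generate_migration(GeneratorConfig(seed=8))
        out = cell_type_comparison(mig[mig.substrate != "control"],
                                   [true_kinetics])
        lym = out["lymphocyte"]["indices"]
        assert lym.ci_frag[("FL", "immuno")] is None
        assert lym.ci_frag[("FL", "standard")] is not None

    def test_empty_table_rejected(self, true_kinetics):
        with pytest.raises(ValueError):
            cell_type_comparison(pd.DataFrame(), [true_kinetics])
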