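import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ufscreen.chrom_model import read_chromatogram, read_design
from ufscreen.peakproc import read_panel
from ufscreen.pipeline import process_screen
from ufscreen.simulate import (
    BindingSystem,
    Enzyme,
    Ligand,
    Probe,
    closed_form_pair,
    danshen4_fixture,
    generate_screen_dataset,
    make_grid,
    simulate_retentate,
    solve_equilibrium,
    synthesize_chromatogram,
)

from .conftest import demo_design, demo_grid, demo_panel, demo_system

GOLDEN = (3.0 - math.sqrt(5.0)) / 2.0  # bound conc for E=L=Kd=1


def pair_system(E, L, K, nu=0.1):
    return BindingSystem(
        enzymes=(Enzyme("E", E),),
        ligands=(Ligand("L", L, 1.0, nu, 10.0),),
        kd={("L", "E"): K},
        site={},
        probes={"E": Probe("p", 100.0, 0.1)},
    )


class TestClosedForm:
    def test_symmetric_unit_system(self):
        assert closed_form_pair(1, 1, 1) == pytest.approx(GOLDEN, abs=1e-12)

    @pytest.mark.parametrize("E,L", [(0.0, 5.0), (5.0, 0.0)])
    def test_vanishing_species(self, E, L):
        assert closed_form_pair(E, L, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            closed_form_pair(1.0, 1.0, 0.0)


class TestEquilibriumSolver:
    def test_blank_condition_leaves_everything_free(self):
        st_ = solve_equilibrium(pair_system(1, 1, 1), "blank")
        assert st_.free_ligand["L"] == pytest.approx(1.0)
        assert all(v == pytest.approx(0.0) for v in st_.bound.values())

    def test_unit_pair_matches_quadratic(self):
        st_ = solve_equilibrium(pair_system(1, 1, 1), "experimental")
        assert st_.bound[("L", "E")] == pytest.approx(GOLDEN, abs=1e-9)

    def test_vanishing_affinity_limit(self):
        st_ = solve_equilibrium(pair_system(5, 5, 1e9), "experimental")
        assert st_.bound[("L", "E")] < 1e-6 * 5.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        E=st.floats(1e-3, 1e3),
        L=st.floats(1e-3, 1e3),
        K=st.floats(1e-3, 1e3),
    )
    def test_solver_matches_closed_form(self, E, L, K):
        st_ = solve_equilibrium(pair_system(E, L, K), "experimental")
        assert abs(st_.bound[("L", "E")] - closed_form_pair(E, L, K)) < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), condition=st.sampled_from(
        ["experimental", ("control", "E1"), ("control", "E2")]))
    def test_mass_conservation_random_systems(self, seed, condition):
        rng = np.random.default_rng(seed)
        enzymes = tuple(Enzyme(f"E{j}", rng.uniform(0.1, 10)) for j in range(1, 3))
        ligands = tuple(
            Ligand(f"L{i}", rng.uniform(0.1, 20), 1.0, rng.uniform(0.01, 0.5), 5.0 * i)
            for i in range(1, 5)
        )
        kd, site = {}, {}
        for lig in ligands:
            for enz in enzymes:
                if rng.random() < 0.6:
                    kd[(lig.ligand_id, enz.enzyme_id)] = rng.uniform(0.01, 100)
                    site[(lig.ligand_id, enz.enzyme_id)] = (
                        "orthosteric" if rng.random() < 0.7 else "allosteric"
                    )
        probes = {e.enzyme_id: Probe(f"p_{e.enzyme_id}", rng.uniform(10, 500), rng.uniform(0.01, 1)) for e in enzymes}
        system = BindingSystem(enzymes, ligands, kd, site, probes)
        state = solve_equilibrium(system, condition)
        for lig in ligands:
            bound = sum(v for (l, _), v in state.bound.items() if l == lig.ligand_id)
            total = state.free_ligand[lig.ligand_id] + bound
            assert total == pytest.approx(lig.total_conc, rel=1e-9)

    def test_orthosteric_displacement_monotone_in_probe(self):
        base = demo_system()
        prev = None
        for conc in (0.0, 1.0, 10.0, 100.0, 1000.0):
            system = BindingSystem(
                base.enzymes, base.ligands, base.kd, base.site,
                {"E1": Probe("p1", conc, 0.1), "E2": Probe("p2", conc, 0.1)},
            )
            areas_a = {l: a for l, (_, a) in simulate_retentate(system, "experimental").items()}
            areas_b = {l: a for l, (_, a) in simulate_retentate(system, "blank").items()}
            areas_c = {l: a for l, (_, a) in simulate_retentate(system, ("control", "E1")).items()}
            ssn = (areas_a["orth"] - areas_c["orth"]) / areas_b["orth"]
            if prev is not None:
                assert ssn >= prev - 1e-12
            prev = ssn
            # the allosteric ligand never responds to the orthosteric probe
            assert areas_c["allo"] == pytest.approx(areas_a["allo"], rel=1e-9)

    def test_saturating_probe_restores_blank_area(self):
        # probe -> infinity displaces an orthosteric-only ligand entirely
        system = BindingSystem(
            (Enzyme("E", 1.0),),
            (Ligand("L", 2.0, 1.0, 0.1, 10.0),),
            {("L", "E"): 1.0},
            {},
            {"E": Probe("p", 1e7, 0.1)},
        )
        a_c = simulate_retentate(system, ("control", "E"))["L"][1]
        a_b = simulate_retentate(system, "blank")["L"][1]
        assert a_c == pytest.approx(a_b, rel=1e-4)


class TestRetentate:
    def test_blank_area_is_nonspecific_fraction(self):
        system = pair_system(0.0, 10.0, 1.0, nu=0.1)
        retained, area = simulate_retentate(system, "blank")["L"]
        assert area == pytest.approx(1.0)

    def test_non_binder_model_sn_is_one(self):
        system = BindingSystem(
            (Enzyme("E", 1.0),), (Ligand("L", 10.0, 1.0, 0.1, 10.0),), {}, {}, {},
        )
        a_a = simulate_retentate(system, "experimental")["L"][1]
        a_b = simulate_retentate(system, "blank")["L"][1]
        assert a_a / a_b == pytest.approx(1.0, abs=1e-12)


class TestSynthesize:
    def test_apex_height_from_area(self):
        grid = make_grid(20.0)
        c = synthesize_chromatogram({"x": 2.5066}, {"x": 10.0}, sigma=0.1, grid=grid)
        assert c.signal.max() == pytest.approx(10.0, rel=1e-3)

    def test_zero_everything_gives_zero_trace(self):
        grid = make_grid(20.0)
        c = synthesize_chromatogram({}, {}, sigma=0.1, grid=grid)
        assert np.all(c.signal == 0.0)

    def test_deterministic_given_seed(self):
        grid = make_grid(20.0)
        kw = dict(areas={"x": 1.0}, rts={"x": 10.0}, sigma=0.1,
                  noise_sd=0.1, drift=1.0, grid=grid)
        a = synthesize_chromatogram(seed=7, **kw)
        b = synthesize_chromatogram(seed=7, **kw)
        assert np.array_equal(a.signal, b.signal)

    def test_rt_outside_grid_rejected(self):
        grid = make_grid(20.0)
        with pytest.raises(ValueError):
            synthesize_chromatogram({"x": 1.0}, {"x": 25.0}, sigma=0.1, grid=grid)

    def test_sigma_below_grid_resolution_rejected(self):
        grid = make_grid(20.0)
        with pytest.raises(ValueError):
            synthesize_chromatogram({"x": 1.0}, {"x": 10.0}, sigma=0.02, grid=grid)


class TestGenerateScreenDataset:
    def test_pipeline_recovers_construction_labels(self):
        system = demo_system()
        chroms, truth = generate_screen_dataset(
            system, demo_design(), noise_sd=0.05, drift=1.0, seed=3, grid=demo_grid()
        )
        result = process_screen(chroms, demo_panel(), demo_design())
        for _, row in truth.iterrows():
            call = result.call_of(row.compound_id, row.target)
            assert call.is_specific == row.true_specific

    def test_seed_changes_noise_not_truth(self):
        system = demo_system()
        _, t1 = generate_screen_dataset(system, demo_design(), seed=1, grid=demo_grid())
        _, t2 = generate_screen_dataset(system, demo_design(), seed=2, grid=demo_grid())
        assert np.allclose(t1.model_sn, t2.model_sn)
        assert np.allclose(t1.model_ssn, t2.model_ssn)

    def test_zero_enzyme_screen_scores_unity_everywhere(self):
        system = demo_system(e1_total=0.0, e2_total=0.0)
        chroms, _ = generate_screen_dataset(
            system, demo_design(), noise_sd=0.05, drift=1.0, seed=5, grid=demo_grid()
        )
        result = process_screen(chroms, demo_panel(), demo_design())
        for score in result.scores:
            assert score.sn == pytest.approx(1.0, abs=0.02)
        assert not any(c.is_specific for c in result.calls)


class TestDanshenFixture:
    def test_files_round_trip_through_readers(self, tmp_path):
        design = danshen4_fixture(tmp_path, seed=1)
        back = read_design(tmp_path / "design.yaml")
        assert back.targets == design.targets
        panel = read_panel(tmp_path / "panel.csv")
        assert len(panel.compounds) == 4
        c = read_chromatogram(tmp_path / "blank.csv", "blank", "blank")
        assert c.time.size == 10_500
        assert c.time[-1] == pytest.approx(104.99)

    def test_regeneration_is_byte_identical(self, tmp_path):
        danshen4_fixture(tmp_path / "a", seed=1)
        danshen4_fixture(tmp_path / "b", seed=1)
        for name in ("blank.csv", "experimental.csv", "design.yaml", "ground_truth.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
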