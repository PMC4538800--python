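import numpy as np
import pandas as pd
import pytest

from srnaspike import align, design, simulate, workflows
from srnaspike.exceptions import ParameterError, SimulationError
from srnaspike.simulate import (
    SimScenario,
    SizeSelectionCurve,
    SpikeMix,
    dilution_series_scenario,
    global_shift_scenario,
    make_background,
    simulate_library,
)


class TestSizeSelectionCurve:
    def test_band_pass_shape(self):
        curve = SizeSelectionCurve()
        eff = {L: curve.efficiency(L) for L in (10, 16, 22, 25, 50, 70)}
        assert eff[22] > 0.9 and eff[25] > 0.9
        assert eff[10] < 0.2 and eff[70] < 0.1
        assert eff[50] < eff[25]
        assert all(0 <= e <= 1 for e in eff.values())

    def test_shift_moves_window(self):
        curve = SizeSelectionCurve()
        up = curve.shifted(4)
        assert up.efficiency(60) > curve.efficiency(60)
        assert up.efficiency(12) < curve.efficiency(12)

    def test_flat_curve(self):
        flat = SizeSelectionCurve.flat()
        assert flat.efficiency(10) == pytest.approx(1.0)
        assert flat.efficiency(70) == pytest.approx(1.0)


class TestMakeBackground:
    def test_top10_share_in_window(self):
        bg = make_background(n_species=300, seed=5)
        ab = np.sort([s.abundance for s in bg])
        share = ab[-10:].sum() / ab.sum()
        assert 0.3 <= share <= 0.7

    def test_sigma_zero_equal_abundances(self):
        bg = make_background(n_species=50, sigma=0.0, seed=1,
                             top10_share_range=None)
        ab = np.array([s.abundance for s in bg])
        share = np.sort(ab)[-10:].sum() / ab.sum()
        assert share == pytest.approx(10 / 50)

    def test_deterministic(self):
        a = make_background(n_species=40, seed=9, top10_share_range=None)
        b = make_background(n_species=40, seed=9, top10_share_range=None)
        assert a == b

    def test_class_length_modes(self):
        bg = make_background(n_species=200, seed=2)
        mi = [len(s.seq) for s in bg if s.cls == simulate.CLASS_MIRNA]
        pi = [len(s.seq) for s in bg if s.cls == simulate.CLASS_PIRNA]
        assert 21 <= np.mean(mi) <= 23
        assert 27 <= np.mean(pi) <= 29

    def test_bad_class_mix(self):
        with pytest.raises(ParameterError):
            make_background(class_mix={"nonsense": 1.0})
        with pytest.raises(ParameterError):
            make_background(n_species=5)


class TestSimulateLibrary:
    def test_single_spike_error_free(self, erdn_set):
        mix = SpikeMix(
            design.SpikeInSet((erdn_set.oligos[0],)),
            design.MixSpec({erdn_set.oligos[0].id: 1.0}), 0.1)
        scen = SimScenario(background=(), mixes=(mix,),
                           selection=SizeSelectionCurve.flat(),
                           depth=200, error_rate=0.0, seed=3)
        lib = simulate_library(scen)
        assert len(lib.reads) == 200
        assert all(r.seq == erdn_set.oligos[0].seq for r in lib.reads)

    def test_depth_conservation_and_truth(self, erdn_set):
        bg = make_background(n_species=50, seed=4, top10_share_range=None)
        mix = SpikeMix(erdn_set, design.ladder_mix(erdn_set), 0.03)
        scen = SimScenario(background=bg, mixes=(mix,),
                           selection=SizeSelectionCurve(), depth=5000,
                           seed=8)
        lib = simulate_library(scen)
        assert len(lib.reads) == 5000
        assert lib.truth["realized"].sum() == 5000
        assert lib.truth["expected"].sum() == pytest.approx(5000)

    def test_ladder_ratio_near_two(self, erdn_set):
        """Consecutive ERDN expected counts differ ~2-fold under a flat
        selection curve; realized counts stay in the multinomial envelope."""
        mix = SpikeMix(erdn_set, design.ladder_mix(erdn_set), 0.1)
        scen = SimScenario(background=(), mixes=(mix,),
                           selection=SizeSelectionCurve.flat(),
                           depth=1_000_000, error_rate=0.0, seed=5)
        lib = simulate_library(scen)
        expected = lib.truth["expected"]
        ratios = expected.values[1:] / expected.values[:-1]
        np.testing.assert_allclose(ratios, 2.0)
        top = lib.truth.loc["DN-19"]
        sd = np.sqrt(top["expected"])
        assert abs(top["realized"] - top["expected"]) < 5 * sd

    def test_empty_pool_raises(self):
        with pytest.raises(SimulationError):
            simulate_library(SimScenario(background=(), mixes=(),
                                         selection=SizeSelectionCurve(),
                                         depth=10))

    def test_truth_matches_counting_error_free(self, erdn_set, srqc_set):
        """Error-free reads recount exactly to the truth table for spike-ins
        within the 40-nt cropping rule's reach."""
        mixes = (SpikeMix(erdn_set, design.ladder_mix(erdn_set), 0.05),
                 SpikeMix(srqc_set,
                          design.MixSpec.from_weights(
                              {o.id: 1.0 for o in srqc_set}), 0.05))
        scen = SimScenario(background=(), mixes=mixes,
                           selection=SizeSelectionCurve.flat(), depth=20000,
                           error_rate=0.0, seed=11)
        lib = simulate_library(scen)
        from srnaspike.reads import crop_reads
        counts, unassigned = align.count_reads(
            crop_reads(lib.reads, 40), list(erdn_set) + list(srqc_set),
            workflows.SPIKE_RULE)
        for oid, row in lib.truth.iterrows():
            assert counts[oid] == row["realized"], oid
        assert unassigned == 0


class TestDilutionScenario:
    def test_inputs_span_2_to_7(self, erdn_set, srqc_set):
        bg = make_background(n_species=30, seed=0, top10_share_range=None)
        scens, log2_input = dilution_series_scenario(srqc_set, erdn_set, bg,
                                                     seed=1)
        assert len(scens) == 8
        fc_fracs = [s.mixes[1].fraction for s in scens]
        assert fc_fracs[0] / fc_fracs[-1] == pytest.approx(2 ** 7)
        np.testing.assert_allclose(np.diff(log2_input.values), -1.0)

    def test_background_and_erdn_constant(self, erdn_set, srqc_set):
        bg = make_background(n_species=30, seed=0, top10_share_range=None)
        scens, _ = dilution_series_scenario(srqc_set, erdn_set, bg, seed=1)
        assert all(s.background is bg for s in scens)
        erdn_fracs = {s.mixes[0].fraction for s in scens}
        assert len(erdn_fracs) == 1

    def test_step_one_is_negative_control(self, erdn_set, srqc_set):
        bg = make_background(n_species=30, seed=0, top10_share_range=None)
        scens, log2_input = dilution_series_scenario(
            srqc_set, erdn_set, bg, fold_step=1.0, seed=1)
        assert len({s.mixes[1].fraction for s in scens}) == 1
        np.testing.assert_allclose(log2_input.values, 0.0)


@pytest.fixture(scope="module")
def design_obj(erdn_set):
    bg = make_background(n_species=120, seed=3)
    mix = SpikeMix(erdn_set, design.ladder_mix(erdn_set), 0.03)
    return global_shift_scenario(0.10, 0.29, n_per_group=2,
                                 background=bg, mixes=(mix,),
                                 depth=60_000, seed=7)


class TestGlobalShiftScenario:
    def test_realized_mirna_fractions_near_targets(self, design_obj):
        for names, target in ((design_obj.group_a, 0.10),
                              (design_obj.group_b, 0.29)):
            for name in names:
                lib = simulate_library(design_obj.scenarios[name])
                mi = lib.truth.loc[lib.truth["kind"] == simulate.CLASS_MIRNA,
                                   "realized"].sum()
                frac = mi / len(lib.reads)
                assert abs(frac - target) < 0.03

    def test_equal_fractions_imply_zero_shift(self, erdn_set):
        bg = make_background(n_species=120, seed=3)
        mix = SpikeMix(erdn_set, design.ladder_mix(erdn_set), 0.03)
        d = global_shift_scenario(0.2, 0.2, n_per_group=1, background=bg,
                                  mixes=(mix,), seed=1)
        assert d.true_log2_mirna_shift == pytest.approx(0.0)

    def test_pirna_per_ug_equal_between_groups(self, design_obj):
        a = design_obj.scenarios[design_obj.group_a[0]]
        b = design_obj.scenarios[design_obj.group_b[0]]
        pi_a = {s.id: s.abundance for s in a.background
                if s.cls == simulate.CLASS_PIRNA}
        pi_b = {s.id: s.abundance for s in b.background
                if s.cls == simulate.CLASS_PIRNA}
        assert pi_a == pi_b


def test_shift_increases_long_spike_fold_abundance(srqc_set):
    """+4-nt midpoint shift raises fold abundance with spike-in length."""
    sel = SizeSelectionCurve()
    balanced = design.efficiency_balanced_mix(
        srqc_set, {o.id: float(sel.efficiency(o.length)) for o in srqc_set})
    mix = SpikeMix(srqc_set, balanced, 0.1)
    libs = {}
    for name, s in (("ref", sel), ("up", sel.shifted(4))):
        scen = SimScenario(background=(), mixes=(mix,), selection=s,
                           depth=100_000, error_rate=0.0, seed=13,
                           label=name)
        libs[name] = simulate_library(scen)
    counts = pd.DataFrame({n: lib.truth["realized"] for n, lib in
                           libs.items()})
    from srnaspike import qc
    fa = qc.fold_abundance(counts, "ref")["up"]
    lengths = [srqc_set.by_id(i).length for i in fa.index]
    from scipy import stats
    rho, _ = stats.spearmanr(lengths, np.log2(fa.values))
    assert rho > 0.8
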