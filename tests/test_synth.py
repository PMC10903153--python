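"""Generator tests: kinetic curves, community tables, gradient profiles."""

import io as _io
import math

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from sipaug.containers import DegradationSeries
from sipaug.design import (
    CommunityConfig,
    ExperimentDesign,
    Inoculant,
    KineticsParams,
    LabelConfig,
    Responder,
)
from sipaug.synth import (
    expected_gradient_profile,
    fraction_midpoints,
    latent_abundances,
    random_coalescent_tree,
    simulate_community,
    simulate_degradation,
    simulate_gradient,
    unlabeled_buoyant_density,
)


# ----------------------------------------------------------------------
# design validation
# ----------------------------------------------------------------------

class TestDesignValidation:
    def test_non_contiguous_phases_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ExperimentDesign(phase_bounds={"I": (0, 8), "II": (9, 10)})

    def test_dosing_day_must_open_a_phase(self):
        with pytest.raises(ValueError, match="phase start"):
            ExperimentDesign(dosing_days=(0.0, 5.0))

    def test_measurement_outside_incubation_rejected(self):
        with pytest.raises(ValueError, match="outside the incubation"):
            ExperimentDesign(measurement_days=(0.0, 12.0))

    @pytest.mark.parametrize(
        "kwargs", [{"dose_mg_per_l": 0.0}, {"replicates": 0}]
    )
    def test_scalar_invariants(self, kwargs):
        with pytest.raises(ValueError):
            ExperimentDesign(**kwargs)


# ----------------------------------------------------------------------
# degradation
# ----------------------------------------------------------------------

class TestDegradation:
    def test_zero_rates_hold_concentration_between_doses(self):
        design = ExperimentDesign()
        params = KineticsParams(k_abiotic=0.0, k_bio={}, noise_cv=0.0)
        series = simulate_degradation(design, params)
        # each phase is flat; each dose adds 10 mg/L on top of the residual
        for phase, level in (("I", 10.0), ("II", 20.0), ("III", 30.0)):
            vals = series.phase_slice("non-Inoc", phase)["smx_mg_per_l"]
            assert np.allclose(vals, level)

    def test_abiotic_rate_keeps_sterilized_below_3p5_percent(self, single_phase_design):
        params = KineticsParams(k_abiotic=0.004, k_bio={}, noise_cv=0.0)
        series = simulate_degradation(single_phase_design, params)
        traj = series.trajectory("sterilized", 1)
        c0 = traj[traj.day == 0].smx_mg_per_l.iloc[0]
        c8 = traj[traj.day == 8].smx_mg_per_l.iloc[0]
        removal = 100 * (c0 - c8) / c0
        assert removal == pytest.approx(100 * (1 - math.exp(-0.032)), rel=1e-9)
        assert removal < 3.5

    def test_single_phase_exponential_closed_form(self, single_phase_design):
        # C(4)/C(0) = exp(-k t) for total rate 0.5/day, no lag, noiseless
        params = KineticsParams(k_abiotic=0.0, k_bio={"non-Inoc": 0.5}, noise_cv=0.0)
        series = simulate_degradation(single_phase_design, params)
        traj = series.trajectory("non-Inoc", 2)
        ratio = (
            traj[traj.day == 4].smx_mg_per_l.iloc[0]
            / traj[traj.day == 0].smx_mg_per_l.iloc[0]
        )
        assert ratio == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_noiseless_positive_rates_strictly_decrease_within_phase(self):
        design = ExperimentDesign()
        params = KineticsParams(noise_cv=0.0)
        series = simulate_degradation(design, params)
        for treatment in series.treatments:
            for phase in design.phase_bounds:
                vals = (
                    series.phase_slice(treatment, phase)
                    .query("replicate == 1")
                    .sort_values("day")["smx_mg_per_l"]
                    .to_numpy()
                )
                assert np.all(np.diff(vals) < 0)

    def test_lag_delays_biotic_decay_only(self, single_phase_design):
        params = KineticsParams(
            k_abiotic=0.0, k_bio={"non-Inoc": 1.0}, lag_days={"non-Inoc": 2.0},
            noise_cv=0.0,
        )
        series = simulate_degradation(single_phase_design, params)
        traj = series.trajectory("non-Inoc", 1).set_index("day")["smx_mg_per_l"]
        assert traj[2.0] == pytest.approx(10.0)
        assert traj[3.0] == pytest.approx(10.0 * math.exp(-1.0), rel=1e-12)

    def test_fixed_seed_reproduces_bitwise(self):
        design = ExperimentDesign()
        params = KineticsParams()
        a = simulate_degradation(design, params, seed=42).data
        b = simulate_degradation(design, params, seed=42).data
        pd.testing.assert_frame_equal(a, b)


# ----------------------------------------------------------------------
# community
# ----------------------------------------------------------------------

def _quiet_config(**kwargs) -> CommunityConfig:
    defaults = dict(n_asvs=50, sample_jitter_sd=0.0, n_guilds=0)
    defaults.update(kwargs)
    return CommunityConfig(**defaults)


class TestCommunity:
    @pytest.fixture
    def degradation(self):
        design = ExperimentDesign()
        return design, simulate_degradation(design, KineticsParams(noise_cv=0.0))

    def test_no_effect_null_gives_identical_latents_across_treatments(self, degradation):
        design, series = degradation
        config = _quiet_config()
        base = np.random.default_rng(0).lognormal(0, 1.5, config.n_asvs)
        p_a = latent_abundances(design, config, series, "non-SMX", 1, 5.0, base)
        p_b = latent_abundances(design, config, series, "Paen.Inoc", 1, 5.0, base)
        np.testing.assert_allclose(p_a, p_b)
        assert p_a.sum() == pytest.approx(1.0)

    def test_inoculant_latent_matches_closed_form_and_declines(self, degradation):
        design, series = degradation
        inoc = Inoculant("ASV02", initial_fraction=0.2, decay_per_day=0.3)
        config = _quiet_config(inoculants={"Paen.Inoc": inoc})
        base = np.random.default_rng(0).lognormal(0, 1.5, config.n_asvs)
        shares = []
        for day in design.sampling_days:
            p = latent_abundances(design, config, series, "Paen.Inoc", 1, day, base)
            # independent arithmetic for the expected share
            t_dep = 0.0
            traj = series.trajectory("Paen.Inoc", 1)
            t, c = traj["day"].to_numpy(), traj["smx_mg_per_l"].to_numpy()
            for (t0, c0), (t1, c1) in zip(zip(t, c), zip(t[1:], c[1:])):
                if t0 >= day:
                    break
                if c0 < config.loq_mg_per_l and c1 < config.loq_mg_per_l:
                    t_dep += min(t1, day) - t0
            expected = 0.2 * math.exp(-0.3 * t_dep)
            assert p[1] == pytest.approx(expected, rel=1e-9)
            shares.append(p[1])
        assert shares[0] == pytest.approx(0.2)
        # SMX is gone almost immediately in this treatment: monotone decline
        assert all(b < a + 1e-12 for a, b in zip(shares, shares[1:]))

    def test_responder_scales_with_degraded_fraction(self, degradation):
        design, series = degradation
        config = _quiet_config(responders=(Responder("ASV01", "non-Inoc", 2.0),))
        base = np.ones(config.n_asvs)
        p0 = latent_abundances(design, config, series, "non-Inoc", 1, 0.0, base)
        p8 = latent_abundances(design, config, series, "non-Inoc", 1, 8.0, base)
        f8 = series.degraded_fraction("non-Inoc", 1, 8.0)
        assert f8 > 0
        # odds ratio of the responder against any non-responder = exp(effect * f)
        odds0 = p0[0] / p0[5]
        odds8 = p8[0] / p8[5]
        assert odds8 / odds0 == pytest.approx(math.exp(2.0 * f8), rel=1e-9)

    def test_unknown_responder_and_low_depth_rejected(self, degradation):
        design, series = degradation
        with pytest.raises(ValueError, match="unknown ASV"):
            simulate_community(
                design, _quiet_config(responders=(Responder("nope", "non-Inoc", 1.0),)),
                series,
            )
        with pytest.raises(ValueError, match="depth"):
            _quiet_config(depth=999)

    def test_counts_sum_to_depth_and_seed_reproduces(self, degradation):
        design, series = degradation
        config = CommunityConfig(n_asvs=40, depth=10_000)
        t1 = simulate_community(design, config, series, seed=9)
        t2 = simulate_community(design, config, series, seed=9)
        assert (t1.counts.sum(axis=0) == 10_000).all()
        pd.testing.assert_frame_equal(t1.counts, t2.counts)
        assert len(t1.sample_ids) == len(design.community_treatments) * len(
            design.sampling_days
        ) * design.replicates


# ----------------------------------------------------------------------
# gradients
# ----------------------------------------------------------------------

class TestGradient:
    @pytest.fixture
    def community(self, rng):
        asvs = [f"ASV{i:02d}" for i in range(1, 21)]
        counts = pd.Series(rng.integers(50, 500, len(asvs)), index=asvs)
        gc = pd.Series(rng.uniform(0.35, 0.7, len(asvs)), index=asvs)
        return counts, gc

    def test_no_label_null_expected_profiles_identical(self, community):
        counts, gc = community
        config = LabelConfig(atom_fraction_excess={a: 0.0 for a in counts.index})
        lab = expected_gradient_profile(counts, gc, config, labeled=True)
        ctl = expected_gradient_profile(counts, gc, config, labeled=False)
        pd.testing.assert_frame_equal(lab, ctl)

    def test_center_of_mass_tracks_gc_and_full_labeling(self):
        counts = pd.Series({"A": 1000})
        gc = pd.Series({"A": 0.5})
        assert unlabeled_buoyant_density(0.5) == pytest.approx(1.709)
        config = LabelConfig(atom_fraction_excess={"A": 1.0})
        spacing = np.abs(np.diff(fraction_midpoints(config))).mean()
        for labeled, center in ((False, 1.709), (True, 1.745)):
            prof = expected_gradient_profile(counts, gc, config, labeled=labeled)
            mids = fraction_midpoints(config)
            cm = float((prof.iloc[0].to_numpy() * mids).sum())
            assert abs(cm - center) < spacing

    def test_copies_conserved_and_seed_reproducible(self, community):
        counts, gc = community
        config = LabelConfig(atom_fraction_excess={counts.index[0]: 0.8})
        lab1, ctl1 = simulate_gradient(counts, gc, config, qpcr_total=3.3e7, seed=5)
        lab2, _ = simulate_gradient(counts, gc, config, qpcr_total=3.3e7, seed=5)
        assert lab1.fractions["total_16s_copies"].sum() == pytest.approx(3.3e7, abs=1e-6)
        assert ctl1.fractions["total_16s_copies"].sum() == pytest.approx(3.3e7, abs=1e-6)
        pd.testing.assert_frame_equal(lab1.counts, lab2.counts)
        assert (lab1.counts.sum(axis=0) == config.fraction_depth).all()

    def test_expected_label_shift_equals_afe_times_max_shift(self, community):
        counts, gc = community
        # pick a taxon whose fully labelled peak stays inside the gradient,
        # away from the censoring edge fractions
        asv = gc.index[(gc > 0.45) & (gc < 0.55)][0]
        for afe in (0.4, 1.0):
            config = LabelConfig(atom_fraction_excess={asv: afe})
            mids = fraction_midpoints(config)
            lab = expected_gradient_profile(counts, gc, config, labeled=True)
            ctl = expected_gradient_profile(counts, gc, config, labeled=False)
            cm_l = float((lab.loc[asv] * mids).sum() / lab.loc[asv].sum())
            cm_c = float((ctl.loc[asv] * mids).sum() / ctl.loc[asv].sum())
            assert cm_l - cm_c == pytest.approx(afe * config.max_density_shift, abs=5e-4)

    def test_out_of_range_density_warns_and_accumulates_at_edge(self):
        counts = pd.Series({"A": 100})
        gc = pd.Series({"A": 0.95})  # BD0 = 1.753; fully labelled exceeds the range
        config = LabelConfig(atom_fraction_excess={"A": 1.0})
        with pytest.warns(UserWarning, match="outside the gradient"):
            prof = expected_gradient_profile(counts, gc, config, labeled=True)
        assert prof.to_numpy().sum() == pytest.approx(1.0)   # nothing lost
        assert prof.iloc[0, 0] > 0.99                        # piled in the heaviest bin

    def test_empty_sample_rejected(self, community):
        counts, gc = community
        with pytest.raises(ValueError, match="empty"):
            simulate_gradient(counts * 0, gc, LabelConfig(), seed=1)


# ----------------------------------------------------------------------
# tree generator
# ----------------------------------------------------------------------

def test_random_coalescent_tree_is_valid_newick():
    ids = [f"ASV{i}" for i in range(1, 13)]
    nwk = random_coalescent_tree(ids, seed=3)
    tree = TreeNode.read(_io.StringIO(nwk))
    assert sorted(t.name for t in tree.tips()) == sorted(ids)
    assert all((n.length or 0) >= 0 for n in tree.traverse() if n.parent is not None)
    assert nwk == random_coalescent_tree(ids, seed=3)
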