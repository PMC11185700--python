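"""CEST simulation, dip picking and global exchange-model fitting."""

import math

import numpy as np
import pytest

import foldswitch_nmr as fn
from foldswitch_nmr.cest import reduced_chi2


OFFSETS = np.arange(104.0, 135.0, 25.0 / 81.08)


def single_state_profile(r1=1.5, trelax=0.5, b1=10.0, shift=119.0):
    model = fn.ExchangeModel(("A",), {})
    spin = fn.SpinParams("x", {"A": shift}, r1=r1, r2=10.0, larmor_mhz=81.08)
    return fn.simulate_cest_profile(model, spin, b1, trelax, OFFSETS, "A")


class TestSimulateCestProfile:
    def test_far_off_resonance_recovers_saturation_free_limit(self):
        # shift at 119 ppm; offsets beyond 50*B1 from it behave like pure
        # R1 decay of the unsaturated z magnetization
        prof = single_state_profile(r1=1.5, trelax=0.5, b1=10.0)
        b1_ppm = 10.0 / 81.08
        far = np.abs(prof.offsets_ppm - 119.0) > 50 * b1_ppm
        assert far.any()
        assert np.allclose(prof.intensity[far], math.exp(-1.5 * 0.5), rtol=0.01)

    def test_three_state_profile_dips_at_enigma_and_pd_shifts(self):
        fx = fn.kaib_fixture("cest15N_20C")
        spin = next(s for s in fx.spins if s.residue == "N84")
        prof = fn.simulate_cest_profile(
            fx.model, spin, 20.0, 0.4, np.array(fx.acquisition.offsets_ppm)
        )
        prof.sigma = np.full_like(prof.intensity, 0.002)
        dips = fn.pick_dips(prof, depth_sigma=1.0)
        step = 25.0 / 81.08
        assert np.any(np.abs(dips - 125.2) <= step)
        assert np.any(np.abs(dips - 122.3) <= step)
        # the major dip sits at the Ground shift
        major = prof.offsets_ppm[prof.intensity.argmin()]
        assert abs(major - 119.5) <= step

    def test_doubling_b1_broadens_major_dip(self):
        fx = fn.kaib_fixture("methyl_cest_20C")
        spin = fx.spins[0]
        offsets = np.array(fx.acquisition.offsets_ppm)

        def width_at_half_depth(b1):
            prof = fn.simulate_cest_profile(fx.model, spin, b1, 0.4, offsets)
            y = prof.intensity
            plateau = np.median(np.sort(y)[-10:])
            half = (plateau + y.min()) / 2
            below = prof.offsets_ppm[y < half]
            return below.max() - below.min()

        assert width_at_half_depth(40.0) > width_at_half_depth(20.0)

    def test_minor_dips_vanish_as_exchange_vanishes(self):
        spin = fn.SpinParams(
            "x", {"A": 118.0, "B": 124.0}, r1=1.5, r2=10.0, larmor_mhz=81.08
        )
        single = single_state_profile(shift=118.0)
        for kex in (1e-3, 1e-4):
            model = fn.two_state_from_kex("A", "B", kex, 0.05)
            prof = fn.simulate_cest_profile(model, spin, 10.0, 0.5, OFFSETS, "A")
            # converges to the single-state profile everywhere
            assert np.max(np.abs(prof.intensity - single.intensity)) < 1e-4

    def test_vanishing_minor_population_converges_to_single_state(self):
        spin = fn.SpinParams(
            "x", {"A": 118.0, "B": 124.0}, r1=1.5, r2=10.0, larmor_mhz=81.08
        )
        single = single_state_profile(shift=118.0)
        model = fn.two_state_from_kex("A", "B", 100.0, 1e-7)
        prof = fn.simulate_cest_profile(model, spin, 10.0, 0.5, OFFSETS, "A")
        assert np.max(np.abs(prof.intensity - single.intensity)) < 1e-6


class TestPickDips:
    def test_flat_profile_returns_empty(self):
        prof = fn.CESTProfile(
            "x", 10.0, 0.5, OFFSETS, np.full(OFFSETS.size, 0.8),
            np.full(OFFSETS.size, 0.01), 81.08,
        )
        assert fn.pick_dips(prof).size == 0

    def test_two_dip_profile_located_within_grid_step(self):
        fx = fn.kaib_fixture("methyl_cest_20C")
        (prof,) = fn.gen_cest(fx, residues=["L82"], noise_abs=0.0, seed=0)
        dips = fn.pick_dips(prof, depth_sigma=1.0)
        step = np.diff(prof.offsets_ppm).mean()
        assert np.any(np.abs(dips - 23.0) <= step)  # Enigma shift of L82

    def test_threshold_above_depth_returns_empty(self):
        fx = fn.kaib_fixture("methyl_cest_20C")
        (prof,) = fn.gen_cest(fx, residues=["L82"], noise_abs=0.0, seed=0)
        prof.sigma = np.full_like(prof.intensity, 10.0)  # 3 sigma >> any dip
        assert fn.pick_dips(prof).size == 0


class TestReducedChi2:
    def test_zero_residuals(self):
        assert reduced_chi2(np.zeros(10), np.ones(10), 3) == 0.0

    def test_unit_normalized_residuals(self):
        assert reduced_chi2(np.ones(8), np.ones(8), 0) == pytest.approx(1.0)

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=40)
        s = rng.uniform(0.5, 2.0, size=40)
        expected = sum((ri / si) ** 2 for ri, si in zip(r, s)) / (40 - 5)
        assert reduced_chi2(r, s, 5) == pytest.approx(expected, abs=1e-12)


class TestFitCestGlobal:
    def test_methyl_two_state_recovery(self, methyl_fit):
        _, _, fit = methyl_fit
        kex = fit.kex[("Enigma", "Ground")]
        assert kex == pytest.approx(173.0, rel=0.10)
        assert fit.populations["Enigma"] == pytest.approx(0.07, rel=0.15)
        assert fit.redchi2 < 1.3

    def test_noiseless_two_state_recovery_tight(self):
        fx = fn.kaib_fixture("methyl_cest_20C")
        profiles = fn.gen_cest(fx, residues=3, noise_abs=0.0, seed=0)
        fit = fn.fit_cest_global(profiles, fx.model, n_starts=1, max_nfev=400)
        assert fit.kex[("Enigma", "Ground")] == pytest.approx(173.0, rel=0.005)
        assert fit.populations["Enigma"] == pytest.approx(0.07, rel=0.005)

    def test_three_state_chain_recovery(self, chain_fit):
        _, _, fit = chain_fit
        assert fit.populations["Enigma"] == pytest.approx(0.08, abs=0.02)
        assert fit.populations["PD"] == pytest.approx(0.03, abs=0.02)
        assert fit.rates[("Ground", "Enigma")] == pytest.approx(12.0, rel=0.2)

    def test_no_exchange_model_fits_worse_than_two_state(self, methyl_fit):
        fx, profiles, fit2 = methyl_fit
        one_state = fn.ExchangeModel(("Ground",), {})
        stripped = [
            fn.CESTProfile(
                p.residue, p.b1_hz, p.trelax_s, p.offsets_ppm, p.intensity,
                p.sigma, p.larmor_mhz, p.observed_state,
            )
            for p in profiles
        ]
        fit1 = fn.fit_cest_global(stripped, one_state, n_starts=1, max_nfev=200)
        assert fit1.redchi2 > fit2.redchi2 * 2

    def test_empty_profile_list_rejected(self):
        fx = fn.kaib_fixture("methyl_cest_20C")
        with pytest.raises(ValueError, match="at least one"):
            fn.fit_cest_global([], fx.model)

    def test_se_calibration_and_bias_over_replicates(self):
        """Recovery bias < 5% and nominal SE within a factor ~2 of empirical."""
        fx = fn.kaib_fixture("methyl_cest_20C")
        kexs, ses = [], []
        for seed in range(8):
            profiles = fn.gen_cest(fx, residues=3, noise_abs=0.01, seed=20 + seed)
            fit = fn.fit_cest_global(profiles, fx.model, n_starts=1, max_nfev=300)
            kexs.append(fit.kex[("Enigma", "Ground")])
            ses.append(fit.kex_se[("Enigma", "Ground")])
        kexs = np.asarray(kexs)
        assert abs(np.mean(kexs) / 173.0 - 1) < 0.05
        empirical = np.std(kexs, ddof=1)
        nominal = np.median(ses)
        assert 0.33 < nominal / empirical < 3.0

    def test_unidentifiable_extra_edge_barely_changes_chi2(self, chain_fit):
        """An Enigma<->PD edge with a tiny rate is invisible to the data."""
        fx, profiles, fit = chain_fit
        base_rates = dict(fit.rates)
        augmented = dict(base_rates)
        augmented[("Enigma", "PD")] = 1e-3
        augmented[("PD", "Enigma")] = 1e-3 * (
            fit.populations["Enigma"] / fit.populations["PD"]
        )

        rows = fit.residue_params.set_index("residue")

        def chi2_for(rates):
            model = fn.ExchangeModel(fit.states, rates)
            total = 0.0
            n = 0
            for p in profiles:
                row = rows.loc[p.residue]
                spin = fn.SpinParams(
                    p.residue,
                    {s: row[f"shift_{s}"] for s in fit.states},
                    r1=row["r1"],
                    r2={s: row[f"r2_{s}"] for s in fit.states},
                    larmor_mhz=p.larmor_mhz,
                )
                sim = fn.simulate_cest_profile(
                    model, spin, p.b1_hz, p.trelax_s, p.offsets_ppm
                )
                total += np.sum(((sim.intensity - p.intensity) / p.sigma) ** 2)
                n += p.intensity.size
            return total / (n - fit.n_params)

        chain = chi2_for(base_rates)
        extra = chi2_for(augmented)
        assert abs(extra - chain) / chain < 0.01


class TestCompareTopologies:
    def test_chain_data_discriminates_topologies(self, chain_fit):
        fx, profiles, _ = chain_fit
        chain = fx.model
        full_rates = dict(chain.rates)
        full_rates[("Enigma", "PD")] = 0.5
        full_rates[("PD", "Enigma")] = 0.5
        fully = fn.ExchangeModel(chain.states, full_rates)
        eg_only = fn.two_state_from_kex("Ground", "Enigma", 145.0, 0.08)
        table = fn.compare_topologies(
            profiles,
            {"chain": chain, "full": fully, "EG-only": eg_only},
            constraints={"tie_r2": [("Enigma", "Ground")]},
            n_starts=1,
            max_nfev=300,
        )
        by_name = table.set_index("topology")
        assert bool(by_name.loc["chain", "comparable"])
        best = table["redchi2"].min()
        assert by_name.loc["EG-only", "redchi2"] > 1.5 * best

    def test_single_topology_list(self, methyl_fit):
        fx, profiles, _ = methyl_fit
        table = fn.compare_topologies(
            profiles[:2], {"two-state": fx.model}, n_starts=1, max_nfev=150
        )
        assert len(table) == 1
        assert bool(table["comparable"].iloc[0])
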