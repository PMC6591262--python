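"""Two-step denitrification simulator and the seeded data generators."""

from __future__ import annotations

import numpy as np
import pytest

from meorkit.columns import CalibrationCurve, ColumnSpec, compute_roip, percent_roip
from meorkit.ecology import aggregate_rank, shannon_index
from meorkit.simulate import (
    FlowSchedule,
    KineticParams,
    NoiseSpec,
    default_params,
    generate_column_dataset,
    generate_dose_response,
    generate_effluent_series,
    generate_otu_counts,
    simulate_batch,
    simulate_chemostat,
)

SCHED = FlowSchedule(steps=[(0, 0.0), (9, 0.1), (29, 0.2)])


@pytest.fixture(scope="module")
def batch_sim():
    return simulate_batch(default_params(), nitrate0=10.0, t_end=12.0)


@pytest.fixture(scope="module")
def chemostat_sim():
    return simulate_chemostat(default_params(), SCHED, t_end=70.0)


class TestBatchKinetics:
    def test_sequential_two_step_reduction_timing(self, batch_sim):
        """Nitrate depleted between day 2 and 4, a transient nitrite peak
        above 5 mM, and nitrite cleared below 0.5 mM by day 9."""
        t = batch_sim.time
        t_no3 = t[np.where(batch_sim.nitrate < 0.1)[0][0]]
        assert 2.0 < t_no3 < 4.0
        assert batch_sim.nitrite.max() > 5.0
        assert np.interp(9.0, t, batch_sim.nitrite) < 0.5

    def test_zero_inoculum_is_inert(self):
        sim = simulate_batch(default_params(X0=0.0), nitrate0=10.0, t_end=5.0)
        assert np.allclose(sim.nitrate, 10.0)
        assert np.allclose(sim.od600, 0.0)

    def test_electron_conservation_at_half_stoichiometric_donor(self):
        p = default_params(donor0=1.19 / 2)
        sim = simulate_batch(p, nitrate0=10.0, t_end=30.0)
        donor_e = (p.donor0 - sim.donor[-1]) * p.gamma_donor
        # 2 e-/N for all nitrate that left the NO3 pool, plus 3 e-/N for the
        # nitrogen that went on to N2
        accepted_e = 2.0 * (10.0 - sim.nitrate[-1]) + 3.0 * sim.n2_n[-1]
        assert accepted_e == pytest.approx(donor_e, rel=0.01)

    def test_nitrogen_balance_closes(self, batch_sim):
        assert batch_sim.nitrogen_residual() < 1e-3

    def test_step_size_cap(self):
        with pytest.raises(ValueError):
            simulate_batch(default_params(), dt=0.5)


class TestChemostat:
    def test_dilution_step_breakthrough_ordering(self, chemostat_sim):
        """Effluent nitrate+nitrite rises after each dilution-rate step; the
        second breakthrough exceeds the first and levels stay below 0.2 mM."""
        t = chemostat_sim.time
        tot = chemostat_sim.nitrate + chemostat_sim.nitrite
        phase1 = tot[(t > 9.0) & (t <= 29.0)]
        phase2 = tot[t > 29.0]
        pre1 = tot[(t > 8.5) & (t <= 9.0)].max()
        pre2 = tot[(t > 28.5) & (t <= 29.0)].max()
        assert phase1.max() > pre1 + 0.01  # breakthrough after first step
        assert phase2.max() > pre2 + 0.01  # and after the second
        assert phase2.max() > phase1.max()  # second exceeds first
        assert phase1.max() < 0.2 and phase2.max() < 0.2

    def test_biomass_reaches_continuous_culture_density(self, chemostat_sim):
        od65 = np.interp(65.0, chemostat_sim.time, chemostat_sim.od600)
        assert 3.0 < od65 < 3.5

    def test_washout_above_maximum_growth_rate(self):
        sim = simulate_chemostat(
            default_params(), FlowSchedule(steps=[(0, 2.5)]), t_end=40.0
        )
        assert sim.od600[-1] < 1e-6
        assert sim.nitrate[-1] == pytest.approx(10.0, rel=0.01)
        # decline is monotone after the initial transient
        tail = sim.od600[sim.time > 10.0]
        assert np.all(np.diff(tail) <= 1e-12)

    def test_zero_dilution_reduces_to_batch(self):
        p = default_params()
        batch = simulate_batch(p, nitrate0=10.0, t_end=12.0)
        chemo = simulate_chemostat(
            p, FlowSchedule(steps=[(0, 0.0)]), t_end=12.0
        )
        assert np.allclose(batch.nitrate, chemo.nitrate)
        assert np.allclose(batch.od600, chemo.od600)

    def test_nitrogen_balance_with_flow(self, chemostat_sim):
        assert chemostat_sim.nitrogen_residual() < 1e-3

    def test_halving_dt_barely_moves_trajectories(self):
        p = default_params()
        a = simulate_batch(p, t_end=12.0, dt=0.01)
        b = simulate_batch(p, t_end=12.0, dt=0.005)
        for chan in ("nitrate", "nitrite", "od600"):
            xa, xb = getattr(a, chan), getattr(b, chan)
            scale = np.abs(xa).max()
            diff = np.abs(np.interp(a.time, b.time, xb) - xa).max()
            assert diff / scale < 1e-4

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            FlowSchedule(steps=[(1, 0.1)])
        with pytest.raises(ValueError):
            FlowSchedule(steps=[(0, 0.1), (0, 0.2)])


class TestEffluentSeries:
    def test_zero_noise_is_exact_interpolation(self, batch_sim):
        days = [0.5, 1.5, 3.25]
        df = generate_effluent_series(
            batch_sim, NoiseSpec(sigma={}, seed=1), days
        )
        expect = np.interp(days, batch_sim.time, batch_sim.nitrate)
        assert df["nitrate_mM"].values == pytest.approx(expect)

    def test_seed_reproducibility(self, batch_sim):
        spec = NoiseSpec(sigma={"nitrate_mM": 0.2}, seed=99)
        days = np.linspace(0, 10, 25)
        a = generate_effluent_series(batch_sim, spec, days)
        b = generate_effluent_series(batch_sim, spec, days)
        assert a.equals(b)

    def test_noise_magnitude(self, batch_sim):
        days = np.linspace(0.0, 11.9, 1000)
        df = generate_effluent_series(
            batch_sim, NoiseSpec(sigma={"od600": 0.2}, seed=3), days
        )
        clean = np.interp(days, batch_sim.time, batch_sim.od600)
        resid = df["od600"].values - clean
        assert np.std(resid) == pytest.approx(0.2, abs=0.02)

    def test_out_of_range_days_rejected(self, batch_sim):
        with pytest.raises(ValueError):
            generate_effluent_series(batch_sim, NoiseSpec(sigma={}, seed=1), [50.0])


class TestDoseResponseGenerator:
    def test_noiseless_table_reproduces_the_line(self):
        df = generate_dose_response(11.2, 8.3, 0.0, [0.258], seed=0)
        assert round(float(df["percent_roip"][0]), 1) == 11.2

    def test_round_trip_through_ols(self):
        from meorkit.response import BiomassDose, fit_ols

        df = generate_dose_response(11.2, 8.3, 0.0, np.linspace(0.1, 1.8, 10), seed=0)
        fit = fit_ols([BiomassDose(r.od600, r.percent_roip) for r in df.itertuples()])
        assert fit.slope == pytest.approx(11.2, rel=1e-9)
        assert fit.intercept == pytest.approx(8.3, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        a = generate_dose_response(11.2, 8.3, 0.5, np.linspace(0.1, 1.8, 20), seed=5)
        b = generate_dose_response(11.2, 8.3, 0.5, np.linspace(0.1, 1.8, 20), seed=5)
        assert a.equals(b)


class TestOtuGenerator:
    PROFILE = {
        "Thauera": 0.529,
        "Pseudomonas": 0.078,
        "Acetoanaerobium": 0.15,
        "Desulfuromonas": 0.13,
        "Sphaerochaeta": 0.113,
    }

    def test_large_depth_recovers_profile_within_one_percent(self):
        table, tax = generate_otu_counts(
            self.PROFILE, depth=10**6, overdispersion=0.0, n_samples=2, seed=12
        )
        agg = aggregate_rank(table, tax, "genus")
        for genus, p in self.PROFILE.items():
            for s in table.samples:
                assert agg.loc[genus, s] == pytest.approx(p, abs=0.01)

    def test_dominant_genus_round_trip(self):
        table, tax = generate_otu_counts(
            self.PROFILE, depth=20000, overdispersion=0.02, n_samples=6, seed=7
        )
        agg = aggregate_rank(table, tax, "genus")
        mean_thauera = agg.loc["Thauera"].mean()
        assert mean_thauera == pytest.approx(0.529, abs=0.08)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            generate_otu_counts(self.PROFILE, 0, 0.0, 1, seed=1)

    def test_profile_must_sum_to_one(self):
        with pytest.raises(ValueError):
            generate_otu_counts({"Thauera": 0.7}, 100, 0.0, 1, seed=1)

    def test_single_taxon_profile_has_zero_shannon(self):
        table, _ = generate_otu_counts({"Thauera": 1.0}, 1000, 0.0, 3, seed=2)
        genus_counts = table.counts.groupby(
            lambda otu: "Thauera"
        ).sum()  # all OTUs same genus
        for s in table.samples:
            assert shannon_index(genus_counts[s].values) == 0.0

    def test_seeded_reproducibility(self):
        a, _ = generate_otu_counts(self.PROFILE, 5000, 0.02, 3, seed=4)
        b, _ = generate_otu_counts(self.PROFILE, 5000, 0.02, 3, seed=4)
        assert a.counts.equals(b.counts)


class TestColumnGenerator:
    CAL = CalibrationCurve(slope=2.0, intercept=0.02)
    SPEC = ColumnSpec(id="col", PV=35.0, oil_injected=33.0)

    def _reduce(self, samples):
        wf = [s for s in samples if s.stage == "waterflood"]
        meor = [s for s in samples if s.stage == "MEOR"]
        return percent_roip(compute_roip(self.SPEC, wf, self.CAL), meor, self.CAL)

    def test_noiseless_round_trip_is_exact(self):
        samples = generate_column_dataset(
            self.SPEC, true_roip=17.0, waterflood_profile=None, meor_percent=16.0,
            calib=self.CAL, noise=NoiseSpec(sigma={}, seed=0),
        )
        res = self._reduce(samples)
        assert res.ROIP == pytest.approx(17.0, rel=1e-9)
        assert res.percent_roip == pytest.approx(16.0, rel=1e-9)

    def test_noisy_round_trip_recovers_percent_within_one(self):
        vals = []
        for seed in range(30):
            samples = generate_column_dataset(
                self.SPEC, 17.0, None, 16.0, self.CAL,
                noise=NoiseSpec(sigma={"a600": 0.01}, seed=seed),
            )
            vals.append(self._reduce(samples).percent_roip)
        assert np.mean(vals) == pytest.approx(16.0, abs=1.0)

    def test_zero_oil_waterflood_leaves_all_injected_oil(self):
        samples = generate_column_dataset(
            self.SPEC, true_roip=self.SPEC.oil_injected, waterflood_profile=None,
            meor_percent=0.0, calib=self.CAL, noise=NoiseSpec(sigma={}, seed=0),
        )
        res = self._reduce(samples)
        assert res.ROIP == pytest.approx(self.SPEC.oil_injected)
        assert res.percent_roip == 0.0

    def test_oil_mass_balance(self):
        samples = generate_column_dataset(
            self.SPEC, 17.0, None, 16.0, self.CAL, noise=NoiseSpec(sigma={}, seed=0)
        )
        from meorkit.columns import oil_volume_from_A600

        produced = sum(oil_volume_from_A600(s, self.CAL) for s in samples)
        remaining = 17.0 * (1 - 0.16)
        assert produced + remaining == pytest.approx(self.SPEC.oil_injected, rel=1e-9)


def test_kinetic_parameter_validation():
    with pytest.raises(ValueError):
        KineticParams(qmax1=-1, qmax2=1, K1=1, K2=1, Y=1, X0=0.1, donor0=1)
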