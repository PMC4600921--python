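"""Phase-2 sampling: organ masses, flows, and the two balance operations."""

import numpy as np
import pytest

from physiopop import (
    ORGANS,
    LOGNORMAL_ORGANS,
    ContextualConstraints,
    simulate_individual,
    simulate_population,
)
from physiopop.organs import (
    BalanceError,
    Z90,
    organ_mass_location,
    rebalance_flows,
    rebalance_masses,
    sample_flow_fractions,
    sample_organ_masses,
)
from conftest import zero_sigma


class TestMassLocations:
    def test_liver_height_linear(self, uk_male_white):
        loc = organ_mass_location(uk_male_white.organs["liver"], "male",
                                  30.0, 176.0, 80.0, 25.0)
        assert loc == pytest.approx(2.449)

    def test_spleen_lognormal_location(self, uk_male_white):
        loc = organ_mass_location(uk_male_white.organs["spleen"], "male",
                                  30.0, 176.0, 80.0, 25.0)
        assert loc == pytest.approx(-1.4448)
        assert np.exp(loc) == pytest.approx(0.2358, abs=1e-3)

    def test_sexual_organs_constant(self, uk_female_white):
        loc = organ_mass_location(uk_female_white.organs["sexual_organs"],
                                  "female", 40.0, 160.0, 60.0, 23.0)
        assert loc == pytest.approx(0.012)

    def test_adipose_full_form(self, uk_male_white):
        loc = organ_mass_location(uk_male_white.organs["adipose"], "male",
                                  30.0, 177.0, 78.0, 25.0)
        assert loc == pytest.approx(2.985, abs=1e-3)
        assert np.exp(loc) == pytest.approx(19.79, abs=0.05)

    def test_bone_male_logistic_saturates(self, uk_male_white):
        bone = uk_male_white.organs["bone"]
        young = organ_mass_location(bone, "male", 16.0, 176.0, 70.0, 23.0)
        adult = organ_mass_location(bone, "male", 40.0, 176.0, 70.0, 23.0)
        c = bone.coeff
        saturated = c("alpha") + (c("h1") + c("h2")) * 176.0
        assert adult == pytest.approx(saturated, abs=0.05)
        assert young < adult  # skeleton still accruing mass at 16


class TestMassSampling:
    def test_truncation_band_and_mean(self, uk_male_white, rng):
        n = 100_000
        masses = sample_organ_masses(uk_male_white, np.full(n, 30.0),
                                     np.full(n, 176.0), np.full(n, 80.0),
                                     np.full(n, 25.8), rng)
        liver = masses["liver"]
        assert liver.min() >= 2.449 - Z90 * 0.591
        assert liver.max() <= 2.449 + Z90 * 0.591
        # symmetric truncation preserves the location as the mean
        assert np.mean(liver) == pytest.approx(2.449, abs=0.01)

    def test_lognormal_organs_positive(self, uk_male_white, rng):
        masses = sample_organ_masses(uk_male_white, np.full(500, 30.0),
                                     np.full(500, 176.0), np.full(500, 80.0),
                                     np.full(500, 25.8), rng)
        for organ in ORGANS:
            assert np.all(masses[organ] > 0), organ

    def test_zero_sigma_returns_locations(self, uk_male_white, rng):
        params = zero_sigma(uk_male_white)
        masses = sample_organ_masses(params, np.array([30.0]), np.array([176.0]),
                                     np.array([80.0]), np.array([25.8]), rng)
        for organ in ORGANS:
            loc = organ_mass_location(params.organs[organ], "male",
                                      30.0, 176.0, 80.0, 25.8)
            expected = np.exp(loc) if organ in LOGNORMAL_ORGANS else loc
            assert masses[organ][0] == pytest.approx(float(expected), rel=1e-12)

    def test_adipose_muscle_correlation_matches_oracle(self, uk_male_white):
        """Sequentially truncated bivariate draws vs a rejection-sampling oracle."""
        n = 100_000
        age, height, bm, bmi = 40.0, 177.0, 80.0, 25.5
        masses = sample_organ_masses(
            uk_male_white, np.full(n, age), np.full(n, height),
            np.full(n, bm), np.full(n, bmi), np.random.default_rng(7))
        r_impl = np.corrcoef(np.log(masses["adipose"]), np.log(masses["muscle"]))[0, 1]

        # independent oracle: plain rejection sampling of the same scheme
        rng = np.random.default_rng(8)
        ad, mu = uk_male_white.organs["adipose"], uk_male_white.organs["muscle"]
        rho = uk_male_white.rho_adipose_muscle
        mu_a = organ_mass_location(ad, "male", age, height, bm, bmi)
        mu_m = organ_mass_location(mu, "male", age, height, bm, bmi)
        la = np.empty(n)
        filled = 0
        while filled < n:
            cand = rng.normal(mu_a, ad.sigma, size=2 * n)
            cand = cand[np.abs(cand - mu_a) <= Z90 * ad.sigma][: n - filled]
            la[filled:filled + cand.size] = cand
            filled += cand.size
        cond_mu = mu_m + (mu.sigma / ad.sigma) * rho * (la - mu_a)
        cond_sd = np.sqrt(1 - rho**2) * mu.sigma
        lm = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            cand = rng.normal(cond_mu[todo], cond_sd)
            ok = np.abs(cand - mu_m) <= Z90 * mu.sigma
            lm[todo[ok]] = cand[ok]
            todo = todo[~ok]
        r_oracle = np.corrcoef(la, lm)[0, 1]
        assert r_impl == pytest.approx(r_oracle, abs=0.01)
        # the strong negative coupling survives truncation
        assert r_impl < -0.75


class TestFlows:
    def test_fractions_within_two_sd(self, uk_female_white, rng):
        fractions = sample_flow_fractions(uk_female_white, 100_000, rng)
        kidney = fractions["kidneys"]
        assert kidney.min() >= 0.204 - 0.092
        assert kidney.max() <= 0.204 + 0.092
        for organ in ORGANS:
            model = uk_female_white.organs[organ]
            assert np.all(fractions[organ] > 0)
            assert np.all(np.abs(fractions[organ] - model.flow_c1)
                          <= 2 * model.flow_sigma + 1e-12)

    def test_zero_sigma_fraction_is_c1(self, uk_female_white, rng):
        fractions = sample_flow_fractions(zero_sigma(uk_female_white), 3, rng)
        for organ in ORGANS:
            assert np.allclose(fractions[organ],
                               uk_female_white.organs[organ].flow_c1)

    def test_rebalance_preserves_ratios_and_total(self, rng):
        fractions = {"a": np.array([0.2]), "b": np.array([0.3]), "c": np.array([0.5])}
        flows = rebalance_flows(fractions, 6.0)
        assert flows["a"][0] == pytest.approx(1.2)
        assert flows["c"][0] == pytest.approx(3.0)

    def test_deterministic_female_kidney_flow(self, uk_female_white):
        fractions = {o: np.array([uk_female_white.organs[o].flow_c1])
                     for o in ORGANS}
        flows = rebalance_flows(fractions, 5.896)
        assert flows["kidneys"][0] == pytest.approx(0.204 / 1.0232 * 5.896, rel=1e-9)
        assert flows["kidneys"][0] == pytest.approx(1.176, abs=2e-3)
        total = sum(v for v in flows.values())
        assert total[0] == pytest.approx(5.896, rel=1e-12)


class TestMassRebalance:
    def test_worked_example(self):
        raw = {"liver": np.array([20.0]), "adipose": np.array([15.0]),
               "muscle": np.array([25.0])}
        out = rebalance_masses(raw, 70.0)
        assert out["adipose"][0] == pytest.approx(18.75)
        assert out["muscle"][0] == pytest.approx(31.25)
        assert out["liver"][0] == 20.0
        # common factor preserves the adipose:muscle ratio
        assert out["adipose"][0] / out["muscle"][0] == pytest.approx(15.0 / 25.0)

    def test_no_room_errors(self):
        raw = {"liver": np.array([80.0]), "adipose": np.array([5.0]),
               "muscle": np.array([10.0])}
        with pytest.raises(BalanceError):
            rebalance_masses(raw, 70.0)


class TestSimulate:
    def test_balance_invariants(self, rng):
        pop = simulate_population(("UK", "male", "White"), 2_000, rng=rng)
        f = pop.frame
        mass_total = f[[f"mass_{o}_kg" for o in ORGANS]].sum(axis=1)
        flow_total = f[[f"flow_{o}_l_min" for o in ORGANS]].sum(axis=1)
        assert np.allclose(mass_total, f["body_mass_kg"], rtol=1e-9)
        assert np.allclose(flow_total, f["cardiac_output_l_min"], rtol=1e-9)
        assert (f[[f"mass_{o}_kg" for o in ORGANS]].to_numpy() > 0).all()
        assert (f[[f"flow_{o}_l_min" for o in ORGANS]].to_numpy() > 0).all()

    def test_soft_tissue_share_plausible(self):
        pop = simulate_population(("UK", "male", "White"), 5_000, seed=42)
        f = pop.frame
        share = (f["mass_adipose_kg"] + f["mass_muscle_kg"]) / f["body_mass_kg"]
        assert np.mean((share >= 0.4) & (share <= 0.9)) >= 0.99

    def test_seeded_runs_identical(self):
        a = simulate_population(("US", "female", "Black"), 200, seed=9)
        b = simulate_population(("US", "female", "Black"), 200, seed=9)
        assert a.frame.equals(b.frame)

    def test_zero_sigma_pipeline_matches_closed_form(self, uk_male_white):
        """Brute-force oracle: with all dispersions at 0 the pipeline must equal
        direct evaluation of the location formulas plus the two rebalances."""
        params = zero_sigma(uk_male_white)
        constraints = ContextualConstraints(age=30)
        phys = simulate_individual(params, constraints=constraints, seed=0)

        # independent closed-form evaluation
        a = params.anthro
        age = 30.0
        height = a.height_alpha + a.height_a1 * age + a.height_a2 * age**2
        bm = np.exp(a.logbm_alpha + a.logbm_a1 * age + a.logbm_a2 * age**2)
        bmi = bm / (height / 100.0) ** 2
        co = (params.co.alpha + params.co.h1 * height + params.co.a1 * age
              + params.co.a2 / (1 + np.exp(-params.co.a3 * (age - 18.0))))
        assert phys.individual.height == pytest.approx(height, rel=1e-12)
        assert phys.individual.body_mass == pytest.approx(bm, rel=1e-12)
        assert phys.individual.cardiac_output == pytest.approx(co, rel=1e-12)

        locs = {}
        for organ in ORGANS:
            c = params.organs[organ].coeff
            if organ == "brain":
                v = c("alpha") + c("a1") * age
            elif organ == "sexual_organs":
                v = c("alpha")
            elif organ == "skin":
                v = c("alpha") + c("m1") * bm + c("m2") * bm**2
            elif organ == "bone":
                v = (c("alpha") + c("h1") * height
                     + c("h2") * height / (1 + np.exp(-c("a1") * (age - 18.0))))
            elif organ in ("adipose", "muscle"):
                v = (c("alpha") + c("a1") * age + c("a2") * age**2
                     + c("h1") * height + c("b1") * bmi + c("b2") * bmi**2)
            else:
                v = c("alpha") + c("h1") * height
            locs[organ] = np.exp(v) if organ in LOGNORMAL_ORGANS else v
        others = sum(v for o, v in locs.items() if o not in ("adipose", "muscle"))
        lam = (bm - others) / (locs["adipose"] + locs["muscle"])
        total_c1 = sum(params.organs[o].flow_c1 for o in ORGANS)
        for organ in ORGANS:
            expected_mass = locs[organ] * (lam if organ in ("adipose", "muscle") else 1.0)
            expected_flow = co * params.organs[organ].flow_c1 / total_c1
            assert phys.masses[organ] == pytest.approx(expected_mass, rel=1e-10), organ
            assert phys.flows[organ] == pytest.approx(expected_flow, rel=1e-10), organ

    def test_physiology_accessor(self):
        pop = simulate_population(("UK", "female", "Asian"), 5, seed=3)
        phys = pop[2]
        assert phys.total_mass() == pytest.approx(phys.individual.body_mass, rel=1e-9)
        assert phys.total_flow() == pytest.approx(phys.individual.cardiac_output,
                                                  rel=1e-9)
        assert 17.5 <= phys.individual.bmi <= 32.5
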