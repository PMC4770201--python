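import math

import numpy as np
import pytest

from dmfsynth.dmf_protocol import serial_dilution_routine
from dmfsynth.dmf_simulator import execute
from dmfsynth.mic_cloning import (
    barcode_collision_prob,
    barcode_space,
    call_clonality,
    clonal_fraction,
    plan_limiting_dilution,
    poisson_occupancy,
    simulate_smpcr,
)


class TestPoissonOccupancy:
    def test_empty_droplet_at_unit_occupancy(self):
        assert poisson_occupancy(1.0, 0) == pytest.approx(math.exp(-1))

    def test_zero_lambda(self):
        assert poisson_occupancy(0.0, 0) == 1.0
        assert poisson_occupancy(0.0, 3) == 0.0

    def test_normalization(self):
        total = sum(poisson_occupancy(1.0, k) for k in range(51))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            poisson_occupancy(-0.1, 0)


class TestClonalFraction:
    def test_closed_form_at_lambda_one(self):
        p1, cond = clonal_fraction(1.0)
        assert p1 == pytest.approx(0.3679, abs=5e-5)
        assert cond == pytest.approx(0.5820, abs=5e-5)

    def test_conditional_fraction_tends_to_one(self):
        _, cond = clonal_fraction(1e-6)
        assert cond == pytest.approx(1.0, abs=1e-5)

    def test_single_molecule_fraction_maximized_at_one(self):
        grid = np.linspace(0.05, 5.0, 200)
        vals = [clonal_fraction(l)[0] for l in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(1.0, abs=0.05)


class TestPlanLimitingDilution:
    def test_64x_is_six_steps(self):
        plan = plan_limiting_dilution(64, 1.0)
        assert plan.steps == 6 and plan.achieved_lambda == 1.0

    def test_thousand_to_half(self):
        plan = plan_limiting_dilution(1000, 0.5)
        assert plan.steps == 11
        assert plan.achieved_lambda == pytest.approx(1000 / 2048)

    def test_already_dilute(self):
        assert plan_limiting_dilution(1.0, 1.0).steps == 0

    def test_achieved_lambda_invariant(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            initial = float(rng.uniform(1, 1e5))
            target = float(rng.uniform(0.05, 1.0))
            plan = plan_limiting_dilution(initial, target)
            assert plan.achieved_lambda <= target + 1e-9
            if plan.steps > 0:
                assert initial / 2 ** (plan.steps - 1) > target

    def test_target_above_initial_rejected(self):
        with pytest.raises(ValueError):
            plan_limiting_dilution(1.0, 2.0)


class TestSimulateSmPcr:
    def test_amplified_fraction_matches_poisson(self):
        out = simulate_smpcr(10_000, 1.0, seed=11)
        frac = np.mean([o.amplified for o in out])
        p = 1 - math.exp(-1)
        se = math.sqrt(p * (1 - p) / len(out))
        assert abs(frac - p) <= 3 * se

    def test_clonal_of_amplified_matches_closed_form(self):
        out = simulate_smpcr(10_000, 1.0, seed=12)
        amp = [o for o in out if o.amplified]
        frac = np.mean([o.clonal for o in amp])
        p = clonal_fraction(1.0)[1]
        se = math.sqrt(p * (1 - p) / len(amp))
        assert abs(frac - p) <= 3 * se

    def test_count_mean_matches_lambda(self):
        lam = 0.7
        out = simulate_smpcr(10_000, lam, seed=13)
        counts = np.array([o.molecules for o in out])
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - lam) <= 3 * se

    def test_zero_lambda_all_empty(self):
        out = simulate_smpcr(100, 0.0, seed=14)
        assert all(not o.amplified and not o.clonal and o.molecules == 0
                   for o in out)
        assert all(o.founder_barcodes == () for o in out)

    def test_clonal_implies_amplified(self):
        out = simulate_smpcr(5000, 2.0, seed=15)
        assert all(o.amplified for o in out if o.clonal)


class TestCallClonality:
    def test_identical_reads_clonal(self):
        call = call_clonality(["ACGTACGTACGTAA"] * 20)
        assert call.call == "clonal"
        assert np.allclose(call.base_fractions.sum(axis=1), 1.0)

    def test_two_founders_mixed(self):
        x, y = "ACGTACGTACGTAA", "ACGTACGTACGTAC"
        assert call_clonality([x] * 10 + [y] * 10).call == "mixed"

    def test_no_reads_empty(self):
        assert call_clonality([]).call == "empty"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_clonality(["ACGT", "ACG"])

    def test_robust_to_one_percent_read_error(self):
        rng = np.random.default_rng(16)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        clonal_calls = 0
        n_trials = 300
        for _ in range(n_trials):
            barcode = bases[rng.integers(0, 4, 14)]
            reads = []
            for _ in range(20):
                read = barcode.copy()
                err = rng.random(14) < 0.01
                read[err] = bases[rng.integers(0, 4, int(err.sum()))]
                reads.append(read.tobytes().decode())
            if call_clonality(reads).call == "clonal":
                clonal_calls += 1
        assert clonal_calls / n_trials >= 0.99


class TestBarcodeCollisionProb:
    def test_single_pair_14n(self):
        assert barcode_collision_prob(2, 14) == pytest.approx(1 / 4 ** 14)

    def test_single_pair_len1(self):
        assert barcode_collision_prob(2, 1) == pytest.approx(0.25)

    def test_matches_monte_carlo(self):
        n, length = 200, 8  # appreciable collision probability
        p = barcode_collision_prob(n, length)
        rng = np.random.default_rng(17)
        space = 4 ** length
        hits = sum(
            len(np.unique(rng.integers(0, space, n))) < n
            for _ in range(20_000)
        )
        frac = hits / 20_000
        se = math.sqrt(p * (1 - p) / 20_000)
        assert abs(frac - p) <= 3 * se

    def test_space_size(self):
        assert barcode_space(14) == 4 ** 14 == 268_435_456


class TestIntegrationWithSimulator:
    def test_clonal_fraction_after_on_cartridge_dilution(self):
        initial = 64
        plan = plan_limiting_dilution(initial, 1.0)
        key = "T" * 200
        prot = serial_dilution_routine(plan.steps, contents={key: initial})
        counts = [
            execute(prot, seed=s).eluted[0].composition[key]
            for s in range(1000)
        ]
        frac_one = np.mean([c == 1 for c in counts])
        p1, _ = clonal_fraction(plan.achieved_lambda)
        se = math.sqrt(p1 * (1 - p1) / len(counts))
        assert abs(frac_one - p1) <= 3 * se
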