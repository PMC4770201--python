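import numpy as np
import pytest

from dmfsynth.dmf_protocol import (
    AVOGADRO,
    DropletOp,
    Protocol,
    ProtocolBuilder,
    ThermalProgram,
    compile_protocol,
    default_layout,
    serial_dilution_routine,
)
from dmfsynth.dmf_simulator import (
    SimulationFault,
    execute,
    pcr_update,
    predict_amplicon,
    volume_ledger,
)
from dmfsynth.pop_planner import plan_pop
from dmfsynth.seqcore import NucSequence, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _seq(rng, n):
    return NucSequence("".join(_BASES[rng.integers(0, 4, n)].astype("U1")))


class TestPcrUpdate:
    rng = np.random.default_rng(0)
    tpl = str(_seq(rng, 300))

    def _primers(self):
        return self.tpl[:20], str(revcomp(self.tpl[-20:]))

    def test_doubling_with_abundant_primers(self):
        f, r = self._primers()
        comp = {self.tpl: 10, f: 1e15, r: 1e15}
        out = pcr_update(comp, efficiency=1.0, cycles=3)
        assert out[self.tpl] == pytest.approx(80)

    def test_no_template_no_product(self):
        f, r = self._primers()
        out = pcr_update({self.tpl: 0, f: 1e15, r: 1e15}, efficiency=1.0, cycles=10)
        assert out[self.tpl] == 0

    def test_primer_cap_at_point_one_picomole(self):
        f, r = self._primers()
        primer_molecules = 0.1e-12 * AVOGADRO  # ~6.0e10
        comp = {self.tpl: 1, f: primer_molecules, r: primer_molecules}
        out = pcr_update(comp, efficiency=1.0, cycles=50)
        assert out[self.tpl] == pytest.approx(primer_molecules, rel=1e-6)
        assert out[self.tpl] < 2 ** 50

    def test_tailed_primers_extend_product(self):
        f, r = self._primers()
        comp = {self.tpl: 100, "TTTT" + f: 1e15, "GGGG" + r: 1e15}
        out = pcr_update(comp, efficiency=1.0, cycles=5)
        product = "TTTT" + self.tpl + "CCCC"
        assert out[product] > out[self.tpl]

    def test_overlap_fusion_join(self):
        rng = np.random.default_rng(3)
        a = str(_seq(rng, 200))
        b_tail = str(_seq(rng, 170))
        b = a[-30:] + b_tail
        out = pcr_update({a: 1e9, b: 1e9}, efficiency=0.9, cycles=10)
        fused = a + b_tail
        assert out[fused] > out[a] and out[fused] > out[b]


class TestPredictAmplicon:
    def test_subfragment_extraction(self):
        rng = np.random.default_rng(4)
        tpl = str(_seq(rng, 400))
        f = tpl[100:125]
        r = str(revcomp(tpl[275:300]))
        assert predict_amplicon(tpl, f, r) == tpl[100:300]

    def test_no_site_returns_none(self):
        rng = np.random.default_rng(5)
        tpl = str(_seq(rng, 400))
        assert predict_amplicon(tpl, "A" * 25, "C" * 25) is None


class TestExecuteEndToEnd:
    def test_pop_round_trip(self, pop_fixture, pop_protocol):
        report = execute(pop_protocol, seed=1)
        assert len(report.eluted) == 1
        assert report.eluted[0].dominant_product == str(pop_fixture.target)
        assert report.violations == []

    def test_mcad_all_24_variants_correct(self, azurin_spec, azurin_plan,
                                          azurin_protocol):
        report = execute(azurin_protocol, seed=1)
        assert len(report.eluted) == 24
        intended = {str(azurin_plan.nodes[nid].sequence)
                    for nid in azurin_plan.targets.values()}
        assert all(e.dominant_product in intended for e in report.eluted)
        # 24 distinct variants, no cross-contamination of dominant products
        assert len({e.dominant_product for e in report.eluted}) == 24
        assert report.violations == []

    def test_adjacency_violation_faults(self):
        layout = default_layout({"a": {}, "b": {}})
        b = ProtocolBuilder(layout)
        d1 = b.dispense("a")
        b.park(d1)
        d2 = b.dispense("b")
        p1 = b.positions[d1]
        bad_path = ((layout.reservoirs["b"].port,)
                    + tuple((p1[0], y) for y in range(1, p1[1] + 1)))
        # hand-crafted MOVE that drives d2 straight onto d1's column
        b.ops.append(DropletOp("MOVE", b.t, 1.0, droplet=d2, path=bad_path))
        prot = Protocol(layout, b.ops)
        with pytest.raises(SimulationFault, match="within one electrode"):
            execute(prot, seed=0)
        report = execute(prot, seed=0, strict=False)
        assert report.violations

    def test_split_below_two_units_faults(self):
        layout = default_layout({"a": {}})
        b = ProtocolBuilder(layout)
        d = b.dispense("a")  # one unit volume
        b.park(d)
        pos = b.positions[d]
        b.ops.append(DropletOp("SPLIT", b.t, 1.0, droplet=d, outs=("x", "y"),
                               positions=(pos, (pos[0] + 1, pos[1]))))
        with pytest.raises(SimulationFault, match="below two unit"):
            execute(Protocol(layout, b.ops), seed=0)

    def test_unknown_droplet_faults(self):
        layout = default_layout({"a": {}})
        ops = [DropletOp("TRASH", 0.0, 1.0, droplet="ghost")]
        with pytest.raises(SimulationFault, match="unknown droplet"):
            execute(Protocol(layout, ops), seed=0)


class TestDeterminismAndConservation:
    def test_identical_seed_identical_report(self, azurin_protocol):
        r1 = execute(azurin_protocol, seed=42)
        r2 = execute(azurin_protocol, seed=42)
        assert r1.to_json() == r2.to_json()

    def test_volume_conserved_on_random_compiled_protocols(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(360, 620))
            target = _seq(rng, n)
            core = ((n - 120) // 2, (n - 120) // 2 + 120)
            plan = plan_pop(target, core)
            prot = compile_protocol(plan)
            report = execute(prot, seed=int(rng.integers(0, 2**31)))
            ledger = volume_ledger(report)
            assert ledger["balanced"]
            assert report.violations == []
            assert ledger["live_nl"] == 0.0

    def test_dilution_consumes_exactly_six_units(self):
        prot = serial_dilution_routine(6)
        report = execute(prot, seed=0)
        assert report.reservoir_use_nl["diluent"] == pytest.approx(6 * 300.0)


class TestDilutionStatistics:
    def test_discrete_copy_mean_after_six_steps(self):
        initial = 1000
        expect = initial / 64
        vals = []
        prot = serial_dilution_routine(6, contents={"X" * 200: initial})
        for s in range(1000):
            rep = execute(prot, seed=s)
            vals.append(rep.eluted[0].composition["X" * 200])
        mean = np.mean(vals)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - expect) <= 3 * se

    def test_exact_partition_mode_halves_precisely(self):
        prot = serial_dilution_routine(6, contents={"X" * 200: 1000})
        rep = execute(prot, seed=0, stochastic_split=False)
        assert rep.eluted[0].composition["X" * 200] == pytest.approx(1000 / 64)
        assert rep.eluted[0].fold_dilution == pytest.approx(64.0)
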