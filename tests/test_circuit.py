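"""Forward model: CPE limits, circuit impedance, effective capacitance."""

import cmath

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eiscap import (
    CircuitParams,
    CPEParams,
    FrequencyGrid,
    circuit_impedance,
    cpe_impedance,
    dispersed_capacitance,
    effective_capacitance,
)
from eiscap.circuit import effective_capacitance_from

from conftest import SIMULATION_CASES

positive_f = st.floats(0.1, 1e5)


class TestCPE:
    def test_resistor_limit(self):
        # P=0 degenerates to an ideal resistor of 1/T ohm
        assert cpe_impedance(CPEParams(T=1.0, P=0.0), 123.4) == pytest.approx(1.0 + 0j)
        assert cpe_impedance(CPEParams(T=0.25, P=0.0), 7.0) == pytest.approx(4.0 + 0j)

    def test_capacitor_limit(self):
        # P=1 is an ideal capacitor: Z = -j/(w C), phase exactly -90 deg
        c, f = 2.2e-6, 50.0
        z = cpe_impedance(CPEParams(T=c, P=1.0), f)
        assert z == pytest.approx(-1j / (2 * np.pi * f * c), rel=1e-12)

    def test_polar_and_rectangular_forms_agree(self):
        # independent polar evaluation: |Z| = 1/(T w^P), phase = -P*90 deg
        T, P, f = 1e-6, 0.7, 10.0
        w = 2 * np.pi * f
        expected = (1 / (T * w**P)) * cmath.exp(-1j * P * cmath.pi / 2)
        z = cpe_impedance(CPEParams(T, P), f)
        assert z == pytest.approx(expected, rel=1e-12)
        assert np.degrees(cmath.phase(z)) == pytest.approx(-63.0, abs=1e-9)

    @given(T=st.floats(1e-8, 1e2), P=st.floats(0.0, 1.0), f=positive_f)
    def test_phase_is_minus_p_ninety(self, T, P, f):
        z = cpe_impedance(CPEParams(T, P), f)
        assert cmath.phase(z) == pytest.approx(-P * np.pi / 2, abs=1e-9)

    @given(T=st.floats(1e-8, 1e2), P=st.floats(0.01, 1.0), f=positive_f)
    def test_loglog_slope_is_minus_p(self, T, P, f):
        cpe = CPEParams(T, P)
        f2 = f * 1.5
        slope = (np.log(abs(cpe_impedance(cpe, f2))) - np.log(abs(cpe_impedance(cpe, f)))) / np.log(f2 / f)
        assert slope == pytest.approx(-P, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("freq", [0.0, -10.0])
    def test_nonpositive_frequency_rejected(self, freq):
        with pytest.raises(ValueError):
            cpe_impedance(CPEParams(1e-6, 0.5), freq)

    def test_invalid_cpe_params_rejected(self):
        with pytest.raises(ValueError):
            CPEParams(T=-1e-6, P=0.5)
        with pytest.raises(ValueError):
            CPEParams(T=1e-6, P=1.5)


class TestCircuitImpedance:
    def test_matches_bruteforce_complex_arithmetic(self, grid, rng):
        # oracle: plain per-frequency complex arithmetic, no shared code
        for _ in range(20):
            p = CircuitParams(
                ts=10 ** rng.uniform(-4, -1), ps=rng.uniform(0.05, 0.95),
                ce=10 ** rng.uniform(-7, -5.3), rd=10 ** rng.uniform(3, 4.3),
                td=10 ** rng.uniform(-7, -5.7), pd=rng.uniform(0.05, 0.95),
            )
            z = circuit_impedance(p, grid).z
            for k, f in enumerate(grid.frequencies_hz):
                w = 2 * cmath.pi * f
                zs = 1 / (p.ts * (1j * w) ** p.ps)
                zce = 1 / (1j * w * p.ce)
                zd = p.rd + 1 / (p.td * (1j * w) ** p.pd)
                expected = zs + zce * zd / (zce + zd)
                assert abs(z[k] - expected) / abs(expected) < 1e-12

    def test_simulation_case_a_shape(self, grid):
        spec = circuit_impedance(SIMULATION_CASES["a"][0], grid)
        assert np.all(spec.phase_deg > -90) and np.all(spec.phase_deg < 0)
        assert np.all(np.diff(spec.magnitude) < 0)  # |Z| falls with frequency

    def test_high_frequency_limit_vanishes(self):
        p = SIMULATION_CASES["a"][0]
        high = circuit_impedance(p, FrequencyGrid(np.array([1e10, 1e11, 1e12])))
        assert np.all(high.magnitude < 1e-2)  # bulk CPE decays as w**-0.3
        assert np.all(np.diff(high.magnitude) < 0)

    @given(
        ts=st.floats(1e-4, 1e-1), ps=st.floats(0.05, 0.95),
        ce=st.floats(1e-7, 5e-6), rd=st.floats(1e3, 2e4),
        td=st.floats(1e-7, 2e-6), pd=st.floats(0.05, 0.95),
        f=st.floats(10, 1000),
    )
    def test_passivity(self, ts, ps, ce, rd, td, pd, f):
        # any R/C/CPE network here must keep the phase in [-90, 0] deg
        p = CircuitParams(ts, ps, ce, rd, td, pd)
        spec = circuit_impedance(p, FrequencyGrid(np.array([f])))
        assert -90.0 <= spec.phase_deg[0] <= 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CircuitParams(ts=0.1, ps=0.3, ce=-1e-6, rd=1e4, td=1e-6, pd=0.7)
        with pytest.raises(ValueError):
            CircuitParams(ts=0.1, ps=1.3, ce=1e-6, rd=1e4, td=1e-6, pd=0.7)


class TestEffectiveCapacitance:
    def test_ideal_capacitor_limit(self):
        # Pd=1: Rd^0 = 1 so Cd = Td exactly, independent of Rd
        assert dispersed_capacitance(rd=123.0, td=3.3e-7, pd=1.0) == pytest.approx(3.3e-7, rel=1e-15)
        assert dispersed_capacitance(rd=9e9, td=3.3e-7, pd=1.0) == pytest.approx(3.3e-7, rel=1e-15)

    def test_pd_zero_is_singular(self):
        with pytest.raises(ValueError):
            dispersed_capacitance(rd=1e4, td=1e-6, pd=0.0)

    @pytest.mark.parametrize("case", list(SIMULATION_CASES))
    def test_printed_effective_capacitances(self, case):
        params, printed_uf = SIMULATION_CASES[case]
        assert round(effective_capacitance(params) * 1e6, 1) == printed_uf

    def test_zero_electrode_capacitance_limit(self):
        assert effective_capacitance_from(ce=0.0, rd=1e4, td=1e-6, pd=1.0) == pytest.approx(1e-6)

    def test_monotone_in_pd_and_ce(self):
        cefs = [effective_capacitance(SIMULATION_CASES[c][0]) for c in "abcde"]
        assert all(a < b for a, b in zip(cefs, cefs[1:]))
        pd_grid = np.linspace(0.7, 0.9, 9)
        cds = [dispersed_capacitance(1e4, 1e-6, pd) for pd in pd_grid]
        assert all(a < b for a, b in zip(cds, cds[1:]))

    @given(
        rd=st.floats(1e2, 1e6), td=st.floats(1e-8, 1e-5),
        pd=st.floats(0.3, 1.0), scale=st.floats(1.01, 3.0),
    )
    def test_strictly_increasing_in_td_and_rd(self, rd, td, pd, scale):
        base = dispersed_capacitance(rd, td, pd)
        assert dispersed_capacitance(rd, td * scale, pd) > base
        if pd < 1.0:
            assert dispersed_capacitance(rd * scale, td, pd) > base
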