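"""Langevin pulling: thermostat calibration, conservation, rupture events."""

import numpy as np
import pytest

from smfskit import _kernels
from smfskit.gomodel import build_contact_map, build_hamiltonian
from smfskit.pulling import (
    LangevinParams,
    PullingProtocol,
    SimEvent,
    SimTrace,
    detect_sim_events,
    run_pulling,
    sim_trace_to_force_extension,
    unfolding_order,
    write_sim_trace,
)
from smfskit.synthetic import ToyStructureConfig, generate_toy_structure

SIGMA = 3.6


def _empty_ham_args():
    return (
        np.empty((0, 2), dtype=np.int64), np.empty(0), 0.0,
        np.empty((0, 3), dtype=np.int64), np.empty(0), 0.0,
        np.empty((0, 4), dtype=np.int64), np.empty(0), 0.0, 0.0,
        np.empty((0, 2), dtype=np.int64), np.empty(0), np.empty(0),
        np.empty((0, 2), dtype=np.int64), 4.0,
    )


class TestThermostat:
    def test_tethered_bead_equipartition(self):
        """Spring-extension variance per axis equals kT/Kp (= 1 Å²)."""
        coords = np.zeros((1, 3))
        vels = np.zeros((1, 3))
        origin = np.zeros(3)
        axis = np.array([1.0, 0, 0])
        out = _kernels.run_langevin(
            coords, vels, *_empty_ham_args(),
            0, 0, origin, origin.copy(), axis,
            0.0, 1.0, 0.0,  # anchor off, pulling spring Kp=1, static
            0.005, 1.0, 1.0, 1_200_000, 5, 42,
        )
        snaps = out[4]
        disp = snaps[40_000:, 0, :]  # discard equilibration transient
        var = disp.var(axis=0)
        assert np.all(np.abs(var - 1.0) < 0.05)

    def test_kinetic_energy_equipartition(self, toy_domain, toy_hamiltonian):
        """Mean kinetic energy per bead is (3/2)kT within 2%."""
        structure, _ = toy_domain
        sim = run_pulling(
            structure, toy_hamiltonian, PullingProtocol(v_p=0.0),
            LangevinParams(kT_eps=1.0, n_steps=100_000, n_equil_steps=20_000, seed=2),
            record_every=10,
        )
        ke_per_bead = sim.kinetic_eps.mean() / structure.n_residues
        assert ke_per_bead == pytest.approx(1.5, rel=0.02)

    def test_zero_temperature_static_springs_relax_to_zero_force(
        self, toy_domain, toy_hamiltonian
    ):
        structure, _ = toy_domain
        sim = run_pulling(
            structure, toy_hamiltonian, PullingProtocol(v_p=0.0),
            LangevinParams(kT_eps=0.0, n_steps=20_000, n_equil_steps=5_000, seed=1),
            record_every=100,
        )
        assert np.abs(sim.pull_force_eps_A[-50:]).max() < 1e-3


class TestEnergyConservation:
    def test_no_thermostat_energy_drift(self, toy_domain, toy_hamiltonian):
        """gamma → 0 reduces BAOAB to velocity Verlet; secular drift is tiny."""
        structure, _ = toy_domain
        sim = run_pulling(
            structure, toy_hamiltonian,
            PullingProtocol(v_p=0.0, Kp=1e-30, K_anchor=1e-30),
            LangevinParams(kT_eps=0.5, gamma_per_tau=0.0, n_steps=50_000,
                           n_equil_steps=0, seed=3),
            record_every=10,
        )
        total = sim.potential_eps + sim.kinetic_eps
        slope = np.polyfit(np.arange(total.size), total, 1)[0]
        drift_per_1e4_steps = abs(slope) * 1e4 / 10  # 10 steps per record
        assert drift_per_1e4_steps < 1e-4


class TestPullingRun:
    def test_unfolding_produces_peaks_and_respects_contour(self, two_domain_pull):
        structure, sim = two_domain_pull
        contour = (structure.n_residues - 1) * SIGMA
        events = detect_sim_events(sim)
        assert len(events) >= 2
        assert sim.chain_extension_A.max() <= contour * 1.01
        assert sim.chain_extension_A.max() > 0.9 * contour

    def test_event_extension_change_below_domain_contour(self, two_domain_pull):
        structure, sim = two_domain_pull
        per_domain = {
            name: int(structure.domain_mask(name).sum())
            for name in structure.domain_ranges
        }
        for ev in detect_sim_events(sim):
            if ev.domain is not None:
                assert ev.domain_extension_change_A < per_domain[ev.domain] * SIGMA

    def test_fixed_seed_reproducible(self, small_two_domain):
        structure, ham = small_two_domain
        kw = dict(
            protocol=PullingProtocol(v_p=0.05),
            langevin=LangevinParams(kT_eps=0.5, n_steps=30_000,
                                    n_equil_steps=5_000, seed=123),
            record_every=50,
        )
        s1 = run_pulling(structure, ham, **kw)
        s2 = run_pulling(structure, ham, **kw)
        np.testing.assert_array_equal(s1.pull_force_eps_A, s2.pull_force_eps_A)
        np.testing.assert_array_equal(s1.chain_extension_A, s2.chain_extension_A)

    def test_weaker_domain_unfolds_first(self):
        """Scaling one domain's contact energies down makes it yield first."""
        cfg = ToyStructureConfig(
            n_domains=2, residues_per_domain=16, strand_length=5,
            contact_eps_scale={"SD1": 0.8},
        )
        structure, _ = generate_toy_structure(cfg)
        ham = build_hamiltonian(
            structure, build_contact_map(structure, method="calpha"),
            contact_eps_scale=cfg.contact_eps_scale,
        )
        v_p = 0.05
        n_steps = int((structure.n_residues - 1) * SIGMA / v_p / 0.005)
        firsts = []
        for seed in range(4):
            sim = run_pulling(
                structure, ham, PullingProtocol(v_p=v_p),
                LangevinParams(kT_eps=0.5, n_steps=n_steps,
                               n_equil_steps=20_000, seed=seed),
                record_every=100,
            )
            order = unfolding_order(detect_sim_events(sim))
            firsts.append(order[0] if order else None)
        assert firsts.count("SD1") >= 3

    def test_trace_conversion_units(self, two_domain_pull):
        _, sim = two_domain_pull
        trace = sim_trace_to_force_extension(sim)
        assert trace.source == "simulation"
        # 1 eps/A = 41.7 pN; 10 A pulled distance = 1 nm
        k = 1000
        assert trace.force_pN[k] == pytest.approx(sim.pull_force_eps_A[k] * 41.686,
                                                  rel=1e-3)
        assert trace.extension_nm[k] == pytest.approx(
            sim.pulled_distance_A[k] * 0.1, rel=1e-12
        )

    def test_sim_trace_io(self, two_domain_pull, tmp_path):
        _, sim = two_domain_pull
        path = tmp_path / "sim.tsv"
        write_sim_trace(sim, path)
        lines = path.read_text().splitlines()
        assert any("ext_SD1_A" in l for l in lines if l.startswith("#"))
        assert len([l for l in lines if not l.startswith("#")]) == sim.time_tau.size


class TestEventLogic:
    def _trace(self, force, domains=None):
        n = len(force)
        t = np.arange(1.0, n + 1)
        return SimTrace(
            time_tau=t,
            pull_force_eps_A=np.asarray(force, dtype=float),
            chain_extension_A=np.linspace(10, 50, n),
            pulled_distance_A=t * 0.5,
            domain_extension_A=domains or {},
            potential_eps=np.zeros(n),
            kinetic_eps=np.zeros(n),
            v_p=0.5,
            seed=0,
        )

    def test_monotonic_force_yields_no_events(self):
        sim = self._trace(np.linspace(0, 5, 200))
        assert detect_sim_events(sim) == []

    def test_order_by_first_attribution(self):
        events = [
            SimEvent(10.0, 1.0, 41.7, "A", 5.0),
            SimEvent(30.0, 1.5, 62.5, "B", 8.0),
            SimEvent(50.0, 1.2, 50.0, "A", 6.0),
        ]
        assert unfolding_order(events) == ["A", "B"]

    def test_domains_without_events_omitted(self):
        events = [SimEvent(30.0, 1.5, 62.5, "B", 8.0)]
        assert unfolding_order(events) == ["B"]


class TestProtocolValidation:
    def test_anchor_equals_pull_rejected(self):
        with pytest.raises(ValueError):
            PullingProtocol(anchor_residue=1, pull_residue=1).resolve(30)

    def test_default_is_c_terminal_anchor_n_terminal_pull(self):
        a, p = PullingProtocol().resolve(30)
        assert (a, p) == (29, 0)

    def test_timestep_bound(self):
        with pytest.raises(ValueError):
            LangevinParams(dt_tau=0.02)
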