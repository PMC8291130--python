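"""Network wiring, delay queues, synchronous evolution and the run loop."""

import numpy as np
import pytest

import popgrid as pg
from popgrid.network import DelayQueue


def make_lif_population(name="L", n_v=40, start=(0.5, 0.0), **kwargs):
    model = pg.archive_model("lif")
    grid = pg.build_grid((-1.0, 1.1, -1.0, 1.0), (n_v, 3))
    det = pg.generate_deterministic_matrix(model, grid)
    return pg.GridPopulation(name, model, grid, det_matrix=det,
                             start=start, **kwargs)


class TestValidation:
    def test_sign_rules(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("exc", 10.0), "EXCITATORY")
        net.add_node(pg.RatePopulation("inh", 10.0), "INHIBITORY")
        net.add_node(pg.RatePopulation("neu", 10.0), "NEUTRAL")
        net.add_node(make_lif_population("target"))
        # inhibitory node with negative efficacy: accepted
        net.connect(pg.ConnectionSpec("inh", "target", 1.0, -0.05))
        # neutral: either sign accepted
        net.connect(pg.ConnectionSpec("neu", "target", 1.0, -0.1))
        net.connect(pg.ConnectionSpec("neu", "target", 1.0, 0.1))
        # excitatory with negative efficacy: rejected, naming the connection
        with pytest.raises(pg.ConfigurationError, match="exc->target"):
            net.connect(pg.ConnectionSpec("exc", "target", 1.0, -0.1))
        with pytest.raises(pg.ConfigurationError, match="inh->target"):
            net.connect(pg.ConnectionSpec("inh", "target", 1.0, 0.05))

    def test_unknown_endpoint_rejected(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("a", 1.0))
        with pytest.raises(pg.ConfigurationError, match="ghost"):
            net.connect(pg.ConnectionSpec("a", "ghost", 1.0, 0.1))

    def test_duplicate_node_names_rejected(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("a", 1.0))
        with pytest.raises(pg.ConfigurationError, match="duplicate"):
            net.add_node(pg.RatePopulation("a", 2.0))


class TestEffectiveInputRate:
    @pytest.mark.parametrize("n_conn,activity,expected", [
        (10.0, 10.0, 100.0),
        (0.0, 50.0, 0.0),
        (2.5, 25.0, 62.5),
    ])
    def test_rate_is_weighted_activity(self, n_conn, activity, expected):
        conn = pg.ConnectionSpec("a", "b", n_conn, 0.1)
        assert pg.effective_input_rate(conn, activity) == expected


class TestDelayQueue:
    def test_zero_delay_is_one_step_lag(self):
        q = DelayQueue(0.0, 1e-3)
        assert q.read() == 0.0
        q.push(5.0)
        assert q.read() == 5.0
        q.push(7.0)
        assert q.read() == 7.0

    def test_integer_delay_transport(self):
        # delay d = k*dt delivers with k + 1 steps of transport
        q = DelayQueue(1e-3, 1e-3)
        pushes = [1.0, 2.0, 3.0, 4.0]
        reads = []
        for p in pushes:
            reads.append(q.read())
            q.push(p)
        assert reads == [0.0, 0.0, 1.0, 2.0]

    def test_fractional_delay_interpolates(self):
        q = DelayQueue(1.5e-3, 1e-3)
        reads = []
        for p in [10.0, 0.0, 0.0, 0.0, 0.0]:  # read-then-push, as the engine
            reads.append(q.read())
            q.push(p)
        # the impulse pushed at step 0 is read half at step 2, half at
        # step 3: an effective transport of delay/dt + 1 = 2.5 steps
        assert reads == pytest.approx([0.0, 0.0, 5.0, 5.0, 0.0])


class TestEvolve:
    def test_wrong_input_arity_reports_expected_count(self):
        net = pg.Network(1e-3)
        net.add_node(make_lif_population())
        net.add_external_input(pg.ExternalInputSpec("L", 1.0, 0.05))
        with pytest.raises(pg.ConfigurationError, match="expected 1"):
            net.evolve([])

    def test_subthreshold_node_is_silent(self):
        net = pg.Network(1e-3)
        net.add_node(make_lif_population())
        net.add_output("L")
        out = net.evolve([])
        assert out == [0.0]

    def test_runs_are_bit_identical(self):
        def build():
            net = pg.Network(1e-3)
            net.add_node(make_lif_population())
            net.add_node(pg.RatePopulation("inp", 900.0), "EXCITATORY")
            net.connect(pg.ConnectionSpec("inp", "L", 1.0, 0.1, delay=1e-3))
            return net

        n1, n2 = build(), build()
        for _ in range(100):
            n1.evolve([])
            n2.evolve([])
        assert np.array_equal(n1.nodes["L"].state.mass,
                              n2.nodes["L"].state.mass)
        assert n1.nodes["L"].activity == n2.nodes["L"].activity

    def test_impulse_transport_between_nodes(self):
        # source activity at step n first reaches the target's master input
        # at step n + 2 for delay = dt (queue transit + synchronous update)
        calls = []

        class Probe(pg.RatePopulation):
            is_grid = True

            def __init__(self):
                super().__init__("probe", 0.0)
                lif = make_lif_population("tmp")
                self.model = lif.model
                self.grid = lif.grid
                self.state = lif.state

            def step(self, inputs, dt):
                calls.append([r for r, _ in inputs])
                self.activity = 0.0
                return 0.0

        class Pulse(pg.RatePopulation):
            def __init__(self):
                super().__init__("pulse", 0.0)
                self.n = 0

            def step(self, inputs, dt):
                self.activity = 100.0 if self.n == 0 else 0.0
                self.n += 1
                return self.activity

        net = pg.Network(1e-3)
        net.add_node(Pulse(), "EXCITATORY")
        net.add_node(Probe())
        net.connect(pg.ConnectionSpec("pulse", "probe", 1.0, 0.05,
                                      delay=1e-3))
        for _ in range(5):
            net.evolve([])
        rates = [c[0] for c in calls]
        assert rates == [0.0, 0.0, 100.0, 0.0, 0.0]


class TestRunNetwork:
    def test_zero_length_run_is_empty(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("r", 5.0))
        res = pg.run_network(net, 0.0, rate_records={"r": 1e-3})
        assert res.times.size == 0
        # only the initial sample is recorded
        assert res.rates["r"].times == [0.0]

    def test_lif_mass_accumulates_at_equilibrium(self):
        pop = make_lif_population(start=(0.9, 0.0))
        net = pg.Network(1e-3)
        net.add_node(pop)
        res = pg.run_network(net, 3.0)
        assert np.all(res.activities["L"] == 0.0)
        # after three membrane time constants nearly all mass has settled
        # in the cells around the v = 0 fixed point
        eq_cell = pop.grid.cell_of_point(0.0, 0.0)
        centers = pop.grid.cell_centers_v()
        near_zero = np.abs(centers) < 3.5 * pop.grid.cell_width
        assert pop.state.mass[near_zero].sum() > 0.95
        assert pop.state.mass.argmax() in np.where(near_zero)[0]
        assert pop.state.mass[eq_cell] > 0.1
        assert abs(pop.state.total() - 1.0) < 1e-9

    def test_rate_record_interval(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("r", 5.0))
        res = pg.run_network(net, 0.01, rate_records={"r": 2e-3})
        assert res.rates["r"].times == pytest.approx(
            [0.0, 0.002, 0.004, 0.006, 0.008, 0.01])

    def test_interval_below_t_step_rejected(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("r", 5.0))
        with pytest.raises(pg.ConfigurationError, match="t_interval"):
            pg.run_network(net, 0.01, rate_records={"r": 1e-4})

    def test_density_record_on_rate_node_rejected(self):
        net = pg.Network(1e-3)
        net.add_node(pg.RatePopulation("r", 5.0))
        with pytest.raises(pg.ConfigurationError, match="non-grid"):
            pg.run_network(net, 0.01,
                           density_records={"r": (0.0, 0.01, 1e-3)})

    def test_avgv_activity_tracks_mean_potential(self):
        model = pg.archive_model("lif")
        grid = pg.build_grid((-1.0, 1.1, -1.0, 1.0), (42, 3))
        det = pg.generate_deterministic_matrix(model, grid)
        pop = pg.GridPopulation("L", model, grid, det_matrix=det,
                                activity_kind="avgv", start=(0.8, 0.0))
        net = pg.Network(1e-3)
        net.add_node(pop)
        res = pg.run_network(net, 3.0)
        avgv = res.activities["L"]
        # exponential decay toward 0 from ~0.8, within cell quantisation
        assert avgv[0] < 0.85
        assert np.all(np.diff(avgv) <= 1e-12)
        assert abs(avgv[-1]) < 0.1

    def test_t_step_must_be_multiple_of_node_dt(self):
        pop = make_lif_population()
        net = pg.Network(t_step=1.5e-3)
        net.add_node(pop)
        with pytest.raises(pg.ConfigurationError, match="integer multiple"):
            net.evolve([])

    def test_node_substeps_under_coarser_t_step(self):
        # t_step = 2 * node dt: the node takes two internal steps
        pop_a = make_lif_population("A", start=(0.9, 0.0))
        pop_b = make_lif_population("B", start=(0.9, 0.0))
        net_a = pg.Network(t_step=2e-3)
        net_a.add_node(pop_a)
        net_b = pg.Network(t_step=1e-3)
        net_b.add_node(pop_b)
        net_a.evolve([])
        net_b.evolve([])
        net_b.evolve([])
        assert np.allclose(pop_a.state.mass, pop_b.state.mass, atol=1e-15)
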