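"""Chordae network construction, rupture scenarios and truss equilibrium."""

import json

import numpy as np
import pytest

from mitralmech import chordae as ch
from mitralmech.errors import (
    NetworkSpecError,
    ScenarioError,
    UndefinedQuantityError,
)

from conftest import make_chain, make_v


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def test_default_network_counts(default_network):
    net = default_network
    assert len(net.pm_origin_nodes()) == 17
    counts = net.insertion_counts()
    assert counts[("PML_marginal", "APM")] + counts[("PML_marginal", "PPM")] == 13
    assert counts[("AML_strut", "APM")] + counts[("AML_strut", "PPM")] == 7
    spec = ch.default_table_spec()
    for key, n in spec.insertion_counts.items():
        assert counts[key] == n


def test_chord_paths_bounded_and_consistent(default_network):
    for cid, path in default_network.chord_paths.items():
        assert 1 <= len(path) <= 10
        pm = default_network.chord_pm(cid)
        for sid in path:
            seg = default_network.segments[sid]
            assert seg.pm == pm
            assert seg.rest_length > 0 and seg.area0 > 0


def test_segment_areas_by_group(default_network):
    areas = {s.group: s.area0 for s in default_network.segments.values()}
    assert areas["AML_strut"] == pytest.approx(2.05)
    assert areas["PML_marginal"] == pytest.approx(0.38)
    assert areas["PML_basal"] == pytest.approx(0.71)


def test_build_deterministic():
    a = ch.build_network(seed=123).to_json()
    b = ch.build_network(seed=123).to_json()
    assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)


def test_infeasible_spec_rejected():
    spec = ch.default_table_spec()
    bad = dict(spec.insertion_counts)
    bad[("AML_marginal", "APM")] = 1
    bad[("AML_strut", "APM")] = 1  # 2 insertions for 5 APM/AML origins
    with pytest.raises(NetworkSpecError):
        ch.NetworkSpec(origin_counts=spec.origin_counts, insertion_counts=bad)


def test_json_roundtrip(tmp_path, default_network):
    p = tmp_path / "net.json"
    default_network.to_json(p)
    again = ch.ChordaeNetwork.from_json(p)
    assert again.insertion_counts() == default_network.insertion_counts()
    assert set(again.segments) == set(default_network.segments)


# ---------------------------------------------------------------------------
# rupture scenarios
# ---------------------------------------------------------------------------


def test_control_scenario_empty(default_network):
    assert ch.scenario_segments(default_network, "control").removed_segments == frozenset()


def test_isolated_p2_targets_marginal_intermediate_only(default_network):
    sc = ch.scenario_segments(default_network, "isolated_P2")
    net = default_network
    removed_groups = {net.segments[s].group for s in sc.removed_segments}
    assert removed_groups <= {"PML_marginal", "PML_intermediate"}
    # every marginal/intermediate P2 segment is removed
    for sid, seg in net.segments.items():
        if seg.group in ("PML_marginal", "PML_intermediate") and seg.scallop == "P2":
            assert sid in sc.removed_segments


def test_scenario_severity_is_monotone(default_network):
    for other in ("P3", "P1"):
        iso = ch.scenario_segments(default_network, "isolated_P2").removed_segments
        part = ch.scenario_segments(default_network, f"partial_P2{other}").removed_segments
        tot = ch.scenario_segments(default_network, f"total_P2{other}").removed_segments
        assert iso <= part <= tot
        basal_removed = {
            s for s in tot if default_network.segments[s].group == "PML_basal"
        }
        assert basal_removed and not any(
            default_network.segments[s].group == "PML_basal" for s in part
        )


def test_unknown_scenario(default_network):
    with pytest.raises(ScenarioError):
        ch.scenario_segments(default_network, "isolated_P9")


# ---------------------------------------------------------------------------
# statics: closed-form cases
# ---------------------------------------------------------------------------


def control(net):
    return ch.RuptureScenario("control", frozenset())


def test_zero_load_zero_tension(default_network, ogden):
    load = ch.LoadCase(0.0, {})
    sol = ch.solve_static_tensions(default_network, control(default_network), load, ogden)
    assert max(sol.segment_tensions.values()) == 0.0
    assert max(np.abs(d).max() for d in sol.node_displacements.values()) == 0.0


def test_single_chord_axial_pull(ogden):
    net = make_chain(1)
    load = ch.LoadCase(0.0, {"tip": np.array([0.0, 0.0, 1.0])})
    sol = ch.solve_static_tensions(net, control(net), load, ogden)
    assert sol.segment_tensions["s1"] == pytest.approx(1.0, rel=1e-8)


def test_chain_refinement_invariance(ogden):
    """Splitting a straight chord into more collinear segments leaves its
    tension unchanged."""
    tensions = []
    for n in (1, 2):
        net = make_chain(n)
        load = ch.LoadCase(0.0, {"tip": np.array([0.0, 0.0, 2.0])})
        sol = ch.solve_static_tensions(net, control(net), load, ogden)
        tensions.append(sol.segment_tensions[f"s{n}"])
    assert tensions[1] == pytest.approx(tensions[0], rel=1e-6)


def test_v_truss_closed_form(stiff_ogden):
    """Symmetric two-chord V at half-angle 30 deg: each tension is
    F / (2 cos 30)."""
    F = 1.0
    net = make_v(theta_deg=30.0)
    load = ch.LoadCase(0.0, {"apex": np.array([0.0, 0.0, -F])})
    sol = ch.solve_static_tensions(net, control(net), load, stiff_ogden)
    expected = F / (2.0 * np.cos(np.radians(30.0)))
    # near-inextensible chords: deformed angle ~ reference angle
    assert sol.segment_tensions["s1"] == pytest.approx(expected, rel=1e-3)
    assert sol.segment_tensions["s2"] == pytest.approx(expected, rel=1e-3)
    # exact statics at the deformed angle
    apex = net.nodes["apex"].xyz + sol.node_displacements["apex"]
    cos_th = (net.nodes["o1"].xyz - apex)[2] / np.linalg.norm(net.nodes["o1"].xyz - apex)
    assert sol.segment_tensions["s1"] == pytest.approx(F / (2 * cos_th), rel=1e-7)


def test_parallel_chord_rupture_shifts_load(ogden):
    """Two chords sharing one insertion: rupturing one strictly increases
    the survivor's tension."""
    nodes = {
        "o1": ch.Node("o1", np.array([-2.0, 0.0, 10.0]), "pm_origin", "APM"),
        "o2": ch.Node("o2", np.array([2.0, 0.0, 10.0]), "pm_origin", "PPM"),
        "tip": ch.Node("tip", np.array([0.0, 0.0, 0.0]), "insertion", "leaflet"),
    }
    L = float(np.linalg.norm([2.0, 0.0, 10.0]))
    segs = {
        "s1": ch.Segment("s1", "o1", "tip", "PML_marginal", "P2", 1.0, L, "APM"),
        "s2": ch.Segment("s2", "o2", "tip", "PML_marginal", "P2", 1.0, L, "PPM"),
    }
    net = ch.ChordaeNetwork(nodes, segs, {"c1": ["s1"], "c2": ["s2"]})
    load = ch.LoadCase(0.0, {"tip": np.array([0.0, 0.0, -1.0])})
    t_both = ch.solve_static_tensions(net, control(net), load, ogden).segment_tensions
    sc = ch.RuptureScenario("isolated_P2", frozenset({"s2"}))
    sol = ch.solve_static_tensions(net, sc, load, ogden)
    assert sol.segment_tensions["s2"] == 0.0
    assert sol.segment_tensions["s1"] > t_both["s1"]


def test_disconnected_loaded_insertion_reported_slack(ogden):
    net = make_chain(2)
    sc = ch.RuptureScenario("isolated_P2", frozenset({"s1"}))
    load = ch.LoadCase(0.0, {"tip": np.array([0.0, 0.0, 1.0])})
    sol = ch.solve_static_tensions(net, sc, load, ogden)
    assert sol.slack_chords == ("chord",)
    assert all(t == 0.0 for t in sol.segment_tensions.values())


# ---------------------------------------------------------------------------
# statics: properties on the full network
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def default_solution(default_network, ogden):
    load = ch.loads_from_pressure(default_network, 120.0)
    sol = ch.solve_static_tensions(
        default_network, ch.RuptureScenario("control", frozenset()), load, ogden
    )
    return load, sol


def test_global_equilibrium(default_network, default_solution):
    load, sol = default_solution
    total = sum(load.insertion_loads.values())
    rx = ch.pm_reactions(default_network, sol)
    imbalance = np.abs(rx["APM"] + rx["PPM"] + total).max()
    assert imbalance <= 1e-6 * np.abs(total).max()


def test_tensions_nonnegative(default_solution):
    _, sol = default_solution
    assert min(sol.segment_tensions.values()) >= 0.0


def test_removed_segments_zero_tension(default_network, ogden):
    sc = ch.scenario_segments(default_network, "total_P2P1")
    load = ch.loads_from_pressure(default_network, 120.0, scenario=sc)
    sol = ch.solve_static_tensions(default_network, sc, load, ogden)
    assert all(sol.segment_tensions[sid] == 0.0 for sid in sc.removed_segments)


def test_pm_distribution_rows_sum_to_100(default_network, default_solution):
    _, sol = default_solution
    table = ch.pm_force_distribution(default_network, sol)
    for pm in ("APM", "PPM"):
        assert table.loc[pm].sum() == pytest.approx(100.0, abs=0.1)


def test_pm_distribution_single_pm(ogden):
    net = make_chain(1)
    load = ch.LoadCase(0.0, {"tip": np.array([0.0, 0.0, 1.0])})
    sol = ch.solve_static_tensions(net, ch.RuptureScenario("control", frozenset()), load, ogden)
    table = ch.pm_force_distribution(net, sol)
    assert table.loc["APM", "PML_marginal"] == pytest.approx(100.0)
    # a present-but-slack PM is an error
    with pytest.raises(UndefinedQuantityError):
        ch.pm_force_distribution(
            net,
            ch.TensionSolution({"s1": 0.0}, {}, True, 0.0),
        )


def test_group_force_single_chord(ogden):
    net = make_chain(1)
    load = ch.LoadCase(0.0, {"tip": np.array([0.0, 0.0, 2.0])})
    sol = ch.solve_static_tensions(net, ch.RuptureScenario("control", frozenset()), load, ogden)
    vec, mag = ch.group_force(net, sol, "PML_marginal")
    assert mag == pytest.approx(2.0, rel=1e-8)
    assert vec[2] == pytest.approx(2.0, rel=1e-8)  # pull directed toward leaflet


def test_group_force_mirrored_cancellation(stiff_ogden):
    net = make_v(theta_deg=40.0)
    load = ch.LoadCase(0.0, {"apex": np.array([0.0, 0.0, -1.0])})
    sol = ch.solve_static_tensions(net, ch.RuptureScenario("control", frozenset()), load, stiff_ogden)
    vec, mag = ch.group_force(net, sol, "PML_marginal")
    t_sum = sum(sol.segment_tensions.values())
    assert abs(vec[0]) < 1e-8  # mirror components cancel
    assert mag < t_sum


def test_small_strain_load_scaling(stiff_ogden, default_network):
    """With near-inextensible chords (small strains), tensions scale
    linearly with the applied load within 1%."""
    base = ch.loads_from_pressure(default_network, 10.0)
    sc = ch.RuptureScenario("control", frozenset())
    sols = {}
    for s in (0.5, 1.0, 2.0):
        load = ch.LoadCase(
            10.0 * s, {k: v * s for k, v in base.insertion_loads.items()}
        )
        sols[s] = ch.solve_static_tensions(default_network, sc, load, stiff_ogden)
    ref = sols[1.0].segment_tensions
    big = {k: v for k, v in ref.items() if v > 1e-6}
    for s in (0.5, 2.0):
        for k in big:
            assert sols[s].segment_tensions[k] == pytest.approx(s * ref[k], rel=1e-2)


def test_compare_scenarios_control_baseline(default_network, ogden):
    load = ch.loads_from_pressure(default_network, 120.0)
    scenarios = [
        ch.RuptureScenario("control", frozenset()),
        ch.scenario_segments(default_network, "isolated_P2"),
    ]
    df = ch.compare_scenarios(default_network, scenarios, load, ogden)
    for g in ch.GROUPS:
        assert df.loc["control", f"{g}_pct_change"] == pytest.approx(0.0, abs=1e-9)
    # rupture sheds the removed groups' force
    assert df.loc["isolated_P2", "PML_marginal"] < df.loc["control", "PML_marginal"]
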