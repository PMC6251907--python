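import numpy as np
import pytest

from mitralmech import chordae, constitutive, synthetic


@pytest.fixture(scope="session")
def leaflet_params():
    return constitutive.EXAMPLE_LEAFLET_PARAMS


@pytest.fixture(scope="session")
def ogden():
    return constitutive.EXAMPLE_OGDEN_PARAMS


@pytest.fixture(scope="session")
def stiff_ogden():
    # near-inextensible chords: keeps geometry changes negligible where a
    # test compares against rigid-geometry statics
    return constitutive.OgdenParams(terms=((5000.0, 2.0),))


@pytest.fixture(scope="session")
def default_network():
    return chordae.build_network(seed=0)


@pytest.fixture(scope="session")
def control_record_truth():
    return synthetic.gen_waveforms_with_truth()


@pytest.fixture(scope="session")
def control_record(control_record_truth):
    return control_record_truth[0]


def make_chain(n_segments: int, length: float = 10.0, area: float = 1.0):
    """A single straight chord along +z split into n collinear segments."""
    nodes = {"org": chordae.Node("org", np.array([0.0, 0.0, 0.0]), "pm_origin", "APM")}
    segs = {}
    path = []
    prev = "org"
    for k in range(1, n_segments + 1):
        nid = "tip" if k == n_segments else f"b{k}"
        role = "insertion" if k == n_segments else "branch"
        nodes[nid] = Node = chordae.Node(
            nid, np.array([0.0, 0.0, length * k / n_segments]), role, "leaflet"
        )
        sid = f"s{k}"
        segs[sid] = chordae.Segment(
            sid, prev, nid, "PML_marginal", "P2", area, length / n_segments, "APM"
        )
        path.append(sid)
        prev = nid
    return chordae.ChordaeNetwork(nodes, segs, {"chord": path})


def make_v(theta_deg: float = 30.0, leg: float = 10.0, area: float = 1.0):
    """Two chords meeting at a loaded apex, each at theta from the apex load
    axis (-z): the classic symmetric V truss."""
    th = np.radians(theta_deg)
    x = leg * np.sin(th)
    z = leg * np.cos(th)
    nodes = {
        "o1": chordae.Node("o1", np.array([-x, 0.0, z]), "pm_origin", "APM"),
        "o2": chordae.Node("o2", np.array([x, 0.0, z]), "pm_origin", "PPM"),
        "apex": chordae.Node("apex", np.array([0.0, 0.0, 0.0]), "insertion", "leaflet"),
    }
    segs = {
        "s1": chordae.Segment("s1", "o1", "apex", "PML_marginal", "P2", area, leg, "APM"),
        "s2": chordae.Segment("s2", "o2", "apex", "PML_marginal", "P2", area, leg, "PPM"),
    }
    return chordae.ChordaeNetwork(nodes, segs, {"c1": ["s1"], "c2": ["s2"]})
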