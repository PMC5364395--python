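import numpy as np
import pytest

from navtopo.network import PrimalNetwork, StreetSegment, build_dual_graph


def make_chain(n: int, lengths=None) -> PrimalNetwork:
    """n segments in a line: S0 - S1 - ... - S(n-1), joined end to end."""
    lengths = lengths or [50.0] * n
    segs = [
        StreetSegment(id=f"S{i}", name=f"Chain St {i}",
                      endpoint_junctions=(f"j{i}", f"j{i + 1}"), length=lengths[i])
        for i in range(n)
    ]
    return PrimalNetwork.from_segments(segs, boundary_segment_ids=["S0", f"S{n - 1}"])


def make_star(n_arms: int = 6) -> PrimalNetwork:
    """One junction with n incident segments (dual graph is K_n)."""
    segs = [
        StreetSegment(id=f"A{i}", name=f"Arm {i}",
                      endpoint_junctions=("center", f"out{i}"), length=40.0)
        for i in range(n_arms)
    ]
    return PrimalNetwork.from_segments(segs)


def make_hub() -> PrimalNetwork:
    """A central segment with three streets at each end: its dual degree is 6."""
    segs = [StreetSegment(id="HUB", name="High St", endpoint_junctions=("jw", "je"),
                          length=80.0)]
    for i in range(3):
        segs.append(StreetSegment(id=f"W{i}", name=f"West {i}",
                                  endpoint_junctions=("jw", f"w{i}"), length=30.0))
        segs.append(StreetSegment(id=f"E{i}", name=f"East {i}",
                                  endpoint_junctions=("je", f"e{i}"), length=30.0))
    return PrimalNetwork.from_segments(segs)


def make_grid(rows: int = 4, cols: int = 4) -> PrimalNetwork:
    """Full lattice: every inter-junction stretch is one segment."""
    segs = []
    for r in range(rows):
        for c in range(cols - 1):
            segs.append(StreetSegment(id=f"h{r}_{c}", name=f"Row {r}",
                                      endpoint_junctions=(f"j{r}_{c}", f"j{r}_{c + 1}"),
                                      length=50.0))
    for c in range(cols):
        for r in range(rows - 1):
            segs.append(StreetSegment(id=f"v{c}_{r}", name=f"Col {c}",
                                      endpoint_junctions=(f"j{r}_{c}", f"j{r + 1}_{c}"),
                                      length=50.0))
    boundary = [s.id for s in segs
                if any(j.split("_")[0] in (f"j0", f"j{rows - 1}") or
                       j.endswith(f"_0") or j.endswith(f"_{cols - 1}")
                       for j in s.endpoint_junctions)]
    return PrimalNetwork.from_segments(segs, boundary_segment_ids=boundary)


def random_connected_network(rng: np.random.Generator, n_segments: int) -> PrimalNetwork:
    """Random primal network whose dual graph is connected (rejection sampled)."""
    for _ in range(200):
        n_j = int(rng.integers(max(3, n_segments // 2), n_segments + 2))
        segs = []
        for i in range(n_segments):
            a, b = rng.choice(n_j, size=2, replace=False)
            segs.append(StreetSegment(id=f"S{i}", name=f"S{i}",
                                      endpoint_junctions=(f"j{a}", f"j{b}"),
                                      length=float(rng.uniform(20, 100))))
        net = PrimalNetwork.from_segments(segs)
        try:
            build_dual_graph(net)
        except Exception:
            continue
        return net
    raise RuntimeError("could not sample a connected network")


@pytest.fixture
def chain3():
    return make_chain(3, lengths=[10.0, 20.0, 30.0])


@pytest.fixture
def chain5():
    return make_chain(5)


@pytest.fixture
def star6():
    return make_star(6)


@pytest.fixture
def hub():
    return make_hub()


@pytest.fixture
def grid44():
    return make_grid(4, 4)
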