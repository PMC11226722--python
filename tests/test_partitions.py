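"""Degree partitions of BS_b and of explicit edge lists."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from bsbnet.partitions import (
    EdgePartition,
    GridParams,
    VertexPartition,
    bsb_edge_partition,
    bsb_order_size,
    bsb_vertex_partition,
    partition_from_edges,
    partitions_to_json,
    read_edge_list,
    validate,
)


@pytest.mark.parametrize(
    "m, n, order, size",
    [(1, 1, 12, 12), (5, 5, 220, 300), (1, 2, 22, 24), (8, 8, 544, 768)],
)
def test_order_size(m, n, order, size):
    assert bsb_order_size(GridParams(m, n)) == (order, size)


@pytest.mark.parametrize("m, n", [(0, 1), (1, 0), (-3, 2)])
def test_grid_params_domain(m, n):
    with pytest.raises(ValueError):
        GridParams(m, n)


def test_grid_params_type():
    with pytest.raises(TypeError):
        GridParams(1.5, 2)


@pytest.mark.parametrize(
    "m, n, expected, total",
    [
        (1, 1, {(1, 3): 5, (2, 3): 4, (3, 3): 3}, 12),
        (5, 5, {(1, 3): 21, (2, 3): 36, (3, 3): 243}, 300),
        (1, 2, {(1, 3): 7, (2, 3): 8, (3, 3): 9}, 24),
    ],
)
def test_edge_partition(m, n, expected, total):
    ep = bsb_edge_partition(GridParams(m, n))
    assert ep.entries == expected
    assert ep.size == total == sum(expected.values())


@pytest.mark.parametrize(
    "m, n, mode, expected",
    [
        (1, 1, "consistent", {1: 5, 2: 2, 3: 5}),
        (2, 2, "consistent", {1: 9, 2: 6, 3: 25}),
        # printed counts: deg-3 class 2mn - 2(m+n-1) vanishes at m = n = 1
        (1, 1, "as_printed", {1: 5, 2: 3, 3: 0}),
    ],
)
def test_vertex_partition(m, n, mode, expected):
    vp = bsb_vertex_partition(GridParams(m, n), mode=mode)
    assert vp.entries == expected
    assert vp.order == 8 * m * n + 2 * m + 2 * n  # declared order in both modes


def test_vertex_partition_unknown_mode():
    with pytest.raises(ValueError, match="mode"):
        bsb_vertex_partition(GridParams(1, 1), mode="nope")


def test_consistent_partitions_validate():
    p = GridParams(3, 3)
    report = validate(bsb_vertex_partition(p), bsb_edge_partition(p))
    assert report.ok and report.messages == ()


def test_as_printed_partitions_fail_handshake():
    """The printed vertex counts give sum(d * n_d) = 6mn + 5, not 24mn."""
    p = GridParams(3, 3)
    vp = bsb_vertex_partition(p, mode="as_printed")
    assert vp.degree_sum() == 6 * 9 + 5
    report = validate(vp, bsb_edge_partition(p))
    assert not report.handshake_ok
    assert not report.order_ok
    assert not report.ok and report.messages


def test_validate_empty_partitions_vacuously_ok():
    report = validate(VertexPartition({}, 0), EdgePartition({}, 0))
    assert report.ok


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.integers(1, 30), st.integers(1, 30))
def test_bsb_partition_identities(m, n):
    """Size 12mn, order 8mn+2m+2n, handshake sum 24mn, full validation."""
    p = GridParams(m, n)
    ep = bsb_edge_partition(p)
    vp = bsb_vertex_partition(p)
    assert sum(ep.entries.values()) == 12 * m * n
    assert sum(vp.entries.values()) == 8 * m * n + 2 * m + 2 * n
    assert vp.degree_sum() == 24 * m * n
    assert validate(vp, ep).ok


@pytest.mark.parametrize(
    "edges, vp_expected, ep_expected",
    [
        ([("a", "b"), ("b", "c")], {1: 2, 2: 1}, {(1, 2): 2}),
        ([("a", "b"), ("b", "c"), ("c", "a")], {2: 3}, {(2, 2): 3}),
        (
            [("hub", f"leaf{i}") for i in range(4)],
            {1: 4, 4: 1},
            {(1, 4): 4},
        ),
    ],
)
def test_partition_from_edges(edges, vp_expected, ep_expected):
    vp, ep = partition_from_edges(edges)
    assert vp.entries == vp_expected
    assert ep.entries == ep_expected
    assert validate(vp, ep).ok


def test_partition_from_edges_rejects_self_loop():
    with pytest.raises(ValueError, match="self-loop"):
        partition_from_edges([("a", "a")])


@pytest.mark.parametrize("dup", [("a", "b"), ("b", "a")])
def test_partition_from_edges_rejects_duplicates(dup):
    with pytest.raises(ValueError, match="duplicate"):
        partition_from_edges([("a", "b"), dup])


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=40))
def test_edge_orientation_is_canonical(pairs):
    """Reversing every input pair leaves both partitions unchanged."""
    edges, seen = [], set()
    for a, b in pairs:
        if a == b or frozenset((a, b)) in seen:
            continue
        seen.add(frozenset((a, b)))
        edges.append((f"v{a}", f"v{b}"))
    vp, ep = partition_from_edges(edges)
    vp_rev, ep_rev = partition_from_edges([(v, u) for u, v in edges])
    assert vp == vp_rev
    assert ep.entries == ep_rev.entries and ep.size == ep_rev.size


def test_edge_list_io_and_json(tmp_path):
    path = tmp_path / "edges.txt"
    path.write_text("# a comment\na b\n\nb c\n")
    edges = read_edge_list(path)
    assert edges == [("a", "b"), ("b", "c")]
    vp, ep = partition_from_edges(edges)
    payload = json.loads(partitions_to_json(vp, ep))
    assert payload["vertex_partition"] == {"1": 2, "2": 1}
    assert payload["edge_partition"] == [{"du": 1, "dv": 2, "count": 2}]
    assert payload["order"] == 3 and payload["size"] == 2


def test_edge_list_bad_line(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("a b c\n")
    with pytest.raises(ValueError, match="two vertex tokens"):
        read_edge_list(path)
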