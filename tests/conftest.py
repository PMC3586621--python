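import numpy as np
import pytest
from hypothesis import settings

from skinktrace.alignment import AlignedSequenceSet
from skinktrace.assignment import NativeHaplotype, ReferencePanel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def tiny_alignment() -> AlignedSequenceSet:
    return AlignedSequenceSet(
        (
            ("s1", "ACGTACGTACGT"),
            ("s2", "ACGTACGTACGT"),
            ("s3", "ACGTTCGTACGA"),
            ("s4", "ACGTTCGTACGA"),
            ("s5", "TTGTACGAACGT"),
        )
    )


def _mutate(seq: str, positions: dict[int, str]) -> str:
    chars = list(seq)
    for pos, base in positions.items():
        chars[pos] = base
    return "".join(chars)


@pytest.fixture
def toy_panel() -> ReferencePanel:
    """Two native clades (~10% apart) plus an established set matching the
    first clade's first locality, on 60 bp sequences."""
    rng = np.random.default_rng(42)
    bases = "ACGT"
    root = "".join(rng.choice(list(bases), 60))
    cladeA = root
    cladeB = _mutate(root, {i: bases[(bases.index(root[i]) + 1) % 4] for i in range(0, 24, 4)})
    a_loc1 = cladeA
    a_loc2 = _mutate(cladeA, {40: "A" if cladeA[40] != "A" else "G",
                              44: "A" if cladeA[44] != "A" else "G"})
    natives = (
        NativeHaplotype("A1", a_loc1, "Tenterfield", "clade-A"),
        NativeHaplotype("A2", a_loc2, "Armidale", "clade-A"),
        NativeHaplotype("B1", cladeB, "Sydney", "clade-B"),
        NativeHaplotype(
            "B2",
            _mutate(cladeB, {50: "C" if cladeB[50] != "C" else "T"}),
            "Brisbane",
            "clade-B",
        ),
    )
    established = (("NZ1", a_loc1),)
    return ReferencePanel(
        native_haplotypes=natives,
        established_haplotypes=established,
        established_localities=frozenset({"Auckland", "Tauranga"}),
        source_region_label="Tenterfield",
    )


def random_additive_metric(n: int, rng: np.random.Generator):
    """Random unrooted binary tree metric: leaf labels L0..L{n-1}, distances
    are exact tree path lengths.  Used as the NJ consistency oracle."""
    dist = {i: {i: 0.0} for i in range(n)}  # cluster -> {leaf: distance}
    D = np.zeros((n, n))
    active = list(range(n))
    nxt = n
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.05, 0.5, 2)
        for leaf_a, da in dist[a].items():
            for leaf_b, db in dist[b].items():
                D[leaf_a, leaf_b] = D[leaf_b, leaf_a] = da + la + db + lb
        dist[nxt] = {leaf: d + la for leaf, d in dist[a].items()}
        dist[nxt].update({leaf: d + lb for leaf, d in dist[b].items()})
        del dist[a], dist[b]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    a, b = active
    bridge = rng.uniform(0.05, 0.5)
    for leaf_a, da in dist[a].items():
        for leaf_b, db in dist[b].items():
            D[leaf_a, leaf_b] = D[leaf_b, leaf_a] = da + db + bridge
    labels = tuple(f"L{i}" for i in range(n))
    return labels, D
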