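import numpy as np
import pytest

from stretchpore.synthetic import CompositionSpec, build_frame, default_box

SMALL_CHOL = CompositionSpec(24, 16, 600, label="chol40")
SMALL_PURE = CompositionSpec(36, 0, 700, label="pure")


def make_frame(comp=SMALL_CHOL, l_x=4.0, thickness=3.6, tilt_sd=10.0,
               interdigitation=0.0, seed=0, **kw):
    box = default_box(comp, l_x=l_x, thickness=max(thickness, 3.0))
    return build_frame(comp, box, thickness, tilt_sd=tilt_sd,
                       interdigitation_depth=interdigitation, seed=seed, **kw)


@pytest.fixture(scope="session")
def chol_frame():
    return make_frame(seed=11)


@pytest.fixture(scope="session")
def pure_frame():
    return make_frame(SMALL_PURE, seed=12)


# ---------------------------------------------------------------------------
# independent brute-force oracles (kept free of the package's graph code)
# ---------------------------------------------------------------------------

def brute_force_adjacency(pos, box, cutoff, periodic=(True, True, True)):
    """O(n^2) adjacency via explicit minimum-image over all 27 image offsets."""
    n = len(pos)
    offsets = []
    for ox in ((-1, 0, 1) if periodic[0] else (0,)):
        for oy in ((-1, 0, 1) if periodic[1] else (0,)):
            for oz in ((-1, 0, 1) if periodic[2] else (0,)):
                offsets.append([ox * box[0], oy * box[1], oz * box[2]])
    offsets = np.asarray(offsets)
    diff = pos[:, None, :] - pos[None, :, :]
    d2min = np.full((n, n), np.inf)
    for off in offsets:
        d2 = np.sum((diff + off) ** 2, axis=-1)
        d2min = np.minimum(d2min, d2)
    adj = d2min <= cutoff ** 2
    np.fill_diagonal(adj, False)
    return adj


def brute_force_components(pos, box, cutoff, periodic=(True, True, True)):
    """Component label per point, via union-find on the brute-force adjacency."""
    adj = brute_force_adjacency(np.asarray(pos), box, cutoff, periodic)
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in np.nonzero(adj[i])[0]:
            ri, rj = find(i), find(int(j))
            if ri != rj:
                parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def canonical_partition(labels):
    """Frozen set-of-frozensets representation for partition comparison."""
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return frozenset(frozenset(g) for g in groups.values())
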