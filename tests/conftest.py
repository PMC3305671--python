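import numpy as np
import pytest

import mosaicstripes as ms


@pytest.fixture(scope="session")
def rendered_cornea():
    """One noise-free rendered cornea shared across tests (deterministic)."""
    ring = ms.simulate_clone_ring(12, 0.5, width_model="dirichlet", seed=11)
    return ms.render_cornea(ring, image_size=512, seed=11)


def profile_from_classes(classes):
    """Uniform-angle circular profile from a 0/1 class sequence."""
    classes = np.asarray(classes, dtype=np.uint8)
    n = classes.size
    return ms.CircularProfile(angles=np.arange(n) * (2 * np.pi / n), classes=classes)


def linear_rle_oracle(classes):
    """Independent wrap-aware run extraction: rotate the profile so it
    starts at a class transition, then do a plain linear scan.

    Returns the multiset of (is_positive, width) pairs with widths as
    sample-count fractions (valid for uniformly spaced profiles).
    """
    classes = list(int(c) for c in classes)
    n = len(classes)
    trans = [i for i in range(n) if classes[i] != classes[i - 1]]
    if not trans:
        return [(bool(classes[0]), 1.0)]
    k = trans[0]
    rot = classes[k:] + classes[:k]
    runs = []
    start = 0
    for i in range(1, n + 1):
        if i == n or rot[i] != rot[start]:
            runs.append((bool(rot[start]), (i - start) / n))
            start = i
    return runs
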