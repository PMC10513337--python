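"""Shared fixtures: synthetic sections and desk-scale configs.

Expensive artifacts (sections, trained models) are session-scoped so the
whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from culmvb import morphometry as mm
from culmvb import synthgen as sg


@pytest.fixture(scope="session")
def internode2_section():
    """Default internode-2 section with ground truth (seed 1)."""
    arch = sg.make_archetype(2)
    return sg.generate_section(arch, seed=1)


@pytest.fixture(scope="session")
def internode2_records(internode2_section):
    _, gt = internode2_section
    return mm.measure_all(gt.instance_mask, gt.tissue_frame, exclude_border=True)


@pytest.fixture(scope="session")
def small_sections():
    """Narrow sections of all four internodes for fast training tests."""
    out = []
    for i, iid in enumerate((2, 12, 22, 32)):
        arch = sg.make_archetype(iid)
        out.append(sg.generate_section(arch, seed=10 + i, tangential_width=512))
    return out


def random_blob_mask(rng: np.random.Generator, shape=(100, 100), n=4) -> np.ndarray:
    """Union of random ellipses — irregular but realistic test regions."""
    m = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(n):
        r0 = rng.integers(12, shape[0] - 12)
        c0 = rng.integers(12, shape[1] - 12)
        a, b = rng.uniform(3, 12, 2)
        th = rng.uniform(0, np.pi)
        x, y = xx - c0, yy - r0
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        m |= (u / a) ** 2 + (v / b) ** 2 <= 1
    return m
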