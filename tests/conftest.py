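from __future__ import annotations

import numpy as np
import pytest

from seedscan import Component, FieldSpec, render_field
from seedscan.segmentation import BinaryMask, label_components


def mask_to_components(mask: np.ndarray) -> list[Component]:
    return label_components(BinaryMask(mask))


def single_component(mask: np.ndarray) -> Component:
    comps = mask_to_components(mask)
    assert len(comps) == 1, f"expected one component, got {len(comps)}"
    return comps[0]


@pytest.fixture(scope="session")
def mixed_field():
    """A rendered field with all four object classes and its ground truth."""
    spec = FieldSpec(n_singles=20, n_pairs=5, n_scratches=3, n_debris=5, rng_seed=202)
    image, truths = render_field(spec)
    return spec, image, truths


def nearest_truth(record, truths):
    """Ground-truth object closest to a measured component's centroid."""
    return min(
        truths,
        key=lambda t: (record.centroid[0] - t.center[0]) ** 2
        + (record.centroid[1] - t.center[1]) ** 2,
    )
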