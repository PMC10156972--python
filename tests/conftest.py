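import numpy as np
import pytest

from octamorph import (NetworkSpec, VesselMask, build_graph, gen_network_image,
                       label_branches, make_sectors, skeletonize)

SCALE = 6.0 / 304


@pytest.fixture(scope="session")
def network_truth():
    """One seeded synthetic vessel network with its clean mask."""
    img, truth = gen_network_image(NetworkSpec(seed=11))
    return img, truth


@pytest.fixture(scope="session")
def network_graph(network_truth):
    """Skeleton graph of the clean network mask, sector-labelled."""
    _, truth = network_truth
    mask = VesselMask(truth.mask, SCALE)
    graph = build_graph(skeletonize(mask))
    sectors = make_sectors(mask.shape, None, 6.0, SCALE, "OD")
    label_branches(graph.branches, sectors)
    return graph, sectors, mask
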