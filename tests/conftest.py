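import numpy as np
import pytest

import airwaynav as an


@pytest.fixture(scope="session")
def phantom3():
    """Noiseless 3-generation phantom on a 96^3 grid, shared across tests."""
    spec = an.generate_phantom_spec(levels=3, seed=1, jitter_sd=3.0)
    vol = an.rasterize_phantom(spec, shape=(96, 96, 96))
    return spec, vol


@pytest.fixture(scope="session")
def segmented3(phantom3):
    spec, vol = phantom3
    mask = an.segment_airways(vol)
    return spec, vol, mask


@pytest.fixture(scope="session")
def tree3(segmented3):
    """Extracted airway tree of the shared phantom plus its ground truth."""
    spec, vol, mask = segmented3
    skel = an.skeletonize(mask)
    graph = an.build_skeleton_graph(skel, mask.affine)
    graph = an.extend_leaf_tips(graph, mask.mask, mask.affine)
    graph = an.prune_spurs(graph, 3.0, mask=mask.mask, affine=mask.affine)
    tree = an.direct_from_root(graph, an.world_from_voxel(vol, mask.seed))
    return tree, an.truth_tree(spec)


@pytest.fixture()
def straight_tube_volume():
    """Single vertical branch (radius 3 mm) rasterized at 0.8 mm spacing."""
    spec = an.generate_phantom_spec(levels=1, seed=0, trachea_length_mm=50.0,
                                    trachea_radius_mm=3.0)
    vol = an.rasterize_phantom(spec, shape=(72, 72, 88), spacing=(0.8, 0.8, 0.8))
    return spec, vol
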