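import numpy as np
import pytest

from pcquant.segment import DetectionParams, detect
from pcquant.synth import SceneParams, gen_uptake_scene

# Default detection parameter sets used for synthetic uptake scenes: the cell
# channel needs a size filter large enough to ignore stray pixels but far
# below the smallest cell; protocells (~2 µm, ~12 px at 0.5 µm/px) get a
# smaller one.
CELL_PARAMS = dict(min_object_voxels=20)
PC_PARAMS = dict(min_object_voxels=4)


@pytest.fixture(scope="session")
def uptake_scene():
    """One default uptake scene (50 cells, 40% loaded, SNR 20) with truth."""
    return gen_uptake_scene(SceneParams(seed=7))


@pytest.fixture(scope="session")
def uptake_detections(uptake_scene):
    """Detections on both channels of the default scene."""
    stack, truth = uptake_scene
    cell_labels, cell_recs = detect(stack, "cells", DetectionParams(**CELL_PARAMS))
    pc_labels, pc_recs = detect(stack, "pcs", DetectionParams(**PC_PARAMS))
    return cell_labels, cell_recs, pc_labels, pc_recs
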