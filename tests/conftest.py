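import json

import numpy as np
import pytest

from agnor_screen import quantify, synthetic_data as sd


@pytest.fixture(scope="session")
def group_params():
    return sd.default_group_params()


@pytest.fixture(scope="session")
def rendered_slide(tmp_path_factory):
    """One noisy rendered slide: image, ground truth, boxes, truth-by-label."""
    rng = sd.stream_rng(11, "fixture")
    counts = [3, 5, 2, 4, 1, 6, 2, 3]
    scene = sd.make_scene(counts, rng, n_overlapping_pairs=1, n_artifacts=1)
    image, gt, labelme = sd.render_smear(scene, seed=11)
    path = tmp_path_factory.mktemp("slide") / "slide.labelme.json"
    path.write_text(json.dumps(labelme))
    boxes = quantify.load_boxes(path)
    truth = {n["nucleus_id"]: n["nor_count"] for n in gt["nuclei"]}
    return {
        "image": image,
        "scene": scene,
        "ground_truth": gt,
        "labelme": labelme,
        "boxes": boxes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_cohort(group_params):
    return sd.simulate_cohort(group_params, n_per_group=6, cells_per_patient=40, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
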