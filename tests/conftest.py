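import numpy as np
import pytest

from topoeeg import (
    FiltrationConfig,
    PreprocessConfig,
    RenderConfig,
    SynthesisConfig,
    cut_segments,
    five_point_cloud,
    generate_recording,
    preprocess_recording,
    vr_persistence,
)
from topoeeg.pipeline import featurize_segments


@pytest.fixture(scope="session")
def five_points():
    return five_point_cloud()


@pytest.fixture(scope="session")
def five_point_barcode(five_points):
    return vr_persistence(five_points, FiltrationConfig(n_folds=0))


@pytest.fixture(scope="session")
def separable_dataset():
    """200 balanced 2-s segments from a 4-event synthetic recording.

    Featurized once per session (folded once to 38-point clouds, barcodes
    rendered with a shared x-range) and reused by the classifier,
    evaluation and end-to-end tests.
    """
    syn = SynthesisConfig(
        duration=1200.0,
        seizure_intervals=[(200, 250), (500, 550), (800, 850), (1100, 1150)],
        seed=1,
    )
    pp = PreprocessConfig(interictal_buffer_s=30.0, seed=1)
    rec = preprocess_recording(generate_recording(syn), pp)
    segments = cut_segments(rec, pp)
    examples, barcodes, _ = featurize_segments(
        segments, FiltrationConfig(n_folds=1), RenderConfig()
    )
    return {
        "recording": rec,
        "segments": segments,
        "examples": examples,
        "barcodes": barcodes,
        "annotations": rec.annotations,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
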