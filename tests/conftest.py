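"""Shared fixtures: synthetic phantom corpora at the sizes the tests need."""
import numpy as np
import pytest

from scintidet import detector as det
from scintidet.phantom import PhantomConfig, generate_scan, sample_cohort_config
from scintidet.pipeline import prepare_fused


def make_fused(seed: int, positive: bool = True):
    """One cohort-sampled phantom taken through the full preprocessing chain."""
    cfg = sample_cohort_config(positive, seed=seed)
    scan, ap_boxes, pa_boxes = generate_scan(cfg)
    return prepare_fused(scan, ap_boxes, pa_boxes)


@pytest.fixture(scope="session")
def small_corpus():
    """12 preprocessed phantoms (alternating positive/negative)."""
    return [(make_fused(3000 + i, i % 2 == 0), i % 2 == 0) for i in range(12)]


@pytest.fixture(scope="session")
def easy_corpus():
    """40 low-noise phantoms with clear lesions for detector benchmarks."""
    out = []
    for i in range(40):
        positive = i % 2 == 0
        cfg = PhantomConfig(
            seed=4000 + i,
            n_metastases=3 if positive else 0,
            n_benign=1,
            global_gain=1.0,
            noise="poisson",
        )
        scan, ap_boxes, pa_boxes = generate_scan(cfg)
        out.append((prepare_fused(scan, ap_boxes, pa_boxes), positive))
    return out


@pytest.fixture(scope="session")
def trained_two_class(easy_corpus):
    """A 2-category reference model fit on the easy corpus."""
    images = [img for img, _pos in easy_corpus]
    return det.fit(images, config=det.BackendConfig(seed=7), n_categories=2)
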