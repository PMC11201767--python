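import numpy as np
import pandas as pd
import pytest

from zonequant import nucdetect, synthcortex


@pytest.fixture(scope="session")
def small_geometry():
    return synthcortex.make_geometry(400.0, 400.0, 0.0, 0.5)


@pytest.fixture(scope="session")
def rendered_field(small_geometry):
    """A 200-nucleus AD field rendered at 0.5 µm/px, with its ground truth.

    Nuclei are spaced >= 14 µm apart so none overlap; shared across the
    detection tests and the detection acceptance check.
    """
    cfg = synthcortex.GeneratorConfig.for_condition(
        "AD", n_cases=1, cells_per_case=200, min_spacing=14.0
    )
    cells = synthcortex.sample_cells(small_geometry, cfg, seed=1)
    cells = synthcortex.assign_intensities(cells, cfg, seed=2)
    img, meta = synthcortex.render_image(cells, small_geometry, seed=3)
    return cells, img, meta


@pytest.fixture(scope="session")
def detected_field(rendered_field):
    """Detection chain run on the rendered field: labels, annuli, measurements."""
    cells, img, meta = rendered_field
    channels = dict(zip(meta["channels"], img))
    params = nucdetect.DetectionParams(pixel_size=meta["pixel_size"])
    labels = nucdetect.detect_nuclei(channels["DAPI"], params)
    annuli = nucdetect.expand_pseudoplasm(
        labels, params.expansion_distance, params.pixel_size
    )
    measured = nucdetect.measure_cells(
        labels, annuli, {c: channels[c] for c in ("53BP1", "p16")}, params.pixel_size
    )
    return labels, annuli, measured


def make_positive_cells(n, rng, zones=None):
    """A bare table of damage-positive cells for intensity-model tests."""
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "case_id": "AD1",
            "condition": "AD",
            "nuclear_area": rng.lognormal(np.log(50.0), 0.3, n),
            "zone_true": rng.integers(1, 7, n) if zones is None else zones,
            "damage_positive": True,
        }
    )
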