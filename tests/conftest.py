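import math

import pytest

from phenoscreen.synth import (CellLine, EffectModel, Probe, ScreenDesign,
                               generate_screen, nci60_lines)


def tiny_design(image_shape=(64, 64)) -> ScreenDesign:
    """2 probes x 4 lines x 1 conc x 1 channel x 1 site x 2 times x 2 reps."""
    probes = [Probe("RS-1", "RS", "RS-1"), Probe("BD-1", "BD", "BD-1")]
    return ScreenDesign(probes, nci60_lines(4), [500.0], ["TRITC"], 1,
                        [1.0, 48.0], 2, image_shape=image_shape)


def tiny_effects(**overrides) -> EffectModel:
    """Noise-free model: one probe turns on 5-fold in leukemia lines."""
    kwargs = dict(baseline_log_mean=math.log(2000.0), baseline_log_sd=0.0,
                  turnon_effects={("RS-1", "leukemia"): 5.0})
    kwargs.update(overrides)
    return EffectModel(**kwargs)


@pytest.fixture(scope="session")
def tiny_screen(tmp_path_factory):
    """Noise-free 32-image screen shared across read-only tests."""
    root = tmp_path_factory.mktemp("tiny_screen")
    return generate_screen(tiny_design(), tiny_effects(), seed=3, outdir=root)
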