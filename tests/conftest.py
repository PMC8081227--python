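import pytest
from hypothesis import HealthCheck, settings

from treequity import canopy, synth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_city():
    """A tiny city for fast structural tests."""
    cfg = synth.CityConfig(
        grid_extent_m=600,
        n_blocks=36,
        n_block_groups=9,
        n_tracts=4,
        total_population=3000,
        center_density_scale_m=180,
        seed=11,
    )
    imagery, stack, blocks, bgs, truth = synth.generate_city(cfg)
    return {
        "config": cfg,
        "imagery": imagery,
        "stack": stack,
        "blocks": blocks,
        "block_groups": bgs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_city():
    """The default synthetic city: the validation-scale fixture."""
    cfg = synth.CityConfig(seed=1)
    imagery, stack, blocks, bgs, truth = synth.generate_city(cfg)
    return {
        "config": cfg,
        "imagery": imagery,
        "stack": stack,
        "blocks": blocks,
        "block_groups": bgs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_classification(default_city):
    """Feature stack, trained forest and predicted mask for the default city."""
    truth = default_city["truth"]
    points = synth.sample_control_points(truth, 9424, seed=2)
    stack = canopy.build_feature_stack(default_city["imagery"])
    thresholds = canopy.choose_thresholds(points, stack)
    stack = canopy.apply_thresholds(stack, thresholds)
    model, report = canopy.train_classifier(stack, points, seed=1)
    mask = canopy.classify(stack, model)
    return {
        "points": points,
        "stack": stack,
        "thresholds": thresholds,
        "model": model,
        "report": report,
        "mask": mask,
    }
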