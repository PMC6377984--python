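import copy

import pytest

from baricea.config_io import ModelConfig, baseline_config


def make_raw(**overrides) -> dict:
    """A small, fully valid two-arm configuration for fast unit tests.

    Top-level keys in ``overrides`` replace the corresponding sections.
    """
    raw = {
        "arm_probabilities": {
            "surgery": {
                "remission": 0.7,
                "improved": 0.1,
                "persistent": 0.1,
                "uncontrolled": 0.1,
                "dead": 0.0,
            },
            "no_surgery": {
                "remission": 0.0,
                "improved": 0.2,
                "persistent": 0.3,
                "uncontrolled": 0.5,
                "dead": 0.0,
            },
        },
        "costs": {
            "surgery_one_time": 1000.0,
            "medication": {
                "metformin": 10.0,
                "sulfonylurea": 5.0,
                "thiazolidinedione": 50.0,
                "alpha_glucosidase_inhibitor": 20.0,
                "insulin": 30.0,
            },
            "supplementation": 2.0,
            "complication_management": 100.0,
        },
        "utilities": {
            "remission": 0.9,
            "improved": 0.8,
            "persistent": 0.7,
            "uncontrolled": 0.6,
            "dead": 0.0,
        },
        "transition": {
            "surgery": {"relapse_probability": 0.1, "death_probability": 0.01},
            "no_surgery": {"relapse_probability": 0.0, "death_probability": 0.02},
        },
        "discount_rate": 0.03,
        "horizon_years": 10,
        "wtp_band": [100.0, 200.0],
    }
    raw = copy.deepcopy(raw)
    raw.update(copy.deepcopy(overrides))
    return raw


@pytest.fixture
def toy_config() -> ModelConfig:
    return ModelConfig.from_dict(make_raw())


@pytest.fixture(scope="session")
def thai_config() -> ModelConfig:
    """The bundled Thai baseline configuration."""
    return baseline_config()
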