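"""Shared scenario and paths for the numbered analysis drivers.

Every driver reads/writes under ``results/analysis`` and uses the same
study-like synthetic scenario (16 seedlings, 4 soil-temperature
treatments, 21-d imaging over two growing seasons) with one base seed.
"""

from pathlib import Path

from rootdyn.pipeline import DEFAULT_CONFIG, demography_from_config, schedule_from_config

BASE_SEED = 20220808
OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"


def scenario_config(seed: int = BASE_SEED) -> dict:
    import json

    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg["seed"] = seed
    return cfg


def schedule(cfg):
    return schedule_from_config(cfg)


def demography_params(cfg):
    return demography_from_config(cfg, schedule_from_config(cfg))
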