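"""YAML configuration loading for recipes and training hyperparameters."""

from __future__ import annotations

from pathlib import Path
from typing import List

import yaml

from .synth import ArchetypeSpec, SiteRecipe
from .training import TrainingConfig
from .views import AugmentationPolicy

__all__ = ["load_recipes", "load_training_config", "load_policy", "EXAMPLE_RECIPES_YAML"]

EXAMPLE_RECIPES_YAML = """\
archetypes:
  - name: tonal
    kind: harmonic_tonal
    band: [60, 480]
    duration_range: [1.2, 1.8]
    f0_range: [95, 105]
    n_harmonics: 4
    jitter: 0.05
  - name: pulse
    kind: pulse_train
    band: [500, 800]
    duration_range: [1.2, 1.8]
    pulse_rate_range: [18, 22]
    jitter: 0.05
sites:
  - site_id: S1
    archetype_weights: {tonal: 1.0, pulse: 1.0}
    snr_db_range: [10, 25]
    events_per_clip_range: [4, 7]
    overlap_prob: 0.1
"""

_TUPLE_FIELDS = ("band", "duration_range", "f0_range", "pulse_rate_range",
                 "snr_db_range", "events_per_clip_range")


def load_recipes(path) -> List[SiteRecipe]:
    doc = yaml.safe_load(Path(path).read_text())
    archetypes = {}
    for spec in doc["archetypes"]:
        spec = {k: tuple(v) if k in _TUPLE_FIELDS else v for k, v in spec.items()}
        archetypes[spec["name"]] = ArchetypeSpec(**spec)
    recipes = []
    for site in doc["sites"]:
        site = {k: tuple(v) if k in _TUPLE_FIELDS else v for k, v in site.items()}
        names = list(site["archetype_weights"])
        recipes.append(
            SiteRecipe(archetypes=tuple(archetypes[n] for n in names), **site)
        )
    return recipes


def load_training_config(path) -> TrainingConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if "vic_weights" in doc:
        doc["vic_weights"] = tuple(doc["vic_weights"])
    return TrainingConfig(**doc)


def load_policy(path) -> AugmentationPolicy:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("notch_center_range", "noise_sigma_range"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return AugmentationPolicy(**doc)
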