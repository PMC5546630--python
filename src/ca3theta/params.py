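"""Loaders for the structured-text parameter catalogs shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml


def _read_yaml(name: str):
    text = resources.files("ca3theta.data").joinpath(name).read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=None)
def load_model_config() -> dict:
    """Global model constants (unit scale, receptor ratios, ACh magnitudes)."""
    return _read_yaml("model.yaml")


@lru_cache(maxsize=None)
def load_network_config() -> dict:
    """Region geometry and connection rules."""
    return _read_yaml("network.yaml")


@lru_cache(maxsize=None)
def load_pathway_table() -> dict:
    """Raw pathway catalog (kinetics, delays, weights, b_ach, STP)."""
    return _read_yaml("synapses.yaml")["pathways"]
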