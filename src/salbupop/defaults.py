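"""Loaders for the packaged default parameter files.

The package ships its compound file, tissue partition coefficients,
reference physiology tables, the final population model, and the default
cohort specification as YAML under :mod:`salbupop.data`.
"""

from __future__ import annotations

import functools
from importlib import resources

import yaml

__all__ = [
    "load_yaml",
    "compound_dict",
    "tissue_kp_dict",
    "physiology_dict",
    "final_model_dict",
    "cohort_spec_dict",
]


def load_yaml(name: str) -> dict:
    """Load a packaged YAML data file by file name."""
    ref = resources.files("salbupop.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@functools.lru_cache(maxsize=None)
def compound_dict() -> dict:
    return load_yaml("compound.yaml")


@functools.lru_cache(maxsize=None)
def tissue_kp_dict() -> dict:
    return load_yaml("tissue_kp.yaml")


@functools.lru_cache(maxsize=None)
def physiology_dict() -> dict:
    return load_yaml("physiology.yaml")


@functools.lru_cache(maxsize=None)
def final_model_dict() -> dict:
    return load_yaml("final_model.yaml")


@functools.lru_cache(maxsize=None)
def cohort_spec_dict() -> dict:
    return load_yaml("cohort_default.yaml")
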