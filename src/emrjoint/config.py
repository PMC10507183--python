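"""Flat key-value (YAML) config files for the CLI.

A config file is a single mapping whose keys mirror the
:class:`~emrjoint.model.JointExtractor` constructor (model configs) or
the generator fields (generation configs). Unknown keys are an error —
silent typos in hyperparameter names are worse than a crash.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import JointExtractor
from .synthetic import GeneratorConfig, RelationRule

__all__ = ["load_model_config", "load_generator_config"]


def _load_mapping(path) -> dict:
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if payload is None:
        return {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    return payload


def load_model_config(path) -> dict:
    """Hyperparameter kwargs for JointExtractor; unknown keys are an error."""
    payload = _load_mapping(path)
    allowed = set(JointExtractor().get_params())
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    return payload


def load_generator_config(path) -> GeneratorConfig:
    """Build a GeneratorConfig from a YAML mapping; unknown keys error."""
    payload = _load_mapping(path)
    allowed = {
        "n_docs", "seed", "vocab", "inventories", "relation_rules",
        "doc_len_range", "entity_density", "noise_rate", "distractors",
    }
    unknown = set(payload) - allowed
    if unknown:
        raise ValueError(
            f"{path}: unknown config keys {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )
    kwargs = dict(payload)
    if "vocab" in kwargs:
        kwargs["vocab"] = tuple(kwargs["vocab"])
    if "distractors" in kwargs:
        kwargs["distractors"] = tuple(kwargs["distractors"])
    if "doc_len_range" in kwargs:
        kwargs["doc_len_range"] = tuple(kwargs["doc_len_range"])
    if "inventories" in kwargs:
        kwargs["inventories"] = {
            etype: tuple(tuple(form) if isinstance(form, list) else (form,)
                         for form in forms)
            for etype, forms in kwargs["inventories"].items()
        }
    if "relation_rules" in kwargs:
        kwargs["relation_rules"] = tuple(
            RelationRule(
                head_type=r["head_type"], tail_type=r["tail_type"],
                label=r["label"], probability=float(r["probability"]),
            )
            for r in kwargs["relation_rules"]
        )
    return GeneratorConfig(**kwargs)
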