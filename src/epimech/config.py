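"""Run configuration: YAML files, named profiles, and reproducibility logging."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from .mechanics import MechParams
from .protocol import ProtocolConfig
from .synth import EventGenParams

__all__ = ["load_config", "dump_config", "named_profile", "resolve_protocol_config"]

log = logging.getLogger(__name__)


def named_profile(name: str) -> ProtocolConfig:
    """Built-in protocol profiles: 'default' (61->400->800) and 'scaled' (37->100->200)."""
    if name == "default":
        return ProtocolConfig()
    if name == "scaled":
        return ProtocolConfig.scaled()
    raise KeyError(f"unknown profile '{name}' (use 'default' or 'scaled')")


def resolve_protocol_config(doc: dict) -> ProtocolConfig:
    """Build a ProtocolConfig from a config dict, starting from an optional profile."""
    doc = dict(doc or {})
    cfg = named_profile(doc.pop("profile", "default"))
    mech_doc = doc.pop("mech", None)
    kw = {}
    for f in dataclasses.fields(ProtocolConfig):
        if f.name in doc:
            kw[f.name] = doc.pop(f.name)
    if doc:
        raise KeyError(f"unknown config keys: {sorted(doc)}")
    mech = cfg.mech
    if mech_doc:
        mech = mech.replace(**mech_doc)
    return cfg.replace(mech=mech, **kw)


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return doc


def dump_config(obj, path: str | Path) -> None:
    """Echo a resolved dataclass config (or dict) into an output directory."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(json.dumps(obj, indent=2, default=str))


def event_params_from_dict(doc: dict) -> EventGenParams:
    return EventGenParams(**(doc or {}))
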