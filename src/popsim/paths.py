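"""Dotted-path addressing of workspace numeric fields.

The sensitivity tool and the estimator both need to read and perturb
arbitrary numeric fields of an (immutable) workspace.  Paths look like::

    compounds[drugA].renal_cl
    compounds[0].clint_per_enzyme[CYP3A4]
    trial.regimens[0].amount
    population.organ_volumes[liver].mean

Segments address dataclass attributes, dict keys and sequence indices;
sequences of named records (compounds, PD units) may be indexed by
name.  ``(mean, cv)`` pairs accept ``.mean``/``.cv`` aliases.  Setting
a value rebuilds the frozen dataclass chain and returns a new object.
"""

from __future__ import annotations

import dataclasses
import re

from .errors import ValidationError

__all__ = ["get_path", "set_path"]

_SEGMENT = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)((?:\[[^\]]+\])*)$")
_KEY = re.compile(r"\[([^\]]+)\]")

_PAIR_ALIAS = {"mean": 0, "cv": 1}


def _parse(path: str) -> list[tuple[str, str]]:
    steps: list[tuple[str, str]] = []
    for segment in path.split("."):
        m = _SEGMENT.match(segment.strip())
        if not m:
            raise ValidationError("parameter_path", f"cannot parse segment {segment!r}")
        steps.append(("attr", m.group(1)))
        for key in _KEY.findall(m.group(2)):
            steps.append(("key", key))
    return steps


def _resolve_key(container, key: str):
    if isinstance(container, dict):
        if key in container:
            return key
        try:
            numeric = int(key)
        except ValueError:
            raise ValidationError("parameter_path", f"key {key!r} not found") from None
        if numeric in container:
            return numeric
        raise ValidationError("parameter_path", f"key {key!r} not found")
    # sequence: numeric index or lookup by .name / .unit_id
    try:
        return int(key)
    except ValueError:
        pass
    for i, item in enumerate(container):
        if getattr(item, "name", None) == key or getattr(item, "unit_id", None) == key:
            return i
    raise ValidationError("parameter_path", f"no element named {key!r}")


def _step_get(obj, kind: str, key: str):
    if kind == "attr":
        if isinstance(obj, tuple) and not dataclasses.is_dataclass(obj) and key in _PAIR_ALIAS:
            return obj[_PAIR_ALIAS[key]]
        if not hasattr(obj, key):
            raise ValidationError("parameter_path", f"{type(obj).__name__} has no field {key!r}")
        return getattr(obj, key)
    index = _resolve_key(obj, key)
    return obj[index]


def _step_set(obj, kind: str, key: str, value):
    if kind == "attr":
        if isinstance(obj, tuple) and not dataclasses.is_dataclass(obj) and key in _PAIR_ALIAS:
            i = _PAIR_ALIAS[key]
            return obj[:i] + (value,) + obj[i + 1:]
        if dataclasses.is_dataclass(obj):
            return dataclasses.replace(obj, **{key: value})
        raise ValidationError("parameter_path", f"cannot set attribute on {type(obj).__name__}")
    index = _resolve_key(obj, key)
    if isinstance(obj, dict):
        new = dict(obj)
        new[index] = value
        return new
    if isinstance(obj, tuple):
        return obj[:index] + (value,) + obj[index + 1:]
    new = list(obj)
    new[index] = value
    return new


def get_path(obj, path: str):
    """Read the value addressed by ``path``."""
    for kind, key in _parse(path):
        obj = _step_get(obj, kind, key)
    return obj


def set_path(obj, path: str, value):
    """Return a copy of ``obj`` with the addressed field set to ``value``."""
    steps = _parse(path)

    def rebuild(node, remaining):
        if not remaining:
            return value
        kind, key = remaining[0]
        child = _step_get(node, kind, key)
        return _step_set(node, kind, key, rebuild(child, remaining[1:]))

    return rebuild(obj, steps)
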