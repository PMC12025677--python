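"""Plain-text (YAML) serialization for models, MDPs, channels, distributions.

Every object round-trips through a nested mapping of lists of floats with a
``kind`` discriminator; no binary formats.  Layouts follow the package
conventions documented in :mod:`imotiv.genmodel`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .genmodel import GenerativeModel, MDPSpec
from .infotheory import Categorical, Channel
from .mop import StatePolicy


def _listify(a: np.ndarray):
    return np.asarray(a, dtype=float).tolist()


def to_dict(obj) -> dict:
    """Convert a supported object to a plain nested mapping."""
    if isinstance(obj, Categorical):
        d = {"kind": "categorical", "probs": _listify(obj.probs)}
        if obj.labels is not None:
            d["labels"] = list(obj.labels)
        return d
    if isinstance(obj, Channel):
        return {"kind": "channel", "matrix": _listify(obj.matrix)}
    if isinstance(obj, StatePolicy):
        return {"kind": "state_policy", "matrix": _listify(obj.matrix)}
    if isinstance(obj, GenerativeModel):
        return {
            "kind": "generative_model",
            "likelihood": _listify(obj.likelihood),
            "transitions": _listify(obj.transitions),
            "state_prior": _listify(obj.state_prior.probs),
            "preference": _listify(obj.preference.probs),
            "horizon": obj.horizon,
        }
    if isinstance(obj, MDPSpec):
        return {
            "kind": "mdp",
            "n_states": obj.n_states,
            "n_actions": obj.n_actions,
            "transitions": _listify(obj.transitions),
            "absorbing": sorted(obj.absorbing),
            "labels": [list(l) for l in obj.labels] if obj.labels else None,
        }
    raise ConfigurationError(f"cannot serialize object of type {type(obj)!r}")


def from_dict(d: dict):
    """Rebuild an object from :func:`to_dict` output."""
    kind = d.get("kind")
    if kind == "categorical":
        labels = tuple(d["labels"]) if d.get("labels") else None
        return Categorical(np.asarray(d["probs"]), labels=labels)
    if kind == "channel":
        return Channel(np.asarray(d["matrix"]))
    if kind == "state_policy":
        return StatePolicy(np.asarray(d["matrix"]))
    if kind == "generative_model":
        return GenerativeModel(
            likelihood=np.asarray(d["likelihood"]),
            transitions=np.asarray(d["transitions"]),
            state_prior=Categorical(np.asarray(d["state_prior"])),
            preference=Categorical(np.asarray(d["preference"])),
            horizon=d.get("horizon"),
        )
    if kind == "mdp":
        labels = tuple(tuple(l) for l in d["labels"]) if d.get("labels") else None
        return MDPSpec(
            n_states=int(d["n_states"]),
            n_actions=int(d["n_actions"]),
            transitions=np.asarray(d["transitions"]),
            absorbing=frozenset(d.get("absorbing") or ()),
            labels=labels,
        )
    raise ConfigurationError(f"unknown kind {kind!r} in config")


def save(obj, path: str | Path) -> None:
    """Write a supported object to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(obj), fh, default_flow_style=None)


def load(path: str | Path):
    """Read an object written by :func:`save`."""
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh))


def save_pair(mdp: MDPSpec, gm: GenerativeModel, path: str | Path) -> None:
    """Write an (MDP, generative model) environment pair to one YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump({"kind": "environment", "mdp": to_dict(mdp),
                        "model": to_dict(gm)}, fh, default_flow_style=None)


def load_pair(path: str | Path):
    """Read an environment pair written by :func:`save_pair`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d.get("kind") != "environment":
        raise ConfigurationError(f"{path} is not an environment file")
    return from_dict(d["mdp"]), from_dict(d["model"])
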