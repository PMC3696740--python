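"""YAML configuration round-trip for model parameters and experiments."""

from __future__ import annotations

from typing import Any

import yaml

from .params import params_from_dict, params_to_dict


def load_params(path: str) -> Any:
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))


def dump_params(p: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p), fh, sort_keys=True)
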