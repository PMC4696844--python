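"""Reading run configurations from JSON or YAML files.

Schema (all keys optional unless a command needs them):

.. code-block:: json

    {
      "theta_A": 0.01, "theta_B": 0.01, "rho": 50.0,
      "P_A": [[0.5, 0.5], [0.5, 0.5]], "P_B": [[0.5, 0.5], [0.5, 0.5]],
      "M": [[0.9, 0.1], [0.2, 0.8]], "q_prime": [0.2, 0.8],
      "N": 400,
      "samples": [{"a": [0, 0], "b": [0, 0], "c": [[0, 0], [1, 0]]},
                  {"c": [[0, 0], [0, 1]]}]
    }

Each entry of ``samples`` is one deme's configuration; ``a``/``b`` default
to zeros and ``c`` to the zero matrix.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .models import (MigrationModel, MutationModel, SampleConfig, SubdividedSample,
                     TwoLocusParams)

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Objects built from a configuration file."""

    params: TwoLocusParams | None
    migration: MigrationModel | None
    N: int | None
    sample: SubdividedSample | None
    raw: dict

    def require(self, field: str):
        value = getattr(self, field)
        if value is None:
            raise ValidationError(f"configuration file is missing what is needed for {field!r}")
        return value


def _parse_sample(entry: dict, r_A: int, r_B: int) -> SampleConfig:
    a = entry.get("a", [0] * r_A)
    b = entry.get("b", [0] * r_B)
    c = entry.get("c")
    if c is None:
        c = np.zeros((r_A, r_B), dtype=int)
    return SampleConfig(a, b, c)


def load_config(path) -> RunConfig:
    """Load and validate a JSON (or, by extension, YAML) configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValidationError("configuration file must contain a mapping at top level")

    params = None
    if "P_A" in raw or "theta_A" in raw:
        try:
            mut = MutationModel(theta_A=raw["theta_A"], theta_B=raw["theta_B"],
                                P_A=raw["P_A"], P_B=raw["P_B"])
            params = TwoLocusParams(mut, raw.get("rho", 0.0))
        except KeyError as exc:
            raise ValidationError(f"configuration missing key {exc.args[0]!r}") from None

    migration = None
    if "M" in raw:
        if "q_prime" not in raw:
            raise ValidationError("configuration with 'M' also needs 'q_prime'")
        migration = MigrationModel(raw["M"], raw["q_prime"])

    sample = None
    if "samples" in raw:
        if params is None:
            r_A = r_B = 2
        else:
            r_A, r_B = params.r_A, params.r_B
        sample = SubdividedSample(tuple(
            _parse_sample(entry, r_A, r_B) for entry in raw["samples"]
        ))

    N = raw.get("N")
    return RunConfig(params=params, migration=migration,
                     N=None if N is None else int(N), sample=sample, raw=raw)
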