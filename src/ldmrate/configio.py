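"""YAML/JSON round-tripping for parameter sets and inocula.

The on-disk schema is explicit about units::

    rates:                 # psi in 1/hr, gamma in ml/(cell*hr)
      psi_D: 1.0
      psi_R: 1.0
      psi_T: 1.0
      gamma_D: 1.0e-6
      gamma_T: 1.0e-6
    inoculum:              # densities in cfu/ml
      D0: 100.0
      R0: 100.0
      T0: 0.0
    assay:                 # optional
      t_tilde_hr: 2.5
      culture_volume_ml: 0.1
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core_model import InoculumState, RateParameters
from .errors import DomainError

__all__ = ["load_assay_config", "save_assay_config"]


def load_assay_config(path) -> dict:
    """Load a config file; returns a dict with ``params``, ``init`` and
    any ``assay`` settings (``t_tilde_hr``, ``culture_volume_ml``)."""
    text = Path(path).read_text(encoding="utf-8")
    raw = json.loads(text) if str(path).endswith(".json") \
        else yaml.safe_load(text)
    if not isinstance(raw, dict) or "rates" not in raw:
        raise DomainError(f"{path}: expected a mapping with a 'rates' block")
    out = {
        "params": RateParameters.from_dict(raw["rates"]),
        "init": InoculumState.from_dict(raw.get("inoculum",
                                                {"D0": 0.0, "R0": 0.0})),
    }
    out.update(raw.get("assay", {}))
    return out


def save_assay_config(path, params: RateParameters, init: InoculumState,
                      **assay) -> None:
    doc = {"rates": params.to_dict(), "inoculum": init.to_dict()}
    if assay:
        doc["assay"] = assay
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False),
                          encoding="utf-8")
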