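"""Access to the packaged default configuration files.

The shipped weight table is a clearly-labelled synthetic placeholder (real
analyses must supply the exact consortium betas); the simulation defaults
encode the study conditions the synthetic cohort emulates.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

from .io import _snp_from_record
from .model import WeightTable


def _load_json(name: str) -> dict[str, Any]:
    with resources.files("polyfh.data").joinpath(name).open() as fh:
        return json.load(fh)


def default_weights() -> WeightTable:
    """The shipped placeholder 11-SNP weight table."""
    doc = _load_json("default_weights.json")
    apoe = {k: float(v) for k, v in doc["apoe_diplotype_weights"].items()}
    return WeightTable(
        snps=[_snp_from_record(rec) for rec in doc["snps"]],
        apoe_diplotype_weights=apoe,
    )


def default_sim_dict() -> dict[str, Any]:
    """The shipped simulation defaults as a plain dict."""
    return _load_json("default_sim.json")
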