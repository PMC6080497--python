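"""Configuration loading and logging setup.

A configuration file is YAML (or JSON, which YAML subsumes) with up to four
sections: ``io``, ``fitting``, ``uncertainty``, ``simulation``.  Unknown keys
are preserved so callers can carry their own settings; missing sections fall
back to the package defaults below.
"""
from __future__ import annotations

import copy
import logging
import sys
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Default settings per section.  ``second_order`` selects how the first- and
#: second-order relative propagation terms combine: "quadrature" (default,
#: consistent with a Monte-Carlo oracle), "additive" (theta + chi, the form
#: the propagation equations are usually typeset in) or "none".
DEFAULTS: dict = {
    "io": {
        "delimiter": None,  # None -> sniff comma vs tab
    },
    "fitting": {
        "force_origin": True,
        "origin_weight": 1.0,
        "expansion": 0.10,
        "expansion_mode": "halfwidth",  # or "relative"
        "xtol": 1e-10,
        "max_nfev": 10_000,
    },
    "uncertainty": {
        "second_order": "quadrature",
        "taper_method": "mean_of_ratios",  # or "pooled"
        "stage_midpoints": {"early": 75.0, "mid": 225.0, "late": 350.0},
    },
    "simulation": {},
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a sectioned YAML/JSON config, merged over the package defaults.

    Parameters
    ----------
    path:
        Optional path to a YAML file.  ``None`` returns the defaults.
    overrides:
        Optional mapping merged last (section -> {key: value}).
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(loaded).__name__}")
        for section, values in loaded.items():
            if values is None:
                continue
            if not isinstance(values, dict):
                raise ConfigurationError(f"config section {section!r} must be a mapping")
            cfg.setdefault(section, {}).update(values)
    for section, values in (overrides or {}).items():
        cfg.setdefault(section, {}).update(values)
    return cfg


def get_logger(name: str = "canemetrics", verbosity: int = 0) -> logging.Logger:
    """Return a timestamped stream logger.

    verbosity 0 -> WARNING, 1 -> INFO, >=2 -> DEBUG.
    """
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
        )
        logger.addHandler(handler)
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    logger.setLevel(level)
    return logger
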