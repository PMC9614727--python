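"""YAML run configuration.

One structured file defines everything a CLI run needs: file paths,
selections, channel geometry, region boundaries, bin widths, and the
synthetic-spec overrides.  Example::

    structure: system.gro
    trajectory: run.csv
    selections:
      waters: {role: water-oxygen, indices: [0, 1, 2]}
      backbone: {role: protein-backbone, names: [CA, C, N]}
    channel:
      origin: [5.0, 5.0, 6.0]
      radius: 0.4
      z_lo: -1.25
      z_hi: 1.25
    synthetic:
      seed: 7
      g: 0.2

Selections may list explicit 0-based ``indices`` or atom ``names`` to be
resolved against the structure metadata (the C2 marker atom, in particular,
is named by the user, never hard-coded).
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd
import yaml

from .exceptions import UsageError
from .io_core import ChannelGeometry, Selection
from .synthetic import SyntheticSpec


def load_config(path: str) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise UsageError(f"{path}: config must be a mapping")
    return cfg


def selection_from_config(
    name: str, entry: dict[str, Any], metadata: pd.DataFrame | None = None
) -> Selection:
    """Build a Selection from a config entry (explicit indices or atom names)."""
    role = entry.get("role")
    if role is None:
        raise UsageError(f"selection {name!r}: missing 'role'")
    if "indices" in entry:
        idx = np.asarray(entry["indices"], dtype=np.intp)
    elif "names" in entry:
        if metadata is None:
            raise UsageError(
                f"selection {name!r} uses atom names but no structure was given"
            )
        idx = np.flatnonzero(metadata["name"].isin(entry["names"]).to_numpy())
    else:
        raise UsageError(f"selection {name!r}: need 'indices' or 'names'")
    return Selection(name, idx, role)


def geometry_from_config(entry: dict[str, Any]) -> ChannelGeometry:
    kwargs = dict(
        origin=np.asarray(entry["origin"], dtype=float),
        radius=float(entry["radius"]),
        z_lo=float(entry["z_lo"]),
        z_hi=float(entry["z_hi"]),
    )
    if "direction" in entry:
        kwargs["direction"] = np.asarray(entry["direction"], dtype=float)
    return ChannelGeometry(**kwargs)


def synthetic_spec_from_config(entry: dict[str, Any]) -> SyntheticSpec:
    known = set(SyntheticSpec.__dataclass_fields__)
    unknown = set(entry) - known
    if unknown:
        raise UsageError(f"unknown synthetic-spec keys: {sorted(unknown)}")
    if "box" in entry:
        entry = {**entry, "box": tuple(entry["box"])}
    if "pressures" in entry:
        entry = {**entry, "pressures": tuple(entry["pressures"])}
    return SyntheticSpec(**entry)
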