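"""Flat key/value configuration handling and the versioned default set.

Config format: one ``key = value`` pair per line, ``#`` comments, optional
``include <relative-path>`` lines (processed first, so later keys override
included ones).  Units are embedded in the key names of run configs
(e.g. ``k_se_pN_per_nm``); the kinetic defaults file uses the bare model
symbols documented in :mod:`crossbridge.active`.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

__all__ = ["parse_config", "load_active_defaults", "config_hash", "write_config"]

_DEFAULTS_CACHE: dict | None = None


def _coerce(value: str):
    v = value.strip()
    try:
        return int(v)
    except ValueError:
        pass
    try:
        return float(v)
    except ValueError:
        pass
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    return v


def parse_config(text: str, base: Path | None = None) -> dict:
    """Parse flat key/value config text into a dict."""
    out: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("include "):
            inc = line.split(None, 1)[1].strip()
            path = (base / inc) if base is not None else Path(inc)
            out.update(parse_config(path.read_text(), base=path.parent))
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = _coerce(val)
    return out


def load_config(path: str | Path) -> dict:
    path = Path(path)
    return parse_config(path.read_text(), base=path.parent)


def load_active_defaults() -> dict:
    """Kinetic/energetic defaults of the active model (cached)."""
    global _DEFAULTS_CACHE
    if _DEFAULTS_CACHE is None:
        text = resources.files("crossbridge.data").joinpath(
            "active_defaults.cfg").read_text()
        _DEFAULTS_CACHE = parse_config(text)
    return dict(_DEFAULTS_CACHE)


def config_hash(cfg: dict) -> str:
    """Short deterministic hash of a config dict, for run provenance."""
    blob = "\n".join(f"{k}={cfg[k]!r}" for k in sorted(cfg)).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_config(cfg: dict, path: str | Path) -> None:
    lines = [f"{k} = {cfg[k]}" for k in sorted(cfg)]
    Path(path).write_text("\n".join(lines) + "\n")
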