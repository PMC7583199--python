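"""Small shared I/O helpers: canonical config hashing and JSON sidecars."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path


def _canonical(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _canonical(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def config_hash(config) -> str:
    """Short stable hash of a configuration (dict or dataclass).

    Every output sidecar records this, so identical configurations are
    verifiable as identical across runs.
    """
    payload = json.dumps(_canonical(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_canonical(payload), indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
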