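"""Run manifests: config snapshot, seeds, and content digests per stage."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

from .errors import ConsistencyError, InputError

__all__ = ["RunManifest", "file_digest", "verify_manifest"]


def file_digest(path) -> str:
    if not Path(path).is_file():
        raise InputError(f"no such file: {path}")
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """One manifest per CLI invocation: what ran, on what, producing what."""

    def __init__(self, stage: str, config: dict, root_seed: int):
        from . import __version__

        self.data = {
            "stage": stage,
            "tool_version": __version__,
            "root_seed": root_seed,
            "config": config,
            "inputs": {},
            "outputs": {},
            "started": datetime.now(timezone.utc).isoformat(),
            "finished": None,
        }

    def add_input(self, path) -> None:
        self.data["inputs"][str(path)] = file_digest(path)

    def add_output(self, path) -> None:
        self.data["outputs"][str(path)] = file_digest(path)

    def write(self, out_dir) -> Path:
        self.data["finished"] = datetime.now(timezone.utc).isoformat()
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        target = out / "manifest.json"
        target.write_text(json.dumps(self.data, indent=2))
        return target


def verify_manifest(manifest_path) -> None:
    """Re-hash every recorded output; raise if anything was modified."""
    path = Path(manifest_path)
    if not path.is_file():
        raise InputError(f"no such manifest: {path}")
    data = json.loads(path.read_text())
    for recorded_path, digest in data.get("outputs", {}).items():
        p = Path(recorded_path)
        if not p.is_file():
            raise ConsistencyError(f"manifest output missing: {p}")
        if file_digest(p) != digest:
            raise ConsistencyError(f"manifest digest mismatch for {p}")
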