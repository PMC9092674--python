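"""Run manifest: parameter snapshot plus per-file checksums.

The manifest is byte-stable across reruns with identical parameters and
seed, so it doubles as the whole-pipeline determinism certificate.
Wall-clock timestamps are confined to ``run.log`` for that reason.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["build_manifest", "write_manifest", "file_checksums", "MANIFEST_NAME"]

MANIFEST_NAME = "manifest.json"
_EXCLUDE = {MANIFEST_NAME, "run.log"}


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def file_checksums(out_dir) -> dict[str, str]:
    """SHA-256 of every file under ``out_dir`` except the manifest and log."""
    out_dir = Path(out_dir)
    files = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name not in _EXCLUDE:
            files[path.relative_to(out_dir).as_posix()] = sha256_file(path)
    return files


def build_manifest(params: dict, out_dir, command: str, seed: int) -> dict:
    return {
        "tool": "scdnasim",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": params,
        "files": file_checksums(out_dir),
    }


def write_manifest(params: dict, out_dir, command: str, seed: int) -> Path:
    manifest = build_manifest(params, out_dir, command, seed)
    path = Path(out_dir) / MANIFEST_NAME
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
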