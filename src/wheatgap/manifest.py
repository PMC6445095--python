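"""Run manifests: enough metadata to replay any stage bit-identically."""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["build_manifest", "save_manifest", "load_manifest", "file_digest",
           "replay_matches"]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(stage: str, seed: int, config: dict,
                   outputs: dict | None = None, extra: dict | None = None) -> dict:
    """Assemble a manifest for one pipeline stage.

    ``outputs`` maps labels to file paths; their digests are recorded so
    a replay can be verified byte-for-byte.
    """
    man = {
        "stage": stage,
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "output_digests": {k: file_digest(v) for k, v in (outputs or {}).items()},
    }
    if extra:
        man.update(extra)
    return man


def save_manifest(man: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def replay_matches(man: dict, outputs: dict) -> bool:
    """True if freshly produced output files match the recorded digests."""
    return all(
        man["output_digests"].get(k) == file_digest(v) for k, v in outputs.items()
    )
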