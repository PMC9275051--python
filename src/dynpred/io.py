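"""Model archives and run manifests.

A fitted landmark prediction tool is a bundle: the per-marker mixed models,
the fitted survival learners, optionally the superlearner weights, and the
landmark configuration. Archives are versioned joblib files; the manifest
(JSON) records configuration, seeds and package version so a run can be
reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import joblib

ARCHIVE_VERSION = 1

__all__ = ["save_archive", "load_archive", "write_manifest", "manifest_hash"]


def save_archive(path, *, marker_models, learners, config,
                 superlearner=None, meta=None):
    """Write a versioned model archive."""
    from . import __version__

    payload = {
        "archive_version": ARCHIVE_VERSION,
        "package_version": __version__,
        "marker_models": marker_models,
        "learners": learners,
        "superlearner": superlearner,
        "config": config,
        "meta": dict(meta or {}),
    }
    joblib.dump(payload, path)
    return Path(path)


def load_archive(path) -> dict:
    payload = joblib.load(path)
    if payload.get("archive_version") != ARCHIVE_VERSION:
        raise ValueError(
            f"unsupported archive version {payload.get('archive_version')!r}")
    return payload


def manifest_hash(manifest: dict) -> str:
    blob = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, manifest: dict) -> str:
    """Write the manifest JSON with its own content hash; returns the hash."""
    manifest = dict(manifest)
    manifest["hash"] = manifest_hash(manifest)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                     default=str))
    return manifest["hash"]
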