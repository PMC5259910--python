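"""Flat key-value configuration files and run manifests.

The config format is one ``key = value`` pair per line (``#`` comments);
keys mirror the fields of :class:`rsapred.ibcga.IBCGAConfig` and
:class:`rsapred.synthetic.SynthConfig`.  Command-line flags override file
values.  Every CLI run writes a ``manifest.json`` capturing the subcommand,
the effective configuration, seeds, SHA-256 hashes of the inputs and the
package/snapshot versions, so that two runs with identical manifests
produce identical primary outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any, Mapping


def parse_flat_config(text: str) -> dict[str, str]:
    """Parse ``key = value`` lines; later keys win; '#' starts a comment."""
    out: dict[str, str] = {}
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {i}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_flat_config(path: str | Path) -> dict[str, str]:
    return parse_flat_config(Path(path).read_text())


def coerce_into(cls, raw: Mapping[str, str], **overrides: Any):
    """Build a dataclass from string config values plus keyword overrides."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key not in fields:
            continue
        ftype = fields[key].type
        if "int" in str(ftype):
            kwargs[key] = int(value)
        elif "float" in str(ftype):
            kwargs[key] = float(value)
        elif "tuple" in str(ftype):
            parts = value.replace("(", "").replace(")", "").split(",")
            kwargs[key] = tuple(
                float(p) if "." in p else int(p) for p in parts if p.strip()
            )
        else:
            kwargs[key] = value
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    return cls(**kwargs)


def show_config(cls) -> str:
    """Render a dataclass's defaults in flat-config form."""
    lines = []
    for f in dataclasses.fields(cls):
        default = (
            f.default
            if f.default is not dataclasses.MISSING
            else f.default_factory()  # type: ignore[misc]
        )
        lines.append(f"{f.name} = {default}")
    return "\n".join(lines)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    config_snapshot: Mapping[str, Any],
    seeds: Mapping[str, int],
    inputs: Mapping[str, str | Path] | None = None,
) -> Path:
    """Write the reproducibility manifest for one CLI run."""
    from . import __version__
    from .aaindex import load_bundled_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "config": dict(config_snapshot),
        "seeds": dict(seeds),
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
        },
        "package_version": __version__,
        "aaindex_snapshot_version": load_bundled_table().source_version,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
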