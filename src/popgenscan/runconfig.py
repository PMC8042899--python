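"""YAML run configurations for the CLI.

A config file holds one analysis invocation: a ``command`` key naming the
subcommand plus that subcommand's parameters, e.g.::

    command: fdscan
    vcf: fixture.vcf
    popmap: popmap.tsv
    p1: Wild
    p2: DomCN
    p3: SEASA
    outgroup: Outgroup
    out: results/fd

Validation errors name the offending key. CLI flags passed alongside
``--config`` override config values. Analysis defaults (window geometry,
thresholds, block sizes) live on the subcommands themselves so a config
only needs to state what differs from the study's parameters.
"""

from __future__ import annotations

from pathlib import Path

import yaml

REQUIRED: dict[str, tuple[str, ...]] = {
    "stats": ("vcf", "popmap", "pops", "out"),
    "dstat": ("vcf", "popmap", "p1", "p2", "p3", "outgroup", "out"),
    "f3": ("vcf", "popmap", "target", "sources", "out"),
    "fdscan": ("vcf", "popmap", "p1", "p2", "p3", "outgroup", "out"),
    "sweep": ("vcf", "popmap", "wild", "domestic", "out"),
    "abc": ("mode", "out"),
    "synth": ("out",),
}


class ConfigError(ValueError):
    """A run configuration failed validation; the message names the key."""


def load_run_config(path) -> tuple[str, dict]:
    """Parse and validate a YAML run config; returns (command, params)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    command = raw.pop("command", None)
    if command not in REQUIRED:
        raise ConfigError(
            f"config key 'command' must be one of {sorted(REQUIRED)}, "
            f"got {command!r}")
    missing = [k for k in REQUIRED[command] if k not in raw]
    if missing:
        raise ConfigError(
            f"config for {command!r} is missing required key(s): "
            + ", ".join(repr(m) for m in missing))
    for key in ("vcf", "popmap", "gff"):
        if key in raw and not Path(str(raw[key])).exists():
            raise ConfigError(f"config key {key!r}: no such file "
                              f"{raw[key]!r}")
    return command, {k: v for k, v in raw.items()}
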