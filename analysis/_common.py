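"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import click

from matchsim.experiments import load_config, write_manifest


def add_config(options: dict, config_path) -> dict:
    """CLI options, overridden by an optional flat JSON/YAML config file."""
    cfg = {k: v for k, v in options.items() if k != "config"}
    if config_path is not None:
        cfg.update(load_config(config_path))
    return cfg


def finish(out: Path, cfg: dict, **tables) -> None:
    """Write each table as tidy CSV plus the run manifest."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        click.echo(f"wrote {path}")
    write_manifest(out, {k: str(v) for k, v in cfg.items()})
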