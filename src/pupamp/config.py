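"""Run configuration shared across the command line and the resampling engine."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parameters governing a full analysis run.

    Attributes
    ----------
    seed
        Root RNG seed; every stochastic step derives its stream from it, so
        identical config + identical inputs give byte-identical outputs.
    subset_size
        Rows drawn (without replacement) per resampling cycle.
    n_iterations
        Number of resampling cycles.
    pvalue_threshold
        Raw p-value filter for motif hits.
    dilution_factor
        Plate-to-pupa CFU scaling: each pupa is macerated in 300 uL of which
        50 uL are plated, so one colony represents 6 CFU per pupa.
    output_dir
        Where result tables and the run manifest are written.
    """

    seed: int = 0
    subset_size: int = 60
    n_iterations: int = 4000
    pvalue_threshold: float = 1e-4
    dilution_factor: float = 6.0
    output_dir: Path = Path(".")

    def __post_init__(self) -> None:
        if self.subset_size < 2:
            raise ValueError(f"subset_size must be >= 2, got {self.subset_size}")
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 0.0 < self.pvalue_threshold < 1.0:
            raise ValueError(
                f"pvalue_threshold must lie in (0, 1), got {self.pvalue_threshold}"
            )
        if self.dilution_factor <= 0:
            raise ValueError(
                f"dilution_factor must be positive, got {self.dilution_factor}"
            )
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        return d


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def log(msg: str) -> None:
    """Timestamped progress line on stderr."""
    stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    print(f"[{stamp}] {msg}", file=sys.stderr)


def write_manifest(
    path: str | Path, config: RunConfig, inputs: dict[str, str | Path] | None = None
) -> None:
    """Write a machine-readable run manifest: config, seed, input file hashes."""
    manifest = {
        "config": config.to_dict(),
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (inputs or {}).items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
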