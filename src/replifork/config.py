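"""Run configuration: YAML-backed parameter blocks with serialised defaults.

Every CLI command resolves its effective configuration (file values overlaid
with flag overrides and defaults) and echoes it verbatim into the output
directory, so a run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .fragments import Genome, Origin, load_genome, load_origins
from .simulate import SPhaseModel


@dataclass
class AnalysisDefaults:
    """Shared analysis parameters with their serialised defaults."""

    flank: int = 10_000
    bin_width: int = 100
    halfwidth: int = 10_000
    meta_halfwidth: int = 20_000
    meta_bin_width: int = 100
    meta_exclusion: int = 1_000
    coverage_bin_width: int = 1_000
    match_metric: str = "spearman"
    polarity: str = "flip_okazaki_strand"
    mate_strand: int = 1
    exclude_chroms: tuple[str, ...] = ("chrXII",)
    early_min_oem: float | None = 0.4
    early_top_n: int | None = None
    front_level: float = 0.5
    seed: int = 0


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return data


def dump_config(data: dict, path) -> None:
    """Persist the effective configuration of a run (defaults resolved)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(data), fh, sort_keys=True, default_flow_style=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def genome_from_config(spec, base_dir: Path, exclude=()) -> Genome:
    """Inline mapping ``{name: length}`` or a path to a chrom-sizes TSV."""
    if isinstance(spec, str):
        return load_genome(base_dir / spec if not Path(spec).is_absolute() else spec,
                           exclude=exclude)
    return Genome(spec, exclude=exclude)


def origins_from_config(spec, genome: Genome, base_dir: Path) -> list[Origin]:
    """Inline list of origin mappings or a path to a BED file."""
    if isinstance(spec, str):
        return load_origins(base_dir / spec if not Path(spec).is_absolute() else spec, genome)
    origins = []
    for i, row in enumerate(spec, start=1):
        o = Origin(str(row["chrom"]), int(row["start"]), int(row["end"]),
                   str(row.get("id") or f"origin_{i:04d}"))
        if o.chrom not in genome or o.end > genome[o.chrom]:
            raise ValueError(f"origin {o.id} outside genome")
        origins.append(o)
    order = {n: k for k, n in enumerate(genome.names)}
    origins.sort(key=lambda o: (order[o.chrom], o.midpoint))
    return origins


def model_from_config(block: dict, n_origins: int, seed: int | None = None) -> SPhaseModel:
    """Build an :class:`SPhaseModel` from a YAML ``model`` block.

    Scalar competence / firing parameters are broadcast over the origin list.
    """
    def broadcast(key, default=None):
        val = block.get(key, default)
        if val is None:
            raise ValueError(f"model block missing required field {key!r}")
        arr = np.asarray(val, dtype=float)
        if arr.ndim == 0:
            arr = np.full(n_origins, float(arr))
        if len(arr) != n_origins:
            raise ValueError(f"model field {key!r} has length {len(arr)}, expected {n_origins}")
        return arr

    sites = tuple((str(c), int(p)) for c, p in block.get("sbfi_sites", ()))
    kwargs = dict(
        competence=broadcast("competence"),
        firing_mean=broadcast("firing_mean"),
        firing_sd=broadcast("firing_sd", 0.0),
        fork_speed=float(block["fork_speed"]),
        sbfi_sites=sites,
    )
    for key in ("okazaki_mean", "okazaki_sd", "okazaki_min", "fragment_rate",
                "ribo_rate_pol_eps", "ribo_rate_pol_alpha", "ribo_rate_pol_delta",
                "pol_eps_lagging_fraction", "depletion"):
        if key in block:
            kwargs[key] = float(block[key])
    for key in ("deplete_competence", "deplete_speed"):
        if key in block:
            kwargs[key] = bool(block[key])
    kwargs["seed"] = int(seed if seed is not None else block.get("seed", 0))
    return SPhaseModel(**kwargs)
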