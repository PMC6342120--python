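"""End-to-end run orchestration and report assembly.

A run loads a species x trait CSV, builds functional entities, embeds
them in the Gower/PCoA trait space, computes the diversity report,
tests FV and FOR against the constrained null model, and writes a
self-describing output bundle (CSV tables, JSON records, and a manifest
from which the run can be reproduced exactly).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .indices import report_frame, summarize
from .nullmodel import SCHEME, run_null_tests
from .schema import (
    TraitSchema,
    build_entities,
    collapse_schema,
    default_fine_schema,
    load_trait_table,
)
from .space import gower_matrix, pcoa_cailliez, space_quality

log = logging.getLogger("fediv")

__all__ = ["RunConfig", "run", "write_manifest"]

PERCENT_DECIMALS = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input: Path
    outdir: Path
    schema_path: Path | None = None
    axes: int = 4
    n_sims: int = 9999
    seed: int = 0
    collapse: bool = False
    mantel_permutations: int = 999
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.input = Path(self.input)
        self.outdir = Path(self.outdir)
        if self.axes < 2:
            raise ConfigError("axes must be >= 2")
        if self.n_sims < 99:
            raise ConfigError("n_sims must be >= 99")
        if not self.input.exists():
            raise ConfigError(f"input file not found: {self.input}")
        if self.schema_path is not None and not Path(self.schema_path).exists():
            raise ConfigError(f"schema file not found: {self.schema_path}")

    def load_schema(self) -> TraitSchema:
        if self.schema_path is None:
            return default_fine_schema()
        return TraitSchema.from_yaml(self.schema_path)


def _pkg_version() -> str:
    try:
        return metadata.version("fediv")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_manifest(config: RunConfig, outdir: Path, extra: dict | None = None) -> Path:
    manifest = {
        "input": str(config.input),
        "schema": str(config.schema_path) if config.schema_path else "default-fine",
        "axes": config.axes,
        "n_sims": config.n_sims,
        "seed": config.seed,
        "collapse": config.collapse,
        "mantel_permutations": config.mantel_permutations,
        "null_scheme": SCHEME,
        "fediv_version": _pkg_version(),
        "numpy_version": np.__version__,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _analyse(entities, config: RunConfig, outdir: Path, tag: str, seeds) -> dict:
    """One analysis pass (fine or crude); returns raw results for the manifest."""
    prefix = f"{tag}_" if tag else ""
    entities.to_frame().to_csv(outdir / f"{prefix}entities.csv", index=False)

    log.info("[%s] building trait space (%d entities)", tag or "fine", entities.n_entities)
    D = gower_matrix(entities, entities.schema)
    space = pcoa_cailliez(D, m=config.axes)
    quality = space_quality(
        D, space, permutations=config.mantel_permutations, seed=int(seeds[0])
    )
    coords = pd.DataFrame(
        space.coordinates, columns=[f"axis{i + 1}" for i in range(space.m)]
    )
    coords.to_csv(outdir / f"{prefix}coordinates.csv", index=False)
    pd.DataFrame({"eigenvalue": space.eigenvalues}).to_csv(
        outdir / f"{prefix}eigenvalues.csv", index=False
    )
    (outdir / f"{prefix}quality.json").write_text(
        json.dumps(
            {**quality.to_dict(), "cailliez_constant": space.cailliez_constant},
            indent=1,
        )
    )

    log.info("[%s] computing diversity report", tag or "fine")
    reports = summarize(entities, space)
    report_frame(reports, decimals=PERCENT_DECIMALS).to_csv(
        outdir / f"{prefix}diversity.csv", index=False
    )
    (outdir / f"{prefix}diversity.json").write_text(
        json.dumps({"raw": [r.to_dict() for r in reports]}, indent=1, allow_nan=True)
    )

    log.info("[%s] null-model tests (%d sims)", tag or "fine", config.n_sims)
    nulls = run_null_tests(entities, n_sims=config.n_sims, seed=int(seeds[1]))
    rounded = nulls.copy()
    for c in ("observed", "sim_mean", "sim_sd", "ses"):
        rounded[c] = rounded[c].round(3)
    rounded.to_csv(outdir / f"{prefix}nullmodel.csv", index=False)
    (outdir / f"{prefix}nullmodel.json").write_text(
        json.dumps({"raw": nulls.to_dict(orient="records")}, indent=1)
    )
    return {
        f"{prefix}n_entities": entities.n_entities,
        f"{prefix}cailliez_constant": space.cailliez_constant,
        f"{prefix}mSD": quality.msd,
    }


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    schema = config.load_schema()

    log.info("loading %s", config.input)
    records = load_trait_table(config.input, schema)
    entities = build_entities(records, schema)

    # independent reproducible substreams: fine (mantel, null), crude (mantel, null)
    seeds = [s.generate_state(1)[0] % (2**31) for s in np.random.SeedSequence(config.seed).spawn(4)]
    info = _analyse(entities, config, outdir, tag="", seeds=seeds[:2])

    if config.collapse:
        log.info("collapsing trait categories")
        _, crude_entities = collapse_schema(records, schema, entities.assemblages)
        info.update(_analyse(crude_entities, config, outdir, tag="crude", seeds=seeds[2:]))

    write_manifest(config, outdir, extra=info)
    log.info("run complete: %s", outdir)
    return outdir
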