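"""End-to-end pipeline orchestration and run manifests.

``run_pipeline`` executes generate (optional) → concentration resolution →
ledger → balances → flow matrices → vulnerability → correlations and
writes every output as CSV plus a JSON manifest (config hash, seed, input
digests, toggles, per-stage row counts).  Identical manifests imply
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os

import pandas as pd
import yaml

from . import __version__
from .accounting import DEFAULT_RNI, build_ledger
from .balances import balance_table, classification_table
from .concentrations import resolve_all
from .flows import aggregate_flows, export_sankey_table, yield_by_category
from .io import FLOAT_FORMAT, write_csv
from .nutrients import FLOW_NUTRIENTS, NUTRIENTS
from .synth import World, WorldConfig, generate_world
from .vulnerability import (
    balance_correlations,
    compute_vulnerability_table,
    screen_correlations,
)


@dataclasses.dataclass
class PipelineConfig:
    """Run-level toggles plus either a generation block or an input dir."""

    world: WorldConfig
    foc_adjusted: bool = True
    include_high_seas: bool = True
    fish_dependence_threshold: float | None = None
    climate: bool = True
    rni: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RNI)
    )

    @classmethod
    def from_yaml(cls, path: str, seed: int | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        wc = raw.get("world", {})
        if "year_range" in wc:
            wc["year_range"] = tuple(wc["year_range"])
        if "rw_sigma_range" in wc:
            wc["rw_sigma_range"] = tuple(wc["rw_sigma_range"])
        if seed is not None:
            wc["seed"] = seed
        world = WorldConfig(**wc)
        world.validate()
        rni = dict(DEFAULT_RNI)
        rni.update(raw.get("rni", {}))
        return cls(
            world=world,
            foc_adjusted=raw.get("foc_adjusted", True),
            include_high_seas=raw.get("include_high_seas", True),
            fish_dependence_threshold=raw.get("fish_dependence_threshold"),
            climate=raw.get("climate", True),
            rni=rni,
        )


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(
    config: PipelineConfig, out_dir: str, world: World | None = None
) -> dict:
    """Run the full analysis into ``out_dir``; returns the manifest."""
    os.makedirs(out_dir, exist_ok=True)
    if world is None:
        world = generate_world(config.world)
    world.write_dir(out_dir)
    rni_df = pd.DataFrame(
        {"nutrient": list(NUTRIENTS), "rni_per_day": [config.rni[n] for n in NUTRIENTS]}
    )
    write_csv(rni_df, os.path.join(out_dir, "rni.csv"))

    conc = resolve_all(world.taxa, world.catch, focal_year=world.focal_year)
    conc.audit.to_csv(
        os.path.join(out_dir, "concentration_audit.csv"),
        index=False, float_format=FLOAT_FORMAT,
    )

    ledger = build_ledger(world, conc, rni=config.rni, foc_mode=config.foc_adjusted)
    write_csv(ledger.df, os.path.join(out_dir, "ledger.csv"))

    balances = balance_table(ledger, include_high_seas=config.include_high_seas)
    write_csv(balances, os.path.join(out_dir, "balances.csv"))
    classification = classification_table(balances)
    classification.to_csv(
        os.path.join(out_dir, "classification.csv"),
        index=False, float_format=FLOAT_FORMAT,
    )

    flow_rows = []
    for nutrient in FLOW_NUTRIENTS:
        for channel in ("foreign_fishing", "trade"):
            mat = aggregate_flows(
                ledger, world.indicators, nutrient, channel,
                fish_dependence_filter=config.fish_dependence_threshold,
            )
            tidy = export_sankey_table(mat)
            tidy.insert(0, "channel", channel)
            tidy.insert(0, "nutrient", nutrient)
            flow_rows.append(tidy)
    flows_df = pd.concat(flow_rows, ignore_index=True)
    flows_df.to_csv(
        os.path.join(out_dir, "flows.csv"), index=False, float_format=FLOAT_FORMAT
    )

    yield_rows = []
    for nutrient in FLOW_NUTRIENTS:
        for role in ("source", "sink", "sink_eez_only", "exporter", "importer"):
            med = yield_by_category(
                ledger, world.indicators, nutrient, role,
                fish_dependence_filter=config.fish_dependence_threshold,
            )
            for cat, val in med.items():
                yield_rows.append((nutrient, role, cat, val))
    pd.DataFrame(
        yield_rows, columns=["nutrient", "role", "category", "median_yield_pct"]
    ).to_csv(
        os.path.join(out_dir, "category_yields.csv"),
        index=False, float_format=FLOAT_FORMAT,
    )

    vuln = compute_vulnerability_table(world, ledger, climate=config.climate)
    vuln.to_csv(
        os.path.join(out_dir, "vulnerability.csv"),
        index=False, float_format=FLOAT_FORMAT,
    )

    corr = balance_correlations(balances, world.indicators)
    screen = screen_correlations(world.indicators)
    corr.to_csv(
        os.path.join(out_dir, "correlations.csv"),
        index=False, float_format=FLOAT_FORMAT,
    )
    screen.to_csv(
        os.path.join(out_dir, "correlation_screen.csv"),
        index=False, float_format=FLOAT_FORMAT,
    )

    outputs = sorted(
        f for f in os.listdir(out_dir) if f.endswith(".csv")
    )
    manifest = {
        "software_version": __version__,
        "seed": config.world.seed,
        "config_hash": _config_hash(config),
        "toggles": {
            "foc_adjusted": config.foc_adjusted,
            "include_high_seas": config.include_high_seas,
            "fish_dependence_threshold": config.fish_dependence_threshold,
            "climate": config.climate,
        },
        "row_counts": {
            "catch": int(len(world.catch)),
            "trade": int(len(world.trade)),
            "taxa": int(len(world.taxa)),
            "ledger": int(len(ledger.df)),
            "balances": int(len(balances)),
            "flows": int(len(flows_df)),
            "vulnerability": int(len(vuln)),
        },
        "file_digests": {f: _digest(os.path.join(out_dir, f)) for f in outputs},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
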