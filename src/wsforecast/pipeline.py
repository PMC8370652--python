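"""Convenience wiring of the fixture dataset through the forecasting stages."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml

from .gene_models import GeneModelSet, Region, load_gene_table, load_regions
from .pathway_model import NullModelParams, PredictedSpectrum, predict_spectrum
from .synthetic import fixture_path
from .target_enumeration import IndelModel, TargetSizeTable, build_target_table

__all__ = ["load_config", "build_prediction", "fixture_prediction"]


def load_config(config_path: Optional[str | Path] = None) -> dict:
    """Read the structured model config (bundled default when no path given)."""
    path = Path(config_path) if config_path else fixture_path("model_params.yaml")
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def build_prediction(
    config: dict, genes: GeneModelSet, regions: list[Region]
) -> tuple[TargetSizeTable, NullModelParams, PredictedSpectrum]:
    """Targets -> rates -> normalized predicted spectrum, per the config."""
    table = build_target_table(
        genes,
        config.get("constraints") or {},
        regions,
        IndelModel(
            homopolymer_multiplier=float(config.get("homopolymer_multiplier", 1.0))
        ),
        min_repeat_len=int(config.get("min_repeat_len", 6)),
        max_deletion_len=int(config.get("max_deletion_len", 500)),
    )
    params = NullModelParams(
        rates={k: float(v) for k, v in (config.get("rates") or {}).items()},
        hot_spot_multipliers=config.get("hot_spot_multipliers") or {},
        normalization_scope=config.get("normalization_scope", "three_pathways"),
        mu_total=config.get("mu_total"),
        calibration=config.get("calibration") or {},
    )
    return table, params, predict_spectrum(table, params)


def fixture_prediction(
    config_path: Optional[str | Path] = None,
) -> tuple[TargetSizeTable, NullModelParams, PredictedSpectrum]:
    """The bundled gene set under the frozen parameterization."""
    genes = load_gene_table(fixture_path("pf5_genes.tsv"))
    regions = load_regions(fixture_path("pf5_regions.tsv"), genes)
    return build_prediction(load_config(config_path), genes, regions)
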