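"""Reading and writing run configurations (YAML or JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .ecosystem_mdp import EcosystemConfig
from .experiment_sweep import SweepGrid, _grid_range
from .motif_networks import build_motif

__all__ = [
    "load_mapping",
    "config_from_dict",
    "grid_from_dict",
    "example_run_config",
    "example_grid_config",
    "example_case_study_config",
    "write_example_configs",
]


def load_mapping(path: str | Path) -> dict:
    """Parse a YAML or JSON mapping from ``path`` (by extension)."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def config_from_dict(d: dict) -> EcosystemConfig:
    """Build an :class:`EcosystemConfig` from a run-config mapping."""
    motif = d.get("motif", "linear")
    provider = int(d.get("provider", 1))
    if motif == "custom":
        web = build_motif(
            "custom",
            provider,
            edges=[tuple(e) for e in d["edges"]],
            n_species=int(d.get("n_species", 4)),
        )
    else:
        web = build_motif(motif, provider)
    kwargs = {}
    for key in (
        "gamma",
        "objective",
        "service_unit_value",
        "costs",
        "ef_term_mode",
        "protection_mode",
        "normalization_mode",
        "include_no_action",
    ):
        if key in d:
            kwargs[key] = d[key]
    return EcosystemConfig(
        web=web, alpha=float(d["alpha"]), p0=d["p0"], b=float(d["b"]), **kwargs
    )


def _axis(value) -> tuple[float, ...]:
    if isinstance(value, dict):
        return _grid_range(float(value["start"]), float(value["stop"]), float(value["step"]))
    return tuple(round(float(v), 10) for v in value)


def grid_from_dict(d: dict) -> SweepGrid:
    """Build a :class:`SweepGrid` from a grid-config mapping."""
    kwargs = {}
    if "motifs" in d:
        kwargs["motifs"] = tuple(d["motifs"])
    if "trophic_levels" in d:
        kwargs["trophic_levels"] = tuple(int(v) for v in d["trophic_levels"])
    for name in ("alphas", "p0s", "bs"):
        if name in d:
            kwargs[name] = _axis(d[name])
    for name in (
        "gamma",
        "ef_term_mode",
        "protection_mode",
        "normalization_mode",
        "cost_per_trophic_rank",
    ):
        if name in d:
            kwargs[name] = d[name]
    return SweepGrid(**kwargs)


def example_run_config() -> dict:
    """One fully specified configuration (the peak-EVPI neighbourhood)."""
    return {
        "motif": "omnivory",
        "provider": 4,
        "alpha": 0.8,
        "p0": 0.8,
        "b": 0.9,
        "gamma": 0.997,
        "objective": "service",
        "service_unit_value": 1.0,
        "ef_term_mode": "shared",
        "protection_mode": "prey_limited",
        "normalization_mode": "baseline",
    }


def example_grid_config() -> dict:
    """The standard factorial grids, written out explicitly."""
    return {
        "motifs": list(SweepGrid().motifs),
        "trophic_levels": [1, 2, 3, 4],
        "alphas": {"start": 0.1, "stop": 0.8, "step": 0.1},
        "p0s": {"start": 0.1, "stop": 0.9, "step": 0.1},
        "bs": {"start": 0.1, "stop": 0.9, "step": 0.1},
        "gamma": 0.997,
        "ef_term_mode": "shared",
        "protection_mode": "prey_limited",
        "normalization_mode": "baseline",
        "cost_per_trophic_rank": 0.0,
    }


def example_case_study_config() -> dict:
    """A synthetic salt-marsh-style case study with placeholder survival rates.

    The functional-group labels follow the salt-marsh application (algae,
    snails, shrimps, fish, ...), but every baseline survival probability here
    is a synthetic placeholder, not an empirical estimate.
    """
    return {
        "objective": "service",
        "gamma": 0.997,
        "alpha_grid": {"start": 0.1, "stop": 0.8, "step": 0.01},
        "b_grid": {"start": 0.1, "stop": 0.9, "step": 0.01},
        "motifs": [
            {
                "label": "algae-snails-shrimps-fish (synthetic p0)",
                "motif": "omnivory",
                "p0": [0.8, 0.7, 0.6, 0.5],
                "providers": [1, 4],
            },
            {
                "label": "plants-insects-birds-raptors (synthetic p0)",
                "motif": "linear",
                "p0": [0.85, 0.7, 0.55, 0.45],
                "providers": [1, 3],
            },
        ],
    }


def write_example_configs(directory: str | Path) -> list[Path]:
    """Write documented example config files; returns the paths written."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for name, payload in (
        ("example_run_config.yaml", example_run_config()),
        ("example_sweep_grid.yaml", example_grid_config()),
        ("example_case_study_synthetic.yaml", example_case_study_config()),
    ):
        path = d / name
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        written.append(path)
    return written
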