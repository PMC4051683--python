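"""Run configuration: YAML schema, validation, and defaults.

A run config describes one sample (composition + file paths + analysis
options).  Validation is strict and returns every problem it finds as a
structured error list rather than a partially-built config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .composition import (MembraneComposition, MolecularSpecies, parse_formula,
                          registry_species)

__all__ = ["RunConfig", "AnalysisOptions", "ConfigError", "validate_config",
           "config_errors", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class AnalysisOptions:
    lorentz_exponent: float = 1.0
    max_order: int = 10
    grid_points: int = 1024
    k_components: int = 4
    center_density: float = 0.22
    center_density_scan: tuple[float, float, int] | None = None
    signs: list[int] | None = None
    pose_z_step: float = 0.5
    pose_angle_step: float = 15.0
    embedded_boundary: float = 14.0
    fwhm: float = 4.0
    d_hint: float | None = None


@dataclass
class RunConfig:
    name: str
    composition: MembraneComposition
    seed: int
    files: dict[str, object] = field(default_factory=dict)
    options: AnalysisOptions = field(default_factory=AnalysisOptions)
    output_dir: Path = Path("memdiff_out")


def _resolve_species(name: str, entry, errors: list[str],
                     custom: dict[str, MolecularSpecies]):
    if name in custom:
        return custom[name]
    try:
        return registry_species(name)
    except KeyError:
        errors.append(f"unknown species {name!r} and no formula given "
                      f"under sample.species")
        return None


def validate_config(text_or_dict) -> RunConfig:
    """Parse and validate a YAML config; raises :class:`ConfigError`
    carrying the full structured error list on any problem."""
    errors = config_errors(text_or_dict)
    if errors:
        raise ConfigError(errors)
    return _build(_as_dict(text_or_dict))


def config_errors(text_or_dict) -> list[str]:
    """All validation problems of a config, as human-readable strings."""
    try:
        raw = _as_dict(text_or_dict)
    except Exception as exc:
        return [f"not valid YAML: {exc}"]
    errors: list[str] = []
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    if "seed" not in raw:
        errors.append("missing required key 'seed' (every random operation is seeded)")
    elif not isinstance(raw["seed"], int):
        errors.append("'seed' must be an integer")
    sample = raw.get("sample")
    if not isinstance(sample, dict):
        errors.append("missing 'sample' block")
        return errors
    custom: dict[str, MolecularSpecies] = {}
    for entry in sample.get("species", []) or []:
        try:
            sp = MolecularSpecies(entry["name"], parse_formula(entry["formula"]),
                                  molar_mass=float(entry.get("molar_mass", 0.0)))
            custom[sp.name] = sp
        except Exception as exc:
            errors.append(f"bad custom species entry {entry!r}: {exc}")
    lipids = sample.get("lipids")
    if not isinstance(lipids, dict) or not lipids:
        errors.append("sample.lipids must map species name -> mole fraction")
    else:
        total = sum(lipids.values())
        if abs(total - 1.0) > 1e-9:
            errors.append(f"lipid mole fractions sum to {total}, expected 1")
        for name in lipids:
            _resolve_species(name, None, errors, custom)
    for name in (sample.get("additives") or {}):
        _resolve_species(name, None, errors, custom)
    wpl = sample.get("waters_per_lipid", 0.0)
    if not isinstance(wpl, (int, float)) or wpl < 0:
        errors.append("sample.waters_per_lipid must be a non-negative number")
    apl = sample.get("area_per_lipid", 60.6)
    if not isinstance(apl, (int, float)) or apl <= 0:
        errors.append("sample.area_per_lipid must be positive")
    opts = raw.get("analysis", {}) or {}
    known = set(AnalysisOptions.__dataclass_fields__)
    for key in opts:
        if key not in known:
            errors.append(f"unknown analysis option {key!r}")
    if "signs" in opts and opts["signs"] is not None:
        if any(s not in (-1, 1) for s in opts["signs"]):
            errors.append("analysis.signs entries must be -1 or +1")
    k = opts.get("k_components", 4)
    if not 1 <= int(k) <= 6:
        errors.append("analysis.k_components must be between 1 and 6")
    files = raw.get("files", {}) or {}
    if not isinstance(files, dict):
        errors.append("'files' must be a mapping")
    else:
        for key, val in files.items():
            paths = val if isinstance(val, list) else [val]
            for p in paths:
                if not Path(p).exists():
                    errors.append(f"files.{key}: path {p!r} does not exist")
    return errors


def _as_dict(text_or_dict) -> dict:
    if isinstance(text_or_dict, dict):
        return text_or_dict
    return yaml.safe_load(text_or_dict)


def _build(raw: dict) -> RunConfig:
    sample = raw["sample"]
    custom: dict[str, MolecularSpecies] = {}
    for entry in sample.get("species", []) or []:
        sp = MolecularSpecies(entry["name"], parse_formula(entry["formula"]),
                              molar_mass=float(entry.get("molar_mass", 0.0)))
        custom[sp.name] = sp

    def species(name):
        return custom.get(name) or registry_species(name)

    comp = MembraneComposition(
        lipid_fractions=tuple((species(n), float(f))
                              for n, f in sample["lipids"].items()),
        additives=tuple((species(n), float(r))
                        for n, r in (sample.get("additives") or {}).items()),
        waters_per_lipid=float(sample.get("waters_per_lipid", 0.0)),
        area_per_lipid=float(sample.get("area_per_lipid", 60.6)),
        lamellar_spacing=float(sample.get("lamellar_spacing", 55.0)),
    )
    opts_raw = dict(raw.get("analysis", {}) or {})
    scan = opts_raw.pop("center_density_scan", None)
    options = AnalysisOptions(**opts_raw)
    if scan is not None:
        options.center_density_scan = (float(scan[0]), float(scan[1]), int(scan[2]))
    return RunConfig(
        name=str(sample.get("name", raw.get("name", "sample"))),
        composition=comp,
        seed=int(raw["seed"]),
        files={k: v for k, v in (raw.get("files", {}) or {}).items()},
        options=options,
        output_dir=Path(raw.get("output_dir", "memdiff_out")),
    )


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())
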