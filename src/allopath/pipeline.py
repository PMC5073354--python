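"""Declarative orchestration of the full analysis.

A :class:`RunConfig` is a flat, typed, sectioned mapping (YAML on disk) with
every module parameter defaulted to the values used throughout: 0.5 Angstrom
deviation threshold over >= 3 residues, 1.4 Angstrom probe, 15 Angstrom
network cutoff, projection modes 7-11, 100-mode cross-correlation,
+0.78/-1.0 frustration thresholds. Unknown keys are rejected before any
computation, and the fully resolved config is echoed into the report for
provenance. Stages run in dependency order; a failed stage is recorded and
independent stages still run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clash as clash_mod
from . import ensemble_compare as compare_mod
from . import frustration as frustration_mod
from . import interface as interface_mod
from . import modes as modes_mod
from .errors import ConfigError, EmptyInputError
from .structio import Ensemble, Selection, Structure, read_pdb

# section -> key -> (type, default); None default = optional/unset
_SCHEMA: dict = {
    "inputs": {
        "complex_pdb": (str, None),
        "query_pdb": (str, None),
        "reference_pdb": (str, None),
        "third_pdb": (str, None),
        "apo_structure_pdb": (str, None),
        "apo_ensemble_pdb": (str, None),
        "holo_ensemble_pdb": (str, None),
    },
    "sides": {
        "receptor": (str, "chain A"),
        "ligand": (str, "chain I"),
    },
    "sites": {
        "exosite": (list, [25, 77]),
        "active_site": (list, [57, 102, 195]),
    },
    "interface": {
        "probe_radius": (float, 1.4),
        "n_points": (int, 960),
        "hbond_d_max": (float, 3.5),
        "hbond_angle_min": (float, 90.0),
        "bridge_d_max": (float, 4.0),
    },
    "compare": {
        "threshold": (float, 0.5),
        "min_len": (int, 3),
        "alpha": (float, 0.05),
    },
    "modes": {
        "cutoff": (float, 15.0),
        "gamma": (float, 1.0),
        "n_modes": (int, 100),
        "projection_modes": (list, [7, 8, 9, 10, 11]),
        "dcc_modes": (int, 100),
        "variance_k": (int, 5),
    },
    "frustration": {
        "cutoff": (float, 9.5),
        "min_seq_sep": (int, 3),
        "n_decoys": (int, 1000),
        "minimal_threshold": (float, 0.78),
        "high_threshold": (float, -1.0),
    },
    "clash": {
        "overlap_min": (float, 0.4),
    },
    "seed": (int, 1),
}


@dataclass
class RunConfig:
    data: dict

    def __getitem__(self, section):
        return self.data[section]

    @property
    def seed(self) -> int:
        return self.data["seed"]

    def hash(self) -> str:
        canon = json.dumps(self.data, sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


def _coerce(value, expected_type, where):
    if value is None:
        return None
    if expected_type is float and isinstance(value, int):
        return float(value)
    if not isinstance(value, expected_type):
        raise ConfigError(
            f"{where}: expected {expected_type.__name__}, got "
            f"{type(value).__name__} ({value!r})"
        )
    return value


def resolve_config(raw: dict | None = None) -> RunConfig:
    """Validate a raw mapping against the schema and materialize defaults."""
    raw = dict(raw or {})
    resolved: dict = {}
    for section, spec in _SCHEMA.items():
        if section == "seed":
            expected_type, default = spec
            resolved["seed"] = _coerce(raw.pop("seed", default),
                                       expected_type, "seed")
            continue
        given = raw.pop(section, {}) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        out = {}
        for key, (expected_type, default) in spec.items():
            out[key] = _coerce(given.pop(key, default), expected_type,
                               f"{section}.{key}")
        if given:
            raise ConfigError(
                f"unknown keys in section {section!r}: {sorted(given)}"
            )
        resolved[section] = out
    if raw:
        raise ConfigError(f"unknown config sections: {sorted(raw)}")
    return RunConfig(resolved)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return resolve_config(raw)


def site_distance(s: Structure, site_a, site_b, mode: str = "min") -> float:
    """Minimum (or centroid) atom distance between two residue/atom sites.

    Site items may be residue numbers, residue keys (chain, seq, icode), or
    (chain, seq, icode, atom_name) atom keys.
    """
    def resolve(site):
        if not site:
            raise EmptyInputError("empty site set")
        idx = []
        for item in site:
            if isinstance(item, (tuple, list)) and len(item) == 4:
                idx += [i for i, a in enumerate(s.atoms)
                        if a.atom_key == tuple(item)]
            elif isinstance(item, (tuple, list)):
                idx += [i for i, a in enumerate(s.atoms)
                        if a.residue_key == tuple(item)]
            else:
                idx += [i for i, a in enumerate(s.atoms)
                        if a.res_seq == int(item)]
        if not idx:
            raise EmptyInputError(f"site {site!r} resolved to no atoms")
        return s.coords[sorted(set(idx))]

    xa, xb = resolve(site_a), resolve(site_b)
    if mode == "min":
        d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
        return float(d.min())
    if mode == "centroid":
        return float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    raise ValueError("mode must be 'min' or 'centroid'")


@dataclass
class AnalysisReport:
    config: dict
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def stage(self, name):
        if name in self.errors:
            raise self.errors[name]
        return self.stages.get(name)


def _load_structure(path) -> Structure:
    obj = read_pdb(path)
    if isinstance(obj, Ensemble):
        return obj.frame_structure(0)
    return obj


def _load_ensemble(path) -> Ensemble:
    obj = read_pdb(path)
    if isinstance(obj, Ensemble):
        return obj
    return Ensemble(obj, [obj.coords])


def run_all(cfg: RunConfig) -> AnalysisReport:
    """Execute every stage whose inputs are configured.

    Order: interface -> compare -> modes (+projection/shift, DCC) ->
    frustration (+path) -> clash. Stage failures are recorded in
    ``report.errors`` without aborting independent stages.
    """
    report = AnalysisReport(config=cfg.data, config_hash=cfg.hash(),
                            seed=cfg.seed)
    inputs = cfg["inputs"]
    receptor_sel = Selection.parse(cfg["sides"]["receptor"])
    ligand_sel = Selection.parse(cfg["sides"]["ligand"])

    def run_stage(name, condition, fn):
        if not condition:
            return
        try:
            report.stages[name] = fn()
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            report.errors[name] = exc

    # --- interface ---------------------------------------------------------
    def interface_stage():
        complex_structure = _load_structure(inputs["complex_pdb"])
        p = cfg["interface"]
        return interface_mod.interface_report(
            complex_structure, receptor_sel, ligand_sel,
            probe=p["probe_radius"], n_points=p["n_points"],
            hbond_d_max=p["hbond_d_max"], hbond_angle_min=p["hbond_angle_min"],
            bridge_d_max=p["bridge_d_max"],
        )

    run_stage("interface", inputs["complex_pdb"], interface_stage)

    # --- structural comparison ---------------------------------------------
    def compare_stage():
        query = _load_structure(inputs["query_pdb"] or inputs["complex_pdb"])
        reference = _load_structure(inputs["reference_pdb"])
        third = _load_structure(inputs["third_pdb"])
        p = cfg["compare"]
        return compare_mod.compare_structures(
            query, reference, third,
            threshold=p["threshold"], min_len=p["min_len"], alpha=p["alpha"],
        )

    run_stage(
        "compare",
        (inputs["query_pdb"] or inputs["complex_pdb"])
        and inputs["reference_pdb"] and inputs["third_pdb"],
        compare_stage,
    )

    # --- elastic-network modes ---------------------------------------------
    mode_set = None
    if inputs["apo_structure_pdb"]:
        p = cfg["modes"]

        def modes_stage():
            nonlocal mode_set
            apo = _load_structure(inputs["apo_structure_pdb"])
            mode_set = modes_mod.compute_modes(
                apo, cutoff=p["cutoff"], gamma=p["gamma"],
                n_modes=p["n_modes"],
            )
            return {
                "mode_set": mode_set,
                "variance_fraction": modes_mod.variance_fraction(
                    mode_set, p["variance_k"]
                ),
                "msf": modes_mod.mode_fluctuations(mode_set),
            }

        run_stage("modes", True, modes_stage)

        def dcc_stage():
            return modes_mod.dcc(mode_set, n_modes=p["dcc_modes"])

        run_stage("dcc", mode_set is not None, dcc_stage)

        def projection_stage():
            apo_e = _load_ensemble(inputs["apo_ensemble_pdb"])
            holo_e = _load_ensemble(inputs["holo_ensemble_pdb"])
            numbers = [int(m) for m in p["projection_modes"]]
            p_apo = modes_mod.project_ensemble(apo_e, mode_set, numbers)
            p_holo = modes_mod.project_ensemble(holo_e, mode_set, numbers)
            return {
                "apo": p_apo,
                "holo": p_holo,
                "shifts": modes_mod.population_shift(p_apo, p_holo),
            }

        run_stage(
            "projection",
            mode_set is not None and inputs["apo_ensemble_pdb"]
            and inputs["holo_ensemble_pdb"],
            projection_stage,
        )

    # --- frustration --------------------------------------------------------
    def frustration_stage():
        apo = _load_structure(inputs["apo_structure_pdb"])
        p = cfg["frustration"]
        net = frustration_mod.compute_network(
            apo, cutoff=p["cutoff"], min_seq_sep=p["min_seq_sep"],
            n_decoys=p["n_decoys"], seed=cfg.seed,
            minimal_threshold=p["minimal_threshold"],
            high_threshold=p["high_threshold"],
        )
        path = frustration_mod.frustration_path(
            net, cfg["sites"]["exosite"], cfg["sites"]["active_site"]
        )
        return {"network": net, "path": path}

    run_stage("frustration", inputs["apo_structure_pdb"], frustration_stage)

    # --- clash screening ----------------------------------------------------
    def clash_stage():
        reference_complex = _load_structure(inputs["complex_pdb"])
        ensemble = _load_ensemble(
            inputs["holo_ensemble_pdb"] or inputs["apo_ensemble_pdb"]
        )
        return clash_mod.clash_timecourse(
            ensemble, reference_complex, receptor_sel, ligand_sel,
            overlap_min=cfg["clash"]["overlap_min"],
        )

    run_stage(
        "clash",
        inputs["complex_pdb"]
        and (inputs["holo_ensemble_pdb"] or inputs["apo_ensemble_pdb"]),
        clash_stage,
    )
    return report
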