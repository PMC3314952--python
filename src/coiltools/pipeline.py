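"""Reproducible multi-stage runs.

A :class:`RunConfig` names an output directory, a seed and an ordered list of
stages with their parameters. ``run_pipeline`` executes the stages in order,
writes every product in the package's TSV/JSON dialects, echoes the config
next to the outputs and logs package version, config hash and the property /
random-coil table labels, so a run can be reproduced from its output
directory alone. All randomness flows through the single run seed: stage k
draws from ``seed + k`` (stable against stage reordering-free edits).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import ConfigError
from .hydrodynamics import SedimentationRecord
from .relaxation import R2Profile, detect_clusters, fit_scale_factor
from .sequence import HelixRegions, ResiduePropertyTable, load_sequence
from .shifts import (RandomCoilReference, ShiftTable, random_coil_shifts,
                     region_helicity, secondary_shifts, ssp_profile)
from .stability import (DenaturationCurve, NoTransitionError, fit_two_state,
                        gamma_value, helical_content)
from .couplings import j_from_hnha
from .synthetic import SimulationSpec, simulate, unfolded_im7_variant

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "r2-baseline", "clusters", "ssp", "jcoupling", "hydro",
           "unfold-fit", "helicity", "gamma")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: str
    seed: int = 0
    stages: list = field(default_factory=list)

    _KEYS = {"output_dir", "seed", "stages"}

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        unknown = set(payload) - cls._KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in payload:
            raise ConfigError("config requires 'output_dir'")
        stages = payload.get("stages", [])
        for stage in stages:
            if set(stage) - {"name", "params"}:
                raise ConfigError(f"unknown stage keys in {stage}")
            if stage.get("name") not in _STAGES:
                raise ConfigError(
                    f"unknown stage {stage.get('name')!r}; choose from {_STAGES}")
        return cls(output_dir=payload["output_dir"],
                   seed=int(payload.get("seed", 0)), stages=list(stages))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as handle:
            return cls.from_dict(json.load(handle))

    def to_dict(self) -> dict:
        return {"output_dir": self.output_dir, "seed": self.seed,
                "stages": self.stages}


def _provenance(config: RunConfig, params: dict) -> dict:
    digest = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]
    return {"package_version": __version__, "config_sha256": digest,
            "seed": config.seed, "params": params}


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


def _load_sequence(params: dict):
    if "sequence_fasta" in params:
        return load_sequence(params["sequence_fasta"],
                             first_index=int(params.get("first_index", 1)),
                             tag_length=int(params.get("tag_length", 0)))
    return unfolded_im7_variant()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns {stage: output paths}.

    Any stage error aborts the run with the stage name and offending input in
    the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = ResiduePropertyTable.default()
    reference = RandomCoilReference.default()
    logger.info("coiltools %s | property table: %s | random-coil table: %s",
                __version__, table.label, reference.label)
    _write_json(out / "config.json", config.to_dict())

    results: dict[str, list[str]] = {}
    for k, stage in enumerate(config.stages):
        name = stage["name"]
        params = dict(stage.get("params", {}))
        stage_seed = config.seed + k
        try:
            results[name] = _run_stage(name, params, stage_seed, out, config,
                                       table, reference)
        except FileNotFoundError as exc:
            raise ConfigError(f"stage {name!r}: missing input file: {exc}") from exc
        except Exception as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
    return results


def _run_stage(name, params, seed, out: Path, config, table, reference):
    produced: list[str] = []

    def emit(filename: str) -> Path:
        path = out / filename
        produced.append(str(path))
        return path

    if name == "simulate":
        kind = params.pop("kind", "r2")
        spec = SimulationSpec(seed=seed, kind=kind, params=params)
        spec.to_json(emit(f"simulate_{kind}_spec.json"))
        data = simulate(spec)
        if kind == "r2":
            observed, baseline, truth = data
            observed.to_tsv(emit("r2_observed.tsv"))
            baseline.to_tsv(emit("r2_true_baseline.tsv"))
            _write_json(emit("r2_truth.json"),
                        {"clusters": truth, **_provenance(config, params)})
        elif kind == "shifts":
            data.to_tsv(emit("shifts_observed.tsv"))
        elif kind == "denaturation":
            data.to_tsv(emit("denaturation.tsv"))
        else:  # hnha / decay frames
            from .io import write_tsv
            write_tsv(emit(f"{kind}.tsv"), data, {"seed": seed})
    elif name == "r2-baseline":
        observed = R2Profile.from_tsv(params.get("observed",
                                                 out / "r2_observed.tsv"))
        seq = _load_sequence(params)
        scale, baseline = fit_scale_factor(observed, seq, table,
                                           exclude=params.get("exclude"))
        baseline.conditions["fitted_scale"] = scale
        baseline.to_tsv(emit("r2_baseline.tsv"))
        _write_json(emit("r2_scale.json"),
                    {"scale": scale, **_provenance(config, params)})
    elif name == "clusters":
        observed = R2Profile.from_tsv(params.get("observed",
                                                 out / "r2_observed.tsv"))
        baseline = R2Profile.from_tsv(params.get("baseline",
                                                 out / "r2_baseline.tsv"))
        calls = detect_clusters(observed, baseline,
                                min_run=int(params.get("min_run", 3)),
                                z=float(params.get("z", 2.0)))
        payload = {"clusters": [vars(c) for c in calls],
                   **_provenance(config, params)}
        truth_path = out / "r2_truth.json"
        if truth_path.exists():
            with open(truth_path, encoding="utf-8") as handle:
                truth = json.load(handle)["clusters"]
            centers = [c.center for c in calls]
            payload["truth_centers"] = [t[0] for t in truth]
            payload["recovered"] = [
                any(abs(c - t[0]) <= 1 for c in centers) for t in truth]
        _write_json(emit("clusters.json"), payload)
    elif name == "ssp":
        observed = ShiftTable.from_tsv(params["shifts"] if "shifts" in params
                                       else out / "shifts_observed.tsv")
        seq = _load_sequence(params)
        coil = random_coil_shifts(seq, reference,
                                  nuclei=tuple(params.get("nuclei",
                                                          ("CA", "CB"))))
        deltas = secondary_shifts(observed, coil)
        profile = ssp_profile(deltas, window=int(params.get("window", 5)))
        helicity = region_helicity(profile, HelixRegions())
        from .io import write_tsv
        import pandas as pd
        write_tsv(emit("ssp.tsv"),
                  pd.DataFrame({"residue_index": profile.residues,
                                "ssp": profile.scores}),
                  {"window": profile.window,
                   "nuclei": ",".join(profile.nuclei)})
        _write_json(emit("region_helicity.json"),
                    {"percent_helix": helicity, **_provenance(config, params)})
    elif name == "jcoupling":
        from .io import read_tsv, write_tsv
        frame, _ = read_tsv(params["intensities"] if "intensities" in params
                            else out / "hnha.tsv")
        records = [
            j_from_hnha(row.i_cross, row.i_diag,
                        delta=float(params.get("delta", 0.01254)),
                        noise=float(row.noise), residue=int(row.residue_index))
            for row in frame.itertuples()]
        import pandas as pd
        write_tsv(emit("jcouplings.tsv"), pd.DataFrame(
            {"residue_index": [r.residue for r in records],
             "j_Hz": [r.j for r in records],
             "sigma_j_Hz": [r.sigma_j for r in records],
             "class": [r.conformation for r in records]}))
    elif name == "hydro":
        record = SedimentationRecord.from_json(params["record"]).analyze()
        payload = json.loads(record.to_json())
        payload.update(_provenance(config, params))
        _write_json(emit("hydrodynamics.json"), payload)
    elif name == "unfold-fit":
        curve = DenaturationCurve.from_tsv(
            params["curve"] if "curve" in params else out / "denaturation.tsv")
        try:
            fit = fit_two_state(curve,
                                normalize=bool(params.get("normalize", False)))
            payload = {"dg_unfold_kJmol": fit.dg, "dg_fold_kJmol": fit.dg_fold,
                       "m_value_kJmolM": fit.m_value,
                       "midpoint_M": fit.midpoint,
                       "baselines": {"a": fit.a, "b": fit.b,
                                     "c": fit.c, "d": fit.d},
                       "errors": fit.errors}
        except NoTransitionError as exc:
            payload = {"transition": False, "reason": str(exc)}
        payload.update(_provenance(config, params))
        _write_json(emit("two_state_fit.json"), payload)
    elif name == "helicity":
        percent = helical_content(float(params["mre_variant_222"]),
                                  float(params["mre_wt_222"]))
        _write_json(emit("helicity.json"),
                    {"percent_helix": percent, **_provenance(config, params)})
    elif name == "gamma":
        result = gamma_value(float(params["l_sample"]),
                             float(params["l_control"]))
        _write_json(emit("gamma.json"),
                    {"gamma": result.gamma, **_provenance(config, params)})
    else:  # pragma: no cover - guarded by RunConfig validation
        raise ConfigError(f"unknown stage {name!r}")
    return produced
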