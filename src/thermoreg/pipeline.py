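"""End-to-end driver: four CSVs in, one structured report bundle out.

Stages: ingest → preferred ranges (with the sex-pooling check) →
thermoregulation indices with bootstrap CIs (both species) → habitat
suitability profiling and thermal grouping → selection-versus-availability
tests.  The bundle is a versioned JSON report plus tidy CSV tables.
Output is a pure function of (input files, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import io as tio
from .habitat import (
    classify_thermal_groups,
    compare_microhabitat_te,
    filter_window,
    profiles_to_frame,
    suitability_profile,
)
from .indices import bootstrap_indices
from .ptr import estimate_ptr, sex_pooling_check
from .selection import (
    AVAILABILITY_LABEL,
    frequency_selection_test,
    microhabitat_counts,
    used_vs_available,
)
from .synthetic import StudyData

__all__ = ["run_pipeline", "write_study", "DEFAULT_CONFIG", "SCHEMA_VERSION"]

log = logging.getLogger("thermoreg.pipeline")

SCHEMA_VERSION = 1

DEFAULT_CONFIG: dict = {
    "species": [],  # exactly two labels, required
    "inputs": {},  # kind -> path; tpref/body/operative required
    "column_maps": {},  # kind -> {canonical: actual header}
    "ptr": {"q_low": 0.25, "q_high": 0.75, "by_individual": False},
    "bootstrap": {"n_iter": 100, "seed": 42, "ci_level": 0.95,
                  "ci_method": "percentile"},
    "activity_window": [8, 18],
    "alpha": 0.05,
    "selection_variables": ["ta_c", "ts_c", "refuge_cm", "height_cm"],
}


class PipelineError(RuntimeError):
    """A stage failed; the stage name is part of the message."""


def _merge(default: Mapping, override: Optional[Mapping]) -> dict:
    out = dict(default)
    for k, v in (override or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="index"))
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj


def _validate(cfg: dict) -> None:
    species = cfg.get("species") or []
    if len(species) != 2:
        raise PipelineError(f"config: exactly two species required, got {species}")
    inputs = cfg.get("inputs") or {}
    for kind in ("tpref", "body", "operative"):
        if kind not in inputs:
            raise PipelineError(f"config: inputs.{kind} is required")
        if not Path(inputs[kind]).exists():
            raise PipelineError(f"config: inputs.{kind} not found: {inputs[kind]}")
    for kind in ("availability", "counts"):
        if kind in inputs and not Path(inputs[kind]).exists():
            raise PipelineError(f"config: inputs.{kind} not found: {inputs[kind]}")


def run_pipeline(config: Mapping, outdir) -> dict:
    """Run the whole analysis; write the bundle under ``outdir``.

    Returns the report dict (also written as ``report.json``).  Raises
    :class:`PipelineError` naming the failing stage.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    outdir = Path(outdir)
    _validate(cfg)
    outdir.mkdir(parents=True, exist_ok=True)
    species = list(cfg["species"])
    report: dict = {"schema_version": SCHEMA_VERSION, "species": species,
                    "config": _jsonify(cfg), "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return deco

    # ------------------------------------------------------------------ load
    @stage("load")
    def data():
        maps = cfg["column_maps"]
        inputs = cfg["inputs"]
        out = {
            "tpref": tio.read_records(inputs["tpref"], "tpref",
                                      column_map=maps.get("tpref")),
            "body": tio.read_records(inputs["body"], "body",
                                     column_map=maps.get("body")),
            "operative": tio.read_records(inputs["operative"], "operative",
                                          column_map=maps.get("operative")),
        }
        if "availability" in inputs:
            out["availability"] = tio.read_records(
                inputs["availability"], "availability",
                column_map=maps.get("availability"))
        if "counts" in inputs:
            out["counts"] = tio.read_records(inputs["counts"], "counts",
                                             column_map=maps.get("counts"))
        return out

    for label in species:
        if not any(m.species == label for m in data["tpref"]):
            raise PipelineError(f"stage 'load' failed: no gradient-trial rows "
                                f"for species {label!r}")

    # ------------------------------------------------------------------- ptr
    @stage("ptr")
    def ptr_stage():
        pcfg = cfg["ptr"]
        out = {}
        for label in species:
            ms = [m for m in data["tpref"] if m.species == label]
            pooling = sex_pooling_check(ms, alpha=cfg["alpha"])
            ptr = estimate_ptr(ms, pcfg["q_low"], pcfg["q_high"],
                               by_individual=pcfg["by_individual"])
            out[label] = {"ptr": ptr, "sex_pooling": pooling}
        return out

    ptrs = {label: ptr_stage[label]["ptr"] for label in species}
    report["stages"]["ptr"] = _jsonify(ptr_stage)

    # --------------------------------------------------------------- indices
    window = tuple(cfg["activity_window"])

    @stage("indices")
    def indices_stage():
        bcfg = cfg["bootstrap"]
        te_day = [r.te_c for r in filter_window(data["operative"], window)]
        out = {}
        for label in species:
            tb = [r.tb_c for r in data["body"] if r.species == label]
            if not tb:
                raise PipelineError(f"no field body temperatures for {label!r}")
            out[label] = bootstrap_indices(
                tb, te_day, ptrs[label],
                n_iter=bcfg["n_iter"], seed=bcfg["seed"],
                ci_level=bcfg["ci_level"], ci_method=bcfg["ci_method"],
            )
        return out

    report["stages"]["indices"] = _jsonify(indices_stage)

    # --------------------------------------------------------------- habitat
    @stage("habitat")
    def habitat_stage():
        te_day = filter_window(data["operative"], window)
        suitability = {}
        for label in species:
            profiles = suitability_profile(te_day, ptrs[label],
                                           group_by="microhabitat")
            frame = profiles_to_frame(profiles)
            frame.insert(0, "species", label)
            suitability[label] = frame
        comparison = compare_microhabitat_te(te_day, alpha=cfg["alpha"])
        # the species with the narrower preferred range is the specialist
        spec_label = min(species, key=lambda s: ptrs[s].width)
        gen_label = next(s for s in species if s != spec_label)
        groups = classify_thermal_groups(te_day, ptrs[spec_label],
                                         ptrs[gen_label], window=window)
        return {"suitability": suitability, "comparison": comparison,
                "thermal_groups": groups,
                "roles": {"specialist": spec_label, "generalist": gen_label}}

    suit_frame = pd.concat(list(habitat_stage["suitability"].values()),
                           ignore_index=True)
    suit_frame.to_csv(outdir / "suitability.csv", index=False)
    comparison = habitat_stage["comparison"]
    letters = pd.DataFrame(
        sorted(comparison.letters.items()), columns=["category", "letters"]
    )
    letters.to_csv(outdir / "te_letter_groups.csv", index=False)
    pd.DataFrame(
        sorted(habitat_stage["thermal_groups"].items()),
        columns=["category", "thermal_group"],
    ).to_csv(outdir / "thermal_groups.csv", index=False)
    report["stages"]["habitat"] = _jsonify(
        {
            "omnibus": {"h": comparison.h, "df": comparison.df,
                        "p": comparison.p, "n": comparison.n},
            "letters": comparison.letters,
            "thermal_groups": habitat_stage["thermal_groups"],
            "roles": habitat_stage["roles"],
            "suitability": {k: v.to_dict(orient="records")
                            for k, v in habitat_stage["suitability"].items()},
        }
    )

    # ------------------------------------------------------------- selection
    @stage("selection")
    def selection_stage():
        out: dict = {"variables": {}, "frequency": {}}
        if "availability" in data:
            used = {label: [r for r in data["body"] if r.species == label]
                    for label in species}
            for var in cfg["selection_variables"]:
                try:
                    rep = used_vs_available(used, data["availability"], var,
                                            alpha=cfg["alpha"])
                except ValueError as exc:
                    log.warning("selection on %s skipped: %s", var, exc)
                    continue
                out["variables"][var] = rep
        if "counts" in data:
            by_group: dict = {}
            for c in data["counts"]:
                by_group.setdefault(c.group, {})[c.microhabitat] = c.count
            avail = by_group.get(AVAILABILITY_LABEL)
            seed = cfg["bootstrap"]["seed"]
            pairs = []
            if avail:
                pairs += [(label, AVAILABILITY_LABEL, by_group[label], avail)
                          for label in species if label in by_group]
            if all(label in by_group for label in species):
                pairs.append((species[0], species[1],
                              by_group[species[0]], by_group[species[1]]))
            for name_a, name_b, counts_a, counts_b in pairs:
                res = frequency_selection_test(counts_a, counts_b, seed=seed)
                out["frequency"][f"{name_a} vs {name_b}"] = res
        return out

    sel_rows = []
    for var, rep in selection_stage["variables"].items():
        sel_rows.append({"test": "kruskal_wallis", "variable": var,
                         "statistic": rep.h, "df": rep.df, "p": rep.p,
                         "n": rep.n})
    for pair, res in selection_stage["frequency"].items():
        sel_rows.append({"test": res.method, "variable": f"microhabitat ({pair})",
                         "statistic": None, "df": None, "p": res.p,
                         "n": int(res.table.sum())})
    pd.DataFrame(
        sel_rows, columns=["test", "variable", "statistic", "df", "p", "n"]
    ).to_csv(outdir / "selection_tests.csv", index=False)
    report["stages"]["selection"] = _jsonify(
        {
            "variables": {
                var: {"h": rep.h, "df": rep.df, "p": rep.p, "n": rep.n,
                      "pairwise_p": rep.pairwise_p.to_dict(),
                      "letters": rep.letters}
                for var, rep in selection_stage["variables"].items()
            },
            "frequency": {
                pair: {"p": res.p, "method": res.method,
                       "categories": list(res.categories),
                       "table": res.table.tolist()}
                for pair, res in selection_stage["frequency"].items()
            },
        }
    )

    ptr_frame = pd.DataFrame(
        [
            {"species": label, "lower_c": ptrs[label].lower_c,
             "upper_c": ptrs[label].upper_c, "n_values": ptrs[label].n_values}
            for label in species
        ]
    )
    ptr_frame.to_csv(outdir / "ptr.csv", index=False)

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("report bundle written to %s", outdir)
    return report


def write_study(study: StudyData, outdir) -> dict:
    """Write a synthetic study's datasets as the pipeline's input CSVs.

    Returns the ``inputs`` mapping to splice into a pipeline config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tpref = [m for ms in study.tpref.values() for m in ms]
    body = [r for rs in study.body.values() for r in rs]
    paths = {
        "tpref": outdir / "tpref.csv",
        "body": outdir / "body.csv",
        "operative": outdir / "operative.csv",
        "availability": outdir / "availability.csv",
        "counts": outdir / "counts.csv",
    }
    tio.write_records(tpref, paths["tpref"])
    tio.write_records(body, paths["body"])
    tio.write_records(study.operative, paths["operative"])
    tio.write_records(study.availability, paths["availability"])
    tio.write_records(study.counts, paths["counts"])
    return {k: str(v) for k, v in paths.items()}
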