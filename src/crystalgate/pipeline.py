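"""End-to-end orchestration: generate → analyze → report.

A run is described by a single JSON or YAML document::

    {
      "seed": 1,
      "output_dir": "out",
      "stages": [
        {"name": "gen", "kind": "generate_pcaph",
         "params": {"preset": "kp_composite", "ph_noise_sd": 0.0,
                    "pca_noise_sd": 0.0}},
        {"name": "cx", "kind": "complexity",
         "input": "gen", "params": {"channel": "pH"}}
      ]
    }

Stages execute in order; each stage may reference results of earlier
stages by name.  One global seed deterministically derives per-stage
seeds (seed + stage index) so any stage can be re-run in isolation.
Results never go to stderr; logging does.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as cio
from .complexity import complexity_report
from .electrochem import (CapacitanceSpectrum, capacitance_summary,
                          frequency_response, response_distribution,
                          spectrum_summary)
from .gates import CircuitSpec, crystallization_logic, eval_circuit
from .packing import cell_metrics, packing_summary, segment_spheres
from .synthetic import (HarmonicDatasetParams, PCA_PH_PRESETS, PcaPhParams,
                        SpectrumParams, SphereImageParams, gen_harmonic_dataset,
                        gen_microsphere_image, gen_pca_ph, gen_spectrum)

__all__ = ["RunConfig", "Stage", "run", "load_config", "validate_config"]

logger = logging.getLogger("crystalgate")

STAGE_KINDS = (
    "generate_pcaph", "generate_harmonic", "generate_spectrum",
    "generate_image", "complexity", "spectrum_summary",
    "capacitance_summary", "frequency_response", "response_distribution",
    "gates", "circuit", "voronoi",
)

#: stage kind -> the kinds of stage its "input" may reference
_INPUT_KINDS = {
    "complexity": {"generate_pcaph"},
    "spectrum_summary": {"generate_spectrum"},
    "capacitance_summary": {"generate_spectrum"},
    "frequency_response": {"generate_harmonic"},
    "response_distribution": {"generate_harmonic"},
    "gates": {"generate_pcaph"},
    "voronoi": {"generate_image"},
}


@dataclass(frozen=True)
class Stage:
    name: str
    kind: str
    params: dict = field(default_factory=dict)
    input: str | None = None


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[Stage, ...]
    seed: int = 0
    output_dir: str | None = None
    log_level: str = "WARNING"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        stages = tuple(
            Stage(name=s["name"], kind=s["kind"],
                  params=dict(s.get("params", {})), input=s.get("input"))
            for s in d.get("stages", [])
        )
        return cls(stages=stages, seed=int(d.get("seed", 0)),
                   output_dir=d.get("output_dir"),
                   log_level=str(d.get("log_level", "WARNING")))


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return RunConfig.from_dict(doc)


def validate_config(config: RunConfig | str | Path) -> list[str]:
    """Schema and dependency diagnostics; empty list iff runnable."""
    if not isinstance(config, RunConfig):
        try:
            config = load_config(config)
        except (OSError, ValueError, KeyError) as exc:
            return [f"cannot load config: {exc}"]
    diags: list[str] = []
    seen: dict[str, str] = {}
    for st in config.stages:
        if st.name in seen:
            diags.append(f"duplicate stage name {st.name!r}")
        if st.kind not in STAGE_KINDS:
            diags.append(f"stage {st.name!r}: unknown kind {st.kind!r}")
        needs = _INPUT_KINDS.get(st.kind)
        if needs is not None:
            if st.input is None:
                diags.append(f"stage {st.name!r}: kind {st.kind!r} "
                             f"requires an input stage")
            elif st.input not in seen:
                diags.append(f"stage {st.name!r}: input {st.input!r} is not "
                             f"a previously declared stage")
            elif seen[st.input] not in needs:
                diags.append(
                    f"stage {st.name!r}: input {st.input!r} has kind "
                    f"{seen[st.input]!r}, expected one of {sorted(needs)}")
        seen.setdefault(st.name, st.kind)
    return diags


def _config_hash(config: RunConfig) -> str:
    doc = {
        "seed": config.seed,
        "stages": [
            {"name": s.name, "kind": s.kind, "params": s.params,
             "input": s.input}
            for s in config.stages
        ],
    }
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()).hexdigest()


def _pcaph_params(params: dict, seed: int) -> PcaPhParams:
    preset = params.pop("preset", "kp_composite")
    base = PCA_PH_PRESETS[preset]
    params.setdefault("seed", seed)
    return replace(base, **params)


def run(config: RunConfig | str | Path) -> dict:
    """Execute all stages in order and return the consolidated report.

    Identical config + seed produce an identical report.  When
    ``output_dir`` is set, intermediate artifacts (CSV signals, spectra,
    images, label maps) are persisted there.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    diags = validate_config(config)
    if diags:
        raise ValueError("invalid config: " + "; ".join(diags))
    logging.basicConfig(stream=sys.stderr)
    logger.setLevel(config.log_level.upper())

    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    artifacts: dict[str, object] = {}
    results: dict[str, dict] = {}
    for idx, st in enumerate(config.stages):
        stage_seed = config.seed + idx
        logger.info("stage %s (%s), seed %d", st.name, st.kind, stage_seed)
        params = dict(st.params)
        res = _run_stage(st, params, stage_seed, artifacts, outdir)
        results[st.name] = res
    return {
        "results": results,
        "provenance": {
            "config_sha256": _config_hash(config),
            "seed": config.seed,
            "version": __import__("crystalgate").__version__,
        },
    }


def _run_stage(st: Stage, params: dict, seed: int,
               artifacts: dict, outdir: Path | None) -> dict:
    if st.kind == "generate_pcaph":
        p = _pcaph_params(params, seed)
        pca, ph = gen_pca_ph(p)
        artifacts[st.name] = {"pCa": pca, "pH": ph}
        if outdir:
            cio.write_timeseries(outdir / f"{st.name}_pca.csv", pca)
            cio.write_timeseries(outdir / f"{st.name}_ph.csv", ph)
        return {"kind": st.kind, "n_samples": len(pca),
                "duration_s": pca.duration}

    if st.kind == "generate_harmonic":
        params.setdefault("seed", seed)
        if "harmonics" in params:
            params["harmonics"] = tuple(params["harmonics"])
        p = HarmonicDatasetParams(**params)
        records = gen_harmonic_dataset(p)
        artifacts[st.name] = records
        if outdir:
            for h, vin, vout in records:
                cio.write_timeseries(outdir / f"{st.name}_h{h}_in.csv", vin)
                cio.write_timeseries(outdir / f"{st.name}_h{h}_out.csv", vout)
        return {"kind": st.kind, "harmonics": [h for h, _, _ in records]}

    if st.kind == "generate_spectrum":
        params.setdefault("seed", seed)
        p = SpectrumParams(**params)
        spec = gen_spectrum(p)
        artifacts[st.name] = spec
        if outdir:
            if isinstance(spec, CapacitanceSpectrum):
                cio.write_capacitance(outdir / f"{st.name}.csv", spec)
            else:
                cio.write_impedance(outdir / f"{st.name}.csv", spec)
        return {"kind": st.kind, "profile": p.profile, "n_points": len(spec)}

    if st.kind == "generate_image":
        params.setdefault("seed", seed)
        if "image_size" in params:
            params["image_size"] = tuple(params["image_size"])
        p = SphereImageParams(**params)
        img, centers = gen_microsphere_image(p)
        artifacts[st.name] = {"image": img, "centers": centers,
                              "params": p}
        if outdir:
            cio.write_image(outdir / f"{st.name}.png", img)
            cio.write_json(outdir / f"{st.name}_truth.json",
                           {"centers_row_col": centers.tolist()})
        return {"kind": st.kind, "n_spheres": int(centers.shape[0])}

    if st.kind == "complexity":
        channel = params.pop("channel", "pCa")
        series = artifacts[st.input][channel]
        rep = complexity_report(series, **params)
        return {"kind": st.kind, "channel": channel, **rep.to_dict()}

    if st.kind == "spectrum_summary":
        return {"kind": st.kind, **spectrum_summary(artifacts[st.input])}

    if st.kind == "capacitance_summary":
        cap_f = capacitance_summary(artifacts[st.input])
        return {"kind": st.kind, "plateau_f": cap_f,
                "plateau_nf": cap_f * 1e9}

    if st.kind == "frequency_response":
        harmonic = params.pop("harmonic", None)
        records = artifacts[st.input]
        if harmonic is not None:
            records = [r for r in records if r[0] == harmonic]
        out = {}
        for h, vin, vout in records:
            fr = frequency_response(vin, vout, **params)
            f_stim = np.abs(fr.frequencies - _stim_freq(vin)).argmin()
            out[f"h{h}"] = {
                "gain_at_stimulus": float(fr.gain[f_stim]),
                "phase_at_stimulus_deg": float(fr.phase[f_stim]),
            }
        return {"kind": st.kind, **out}

    if st.kind == "response_distribution":
        out = {}
        for h, _, vout in artifacts[st.input]:
            ds = response_distribution(vout)
            out[f"h{h}"] = {"median": ds.median, "q1": ds.q1, "q3": ds.q3,
                            "min": ds.min, "max": ds.max}
        return {"kind": st.kind, **out}

    if st.kind == "gates":
        src = artifacts[st.input]
        trace = crystallization_logic(src["pCa"], src["pH"], **params)
        if outdir:
            cio.write_boolean_trace(outdir / f"{st.name}.csv", trace)
        return {"kind": st.kind, "n_samples": len(trace),
                "fraction_active": float(np.mean(trace.bits)),
                "n_transitions": int(np.sum(np.abs(np.diff(
                    trace.bits.astype(int)))))}

    if st.kind == "circuit":
        spec = CircuitSpec.from_dict(params["circuit"])
        inputs = {k: artifacts[v] for k, v in params["inputs"].items()}
        trace = eval_circuit(spec, inputs)
        if outdir:
            cio.write_boolean_trace(outdir / f"{st.name}.csv", trace)
        return {"kind": st.kind, "n_samples": len(trace),
                "fraction_active": float(np.mean(trace.bits))}

    if st.kind == "voronoi":
        art = artifacts[st.input]
        p: SphereImageParams = art["params"]
        seg = segment_spheres(
            art["image"], px_size_nm=p.px_size_nm,
            min_distance=max(2, p.radius_px // 2),
            seeds=art["centers"] if params.pop("use_truth_seeds", True)
            else None)
        cells = cell_metrics(seg)
        summary = packing_summary(
            cells,
            sphere_diameter_nm=params.pop(
                "diameter_nm", 2.0 * p.radius_px * p.px_size_nm),
            concentration_m=params.pop("concentration_m", 3e-3))
        if outdir:
            cio.write_image(outdir / f"{st.name}_labels.tif",
                            seg.label_image.astype(np.uint16))
        return {"kind": st.kind, "n_cells": seg.n_cells,
                **summary.to_dict()}

    raise ValueError(f"unknown stage kind {st.kind!r}")


def _stim_freq(vin) -> float:
    """Recover the dominant stimulus frequency from the input record."""
    v = vin.values - vin.values.mean()
    spec = np.abs(np.fft.rfft(v))
    freqs = np.fft.rfftfreq(len(v), d=vin.mean_dt)
    return float(freqs[spec.argmax()])
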