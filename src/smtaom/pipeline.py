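"""End-to-end pipeline: simulate/load -> align -> classify -> summarize.

The pipeline is configured from a YAML mapping (see PipelineConfig) and is
idempotent given a seed: every artifact plus a manifest recording inputs,
parameters, package version and seed is written to the output directory,
and re-running the same configuration reproduces them byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .align import AlignParams
from .classify import ClassifyParams, classify_cohort, write_calls
from .errors import ConfigError
from .quantify import QuantCalibration, read_calibration
from .refmap import read_reference, synthesize_reference, write_reference
from .simulate import SimConfig, read_bnx, simulate_cohort, write_bnx
from .stats import compare_frequencies, compare_lengths, render_report, summarize

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``cohorts`` maps cohort tag -> exactly one of ``{"molecules": path}``
    (a BNX-minimal file) or ``{"simulate": {...}}`` (overrides for the
    cohort's simulation, e.g. ``n_molecules``).
    """

    seed: int
    output_dir: Path
    reference: dict
    cohorts: dict
    sim: SimConfig
    align_params: AlignParams
    classify_params: ClassifyParams
    stats: dict
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "output_dir" not in raw:
            raise ConfigError("output_dir is required")
        seed = int(raw.get("seed", 0))
        reference = raw.get("reference", {"synthesize": {}})
        if ("path" in reference) == ("synthesize" in reference):
            raise ConfigError(
                "reference needs exactly one of 'path' or 'synthesize'"
            )
        cohorts = raw.get("cohorts")
        if not cohorts:
            raise ConfigError("at least one cohort is required")
        for tag, spec in cohorts.items():
            if ("molecules" in spec) == ("simulate" in spec):
                raise ConfigError(
                    f"cohort {tag!r} needs exactly one of 'molecules' or 'simulate'"
                )
        sim_kwargs = dict(raw.get("simulate", {}))
        sim_kwargs["seed"] = seed  # the run seed reaches every stochastic stage
        sim = SimConfig(**sim_kwargs)
        align_params = AlignParams(**raw.get("align", {}))
        classify_kwargs = dict(raw.get("classify", {}))
        calib = classify_kwargs.pop("calibration", None)
        if isinstance(calib, str):
            calib = read_calibration(calib)
        elif isinstance(calib, dict):
            calib = QuantCalibration(**calib)
        elif calib is None and raw.get("nominal_calibration", True):
            # nominal instrument calibration from the simulation constants
            calib = QuantCalibration(
                kb_per_pixel=sim.kb_per_pixel,
                intensity_per_kb=sim.intensity_per_kb,
                resolution_floor_kb=sim.resolution_kb,
            )
        classify_params = ClassifyParams(
            calibration=calib, nominal_kb_per_pixel=sim.kb_per_pixel,
            **classify_kwargs,
        )
        return cls(
            seed=seed,
            output_dir=Path(raw["output_dir"]),
            reference=reference,
            cohorts=cohorts,
            sim=sim,
            align_params=align_params,
            classify_params=classify_params,
            stats=raw.get("stats", {}),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict."""
    logging.basicConfig(level=config.log_level)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    logger.info("stage reference")
    if "path" in config.reference:
        refset = read_reference(config.reference["path"])
    else:
        kwargs = dict(config.reference["synthesize"])
        kwargs.setdefault("seed", config.seed)
        refset = synthesize_reference(**kwargs)
    ref_out = out / "reference.cmap"
    write_reference(refset, ref_out)
    artifacts["reference"] = ref_out

    summaries = []
    all_calls = {}
    for tag, spec in config.cohorts.items():
        logger.info("stage molecules [%s]", tag)
        if "molecules" in spec:
            mols = read_bnx(spec["molecules"])
        else:
            sim_over = {
                k: v for k, v in spec["simulate"].items() if k != "n_molecules"
            }
            sim = dataclasses.replace(config.sim, **sim_over) if sim_over else config.sim
            mols, truths = simulate_cohort(
                refset, sim, tag, n_molecules=spec["simulate"].get("n_molecules")
            )
            bnx = out / f"{tag}.bnx"
            write_bnx(mols, bnx)
            artifacts[f"molecules_{tag}"] = bnx
        logger.info("stage align+classify [%s] (%d molecules)", tag, len(mols))
        calls = classify_cohort(
            mols, refset, config.align_params, config.classify_params
        )
        calls_path = out / f"calls_{tag}.csv"
        write_calls(calls, calls_path)
        artifacts[f"calls_{tag}"] = calls_path
        all_calls[tag] = calls
        summaries.append(summarize(calls, tag))

    logger.info("stage report")
    comparisons = []
    pair = config.stats.get("compare")
    test = config.stats.get("test", "fisher_exact")
    if pair and len(pair) == 2 and all(t in all_calls for t in pair):
        a, b = pair
        sa = next(s for s in summaries if s.cohort == a)
        sb = next(s for s in summaries if s.cohort == b)
        for metric, key in (
            ("its_plus_pct", "n_its_plus"),
            ("its_minus_pct", "n_its_minus"),
            ("tfe_pct", "n_tfe"),
        ):
            comparisons.append(
                compare_frequencies(
                    sa.overall[key], sa.overall["n_molecules"],
                    sb.overall[key], sb.overall["n_molecules"],
                    test=test, metric=metric, cohort_a=a, cohort_b=b,
                )
            )
        la = [c.telomere_kb for c in all_calls[a]
              if c.category == "END_TEL" and c.telomere_kb is not None]
        lb = [c.telomere_kb for c in all_calls[b]
              if c.category == "END_TEL" and c.telomere_kb is not None]
        if len(la) >= 2 and len(lb) >= 2:
            comparisons.append(
                compare_lengths(la, lb, metric="end_tel_mean_kb",
                                cohort_a=a, cohort_b=b)
            )
    report_dir = out / "report"
    render_report(summaries, comparisons, report_dir)
    for name in ("report.csv", "report.json", "per_arm.csv"):
        artifacts[f"report/{name}"] = report_dir / name

    manifest = {
        "package": "smtaom",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "simulate": dataclasses.asdict(config.sim),
            "align": dataclasses.asdict(config.align_params),
            "classify": {
                k: v
                for k, v in dataclasses.asdict(config.classify_params).items()
            },
            "stats": config.stats,
            "reference": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in config.reference.items()
            },
            "cohorts": config.cohorts,
        },
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
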