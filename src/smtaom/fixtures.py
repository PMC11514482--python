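"""Packaged demonstration fixtures.

`make_fixtures` writes, deterministically:

* two cohort call tables whose category counts equal the benchmark
  dCas9/sgTelo vs dCas9/sgNS experiment (1061 molecules: 161 ITS+, 42 ITS-,
  86 TFE, 772 END_TEL; and 1100: 59, 4, 55, 982), with synthetic log-normal
  telomere lengths matching the cohort means, spread over 35 arms;
* a small synthetic reference map / molecule file pair plus a pipeline
  config, for end-to-end smoke runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .classify import EndFeatureCall, write_calls
from .refmap import hg38_arm_names, synthesize_reference, write_reference
from .simulate import SimConfig, simulate_cohort, write_bnx

#: Benchmark cohort composition (events / molecules analyzed) of the
#: dCas9/sgTelo telomere-replication-stress experiment and its control,
#: with the cohort mean telomere lengths (kb) used to draw synthetic
#: per-molecule lengths.
COHORT_COUNTS = {
    "sgTelo": {"n": 1061, "its_plus": 161, "its_minus": 42, "tfe": 86,
               "end_tel_mean_kb": 11.3, "its_plus_mean_kb": 11.8},
    "sgNS": {"n": 1100, "its_plus": 59, "its_minus": 4, "tfe": 55,
             "end_tel_mean_kb": 11.7, "its_plus_mean_kb": 11.2},
}

_FIXTURE_SEED = 210321
_N_ARMS = 35
_CV = 0.35


def _lengths(mean_kb: float, size: int, rng: np.random.Generator) -> np.ndarray:
    sigma2 = np.log1p(_CV**2)
    return rng.lognormal(np.log(mean_kb) - sigma2 / 2.0, np.sqrt(sigma2), size)


def build_fixture_calls(cohort: str) -> list[EndFeatureCall]:
    """Deterministic call list with the benchmark category counts."""
    spec = COHORT_COUNTS[cohort]
    rng = np.random.default_rng(
        np.random.SeedSequence([_FIXTURE_SEED, hash_cohort(cohort)])
    )
    arms = hg38_arm_names(_N_ARMS)
    n_end_tel = spec["n"] - spec["its_plus"] - spec["its_minus"] - spec["tfe"]
    blocks = [
        ("END_TEL", n_end_tel, spec["end_tel_mean_kb"]),
        ("ITS_PLUS", spec["its_plus"], spec["its_plus_mean_kb"]),
        ("ITS_MINUS", spec["its_minus"], None),
        ("TFE", spec["tfe"], None),
    ]
    calls = []
    idx = 0
    for category, count, mean_kb in blocks:
        tel = _lengths(mean_kb, count, rng) if mean_kb is not None else None
        for k in range(count):
            calls.append(
                EndFeatureCall(
                    molecule_id=f"{cohort}-fx{idx:05d}",
                    category=category,
                    arm_id=arms[idx % len(arms)],
                    telomere_kb=float(tel[k]) if tel is not None else None,
                    cohort=cohort,
                )
            )
            idx += 1
    return calls


def hash_cohort(cohort: str) -> int:
    import zlib

    return zlib.crc32(cohort.encode())


def make_fixtures(outdir) -> dict[str, Path]:
    """Write all fixtures into ``outdir``; regeneration is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for cohort in COHORT_COUNTS:
        p = outdir / f"{cohort}_calls.csv"
        write_calls(build_fixture_calls(cohort), p)
        paths[f"calls_{cohort}"] = p

    refset = synthesize_reference(n_arms=4, seed=_FIXTURE_SEED)
    ref_path = outdir / "demo_reference.cmap"
    write_reference(refset, ref_path)
    paths["reference"] = ref_path
    config = SimConfig(seed=_FIXTURE_SEED, molecules_per_arm=6)
    for cohort in ("sgTelo", "sgNS"):
        mols, _ = simulate_cohort(refset, config, cohort)
        p = outdir / f"demo_{cohort}.bnx"
        write_bnx(mols, p)
        paths[f"molecules_{cohort}"] = p
    # paths relative to the fixtures directory keep regeneration
    # byte-identical wherever the fixtures land; run the pipeline from there
    demo_cfg = {
        "seed": int(_FIXTURE_SEED),
        "output_dir": "demo_out",
        "reference": {"path": ref_path.name},
        "cohorts": {
            c: {"molecules": paths[f"molecules_{c}"].name} for c in COHORT_COUNTS
        },
        "stats": {"test": "fisher_exact", "compare": ["sgTelo", "sgNS"]},
    }
    cfg_path = outdir / "demo_config.yaml"
    with cfg_path.open("w") as fh:
        yaml.safe_dump(demo_cfg, fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
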