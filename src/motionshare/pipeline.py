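"""End-to-end pipeline: simulate a cohort, read it repeatedly under an
observer model, compute motion-sharing biomarkers and the repeatability
report.  Deterministic given the configured seeds; every artifact carries a
provenance block (package version, config hash, seed)."""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import write_result_json, write_sequence_csv
from .reliability import repeatability_report
from .sharing import analyze_sequence
from .synthetic import SharingProfile, TableProfile, cohort_sharing_profiles, generate_subject

log = logging.getLogger("motionshare.pipeline")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_subjects": 30,
    "table": {
        "accel": 6.0,
        "plateau_velocity": 6.0,
        "max_angle": 40.0,
        "frame_rate": 15.0,
        "include_return": True,
    },
    "sharing": {
        "mean_range": 0.24,
        "range_sd": 0.09,
        "share_drift": 0.03,
        "noise_sd": 0.52,
    },
    "observer": {
        "raters": ["AxB", "DT1", "DT2"],
        "error_sd": 0.024,
        "rater_bias_sd": 0.0,
    },
    "trim": {"mode": "amplitude", "phases": "both", "lower": 0.10, "upper": 0.90},
    "icc": {"form": "agreement"},
    "pairs": {"intra": ["DT1", "DT2"], "inter": ["AxB", "DT1"]},
    "tracking": {"enabled": False},
    "write_sequences": True,
}


def _validate_keys(config: dict, defaults: dict, prefix: str = "") -> list[str]:
    bad = []
    for key, val in config.items():
        if key not in defaults:
            bad.append(prefix + key)
        elif isinstance(val, dict) and isinstance(defaults[key], dict):
            bad += _validate_keys(val, defaults[key], prefix + key + ".")
    return bad


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults.

    Unknown keys are an error listing every offender.
    """
    config = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    for extra in (
        yaml.safe_load(Path(path).read_text()) if path else None,
        overrides,
    ):
        if extra:
            bad = _validate_keys(extra, DEFAULT_CONFIG)
            if bad:
                raise ValueError(f"invalid config keys: {', '.join(sorted(bad))}")
            merge(config, extra)
    return config


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Run simulate -> biomarkers -> observer readings -> repeatability.

    Writes per-subject sequence CSVs, a long-format readings CSV, report
    tables/plots and a ``results.json``; returns the results dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    chash = config_hash(config)
    provenance = {"version": __version__, "config_hash": chash, "seed": seed}
    log.info("stage=simulate seed=%d n_subjects=%d hash=%s", seed, config["n_subjects"], chash)

    table = TableProfile(**config["table"])
    root = np.random.SeedSequence(seed)
    s_cohort, s_subjects, s_observer = root.spawn(3)
    profiles = cohort_sharing_profiles(
        config["n_subjects"],
        mean_range=config["sharing"]["mean_range"],
        range_sd=config["sharing"]["range_sd"],
        share_drift=config["sharing"]["share_drift"],
        noise_sd=config["sharing"]["noise_sd"],
        seed=s_cohort,
    )
    subject_seeds = s_subjects.spawn(config["n_subjects"])
    seq_dir = outdir / "sequences"
    true_rows = []
    sequences = []
    for i, (prof, sseed) in enumerate(zip(profiles, subject_seeds)):
        seq = generate_subject(table, prof, seed=sseed)
        sequences.append(seq)
        if config["write_sequences"]:
            seq_dir.mkdir(exist_ok=True)
            write_sequence_csv(seq, seq_dir / f"subject_{i + 1:02d}.csv")

    log.info("stage=biomarkers trim=%s phases=%s", config["trim"]["mode"], config["trim"]["phases"])
    for i, seq in enumerate(sequences):
        res = analyze_sequence(
            seq,
            trim=config["trim"]["mode"],
            phases=config["trim"]["phases"],
            lower=config["trim"]["lower"],
            upper=config["trim"]["upper"],
        )
        true_rows.append(
            {"subject": f"S{i + 1:02d}", "msi": res.msi, "msv": res.msv, "n": res.n_retained}
        )
    true_df = pd.DataFrame(true_rows)

    log.info("stage=observer raters=%s", config["observer"]["raters"])
    rng = np.random.default_rng(s_observer)
    raters = list(config["observer"]["raters"])
    bias = rng.normal(0.0, config["observer"]["rater_bias_sd"], size=(len(raters), 2))
    rows = []
    for j, rater in enumerate(raters):
        for _, row in true_df.iterrows():
            for b, biom in enumerate(["msi", "msv"]):
                err = rng.normal(0.0, config["observer"]["error_sd"])
                rows.append(
                    {
                        "subject": row["subject"],
                        "rater": rater,
                        "biomarker": biom.upper(),
                        "value": row[biom] + bias[j, b] + err,
                    }
                )
    readings = pd.DataFrame(rows)
    readings.to_csv(outdir / "readings.csv", index=False, float_format="%.17g")

    log.info("stage=repeatability pairs=%s", config["pairs"])
    pairs = {name: tuple(p) for name, p in config["pairs"].items()}
    report = repeatability_report(
        readings, pairs=pairs, form=config["icc"]["form"], outdir=outdir / "report"
    )

    results = {
        "true_biomarkers": {
            "msi_mean": float(true_df["msi"].mean()),
            "msi_sd": float(true_df["msi"].std(ddof=1)),
            "msv_mean": float(true_df["msv"].mean()),
            "msv_sd": float(true_df["msv"].std(ddof=1)),
        },
        "group_summary": report["summary"].to_dict(orient="records"),
        "repeatability": {
            f"{biom}/{name}": res.to_dict() for (biom, name), res in report["results"].items()
        },
    }
    write_result_json(results, outdir / "results.json", provenance=provenance)
    log.info("stage=done outdir=%s", outdir)
    return results
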