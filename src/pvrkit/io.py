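"""File formats: trace CSV (+ JSON sidecar), cohort CSV, report JSON/Markdown.

CSV dialect: comma-separated, UTF-8, ``.`` decimal, mandatory header row.
``#``-prefixed metadata lines are allowed only in trace files. All numeric
fields round-trip at full precision (repr-level float formatting).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pvrkit.errors import ParseError
from pvrkit.wavesim import BeatShapeParams, GroundTruthBeat, PVRTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_cohort",
    "read_cohort",
    "write_report",
]

_COHORT_COLUMNS = [
    "limb_id", "glass_stage", "imd", "ust_ms", "usr", "msa_mmhg",
    "wavelength_ms", "pulsatile", "notch_present", "flat_interval_present",
    "upstroke_downslope_ratio", "abi", "abi_ge_1_3", "infection", "morphology",
]


def write_trace(trace: PVRTrace, path: str | Path, sidecar: bool = True) -> None:
    """Write a trace as metadata-headed CSV, plus a ground-truth JSON sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# sampling_interval_ms={trace.sampling_interval!r}\n")
        fh.write(f"# cuff_pressure_mmhg={trace.cuff_pressure!r}\n")
        fh.write(f"# limb_id={trace.limb_id}\n")
        fh.write("t_ms,pressure_mmhg\n")
        for i, v in enumerate(trace.samples):
            fh.write(f"{float(i * trace.sampling_interval)!r},{float(v)!r}\n")
    if sidecar and trace.ground_truth is not None:
        gt = [
            {
                "params": dataclasses.asdict(g.params),
                "foot_time": g.foot_time,
                "peak_time": g.peak_time,
                "notch_time": g.notch_time,
                "next_foot_time": g.next_foot_time,
            }
            for g in trace.ground_truth
        ]
        path.with_suffix(".json").write_text(json.dumps(gt, indent=1), encoding="utf-8")


def read_trace(path: str | Path) -> PVRTrace:
    """Read a trace CSV (and its JSON sidecar when present)."""
    path = Path(path)
    meta: dict[str, str] = {}
    samples: list[float] = []
    times: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("# ").partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != "t_ms,pressure_mmhg":
                    raise ParseError(f"{path}:{lineno}: expected header 't_ms,pressure_mmhg'")
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two comma-separated fields")
            try:
                times.append(float(parts[0]))
                samples.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    if not header_seen:
        raise ParseError(f"{path}: missing header row")
    dt = float(meta.get("sampling_interval_ms", "1"))
    ground_truth = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        ground_truth = [
            GroundTruthBeat(
                params=BeatShapeParams(**g["params"]),
                foot_time=g["foot_time"],
                peak_time=g["peak_time"],
                notch_time=g["notch_time"],
                next_foot_time=g["next_foot_time"],
            )
            for g in json.loads(sidecar.read_text(encoding="utf-8"))
        ]
    return PVRTrace(
        samples=np.asarray(samples),
        sampling_interval=dt,
        cuff_pressure=float(meta.get("cuff_pressure_mmhg", "50")),
        limb_id=meta.get("limb_id", path.stem),
        ground_truth=ground_truth,
    )


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a limb table in the standard cohort schema."""
    missing = [c for c in _COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"cohort table missing columns: {missing}")
    frame[_COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a limb table; invariant violations name row and field."""
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if pd.notna(row["msa_mmhg"]) and row["msa_mmhg"] < 0:
            raise ParseError(f"{path}:{line}: field msa_mmhg must be >= 0, got {row['msa_mmhg']}")
        if pd.notna(row["usr"]) and not 0 < row["usr"] < 1:
            raise ParseError(f"{path}:{line}: field usr must be in (0, 1), got {row['usr']}")
        if pd.notna(row["abi"]) and row["abi"] < 0:
            raise ParseError(f"{path}:{line}: field abi must be >= 0, got {row['abi']}")
        if row["glass_stage"] not in ("0", "I", "II", "III", 0):
            raise ParseError(f"{path}:{line}: field glass_stage invalid: {row['glass_stage']}")
        if row["imd"] not in ("P0", "P1", "P2"):
            raise ParseError(f"{path}:{line}: field imd invalid: {row['imd']}")
    df["glass_stage"] = df["glass_stage"].astype(str)
    return df


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(report: dict, path: str | Path, markdown: bool = True) -> None:
    """Write a report bundle as JSON (sorted keys) and a Markdown summary."""
    path = Path(path)
    path.write_text(
        json.dumps(report, indent=1, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8",
    )
    if markdown:
        path.with_suffix(".md").write_text(_report_markdown(report), encoding="utf-8")


def _fmt_pct(x) -> str:
    return "n/a" if x is None else f"{100 * x:.1f}%"


def _report_markdown(report: dict) -> str:
    lines = ["# Diagnostic test accuracy report", ""]
    if "provenance" in report:
        prov = report["provenance"]
        lines += [f"- config hash: `{prov.get('config_hash', '?')}`",
                  f"- seed: {prov.get('seed', '?')}", ""]
    ev = report.get("evaluation", report)
    lines += [
        f"- limbs: {ev.get('n_limbs', '?')}",
        f"- non-pulsatile: {ev.get('n_non_pulsatile', '?')}",
        f"- quantitatively analyzed: {ev.get('n_analyzed', '?')}",
        "",
    ]
    for ep, ep_rep in ev.get("endpoints", {}).items():
        lines.append(f"## Endpoint: {ep}")
        if "skipped" in ep_rep:
            lines += [f"skipped: {ep_rep['skipped']}", ""]
            continue
        lines.append("")
        lines.append("| feature | AUC (95% CI) | cut-off | sensitivity | specificity |")
        lines.append("|---|---|---|---|---|")
        for feat, f in ep_rep.get("features", {}).items():
            lines.append(
                f"| {feat} | {f['auc']:.2f} ({f['auc_ci_low']:.2f}-{f['auc_ci_high']:.2f}) "
                f"| {f['cutoff']:.2f} | {_fmt_pct(f['youden_sensitivity'])} "
                f"| {_fmt_pct(f['youden_specificity'])} |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
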