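"""Cohort manifests, array archives, model serialization and splits.

A cohort on disk is a directory with ``manifest.csv`` (one row per node,
patient-level fields repeated), ``arrays/<patient_id>.npz`` (patch, mask
and ADC arrays keyed by node id) and ``params.json`` echoing the resolved
generator parameters and seed for provenance. All CSV floats are written
with a fixed format and JSON keys are sorted, so re-running any command
with identical inputs reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import FusionMLP, IntensityNet
from .errors import ManifestError
from .model import WisdomConfig, WisdomResults
from .simulate import CohortParams, LymphNodeInstance, PatientBag
from .staging import Stage, count_to_stage

__all__ = [
    "MANIFEST_COLUMNS",
    "save_cohort",
    "load_cohort",
    "manifest_from_bags",
    "load_manifest",
    "validate_manifest",
    "chronological_split",
    "save_model",
    "load_model",
    "load_yaml_config",
    "write_json",
]

FLOAT_FORMAT = "%.6g"
COHORT_TAGS = ("train", "internal_test", "external_test_1", "external_test_2")
MANIFEST_COLUMNS = [
    "patient_id",
    "node_id",
    "long_diam_mm",
    "short_diam_mm",
    "diam_ratio",
    "mean_adc",
    "latent_met",
    "n_resected",
    "n_metastatic",
    "y",
    "rho",
    "stage_true",
    "enroll_key",
    "cohort_tag",
]


def write_json(path, obj) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Stage):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n"
    )


def manifest_from_bags(bags, cohort_tag: str = "train") -> pd.DataFrame:
    rows = []
    for bag in bags:
        for node in bag.nodes:
            rows.append(
                {
                    "patient_id": bag.patient_id,
                    "node_id": node.node_id,
                    "long_diam_mm": node.long_diam_mm,
                    "short_diam_mm": node.short_diam_mm,
                    "diam_ratio": node.diam_ratio,
                    "mean_adc": node.mean_adc,
                    "latent_met": (
                        "" if node.latent_met is None else int(node.latent_met)
                    ),
                    "n_resected": bag.n_resected,
                    "n_metastatic": bag.n_metastatic,
                    "y": bag.y,
                    "rho": bag.rho,
                    "stage_true": str(bag.stage_true),
                    "enroll_key": bag.enroll_key,
                    "cohort_tag": cohort_tag,
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def save_cohort(bags, out_dir, params=None, cohort_tag: str = "train") -> Path:
    """Write manifest.csv, per-patient array archives and params.json."""
    out = Path(out_dir)
    (out / "arrays").mkdir(parents=True, exist_ok=True)
    manifest = manifest_from_bags(bags, cohort_tag=cohort_tag)
    manifest.to_csv(out / "manifest.csv", index=False, float_format=FLOAT_FORMAT)
    for bag in bags:
        arrays = {}
        for node in bag.nodes:
            if node.patch is None:
                continue
            arrays[f"{node.node_id}:patch"] = node.patch
            arrays[f"{node.node_id}:mask"] = node.mask.astype(np.uint8)
            if node.adc_patch is not None:
                arrays[f"{node.node_id}:adc"] = node.adc_patch
        if arrays:
            np.savez_compressed(out / "arrays" / f"{bag.patient_id}.npz", **arrays)
    sidecar = {"cohort_tag": cohort_tag, "n_patients": len(bags)}
    if params is not None:
        if dataclasses.is_dataclass(params):
            params = params.to_dict()
        sidecar["params"] = params
    write_json(out / "params.json", sidecar)
    return out


def load_cohort(cohort_dir):
    """Rebuild patient bags (with arrays when present) from a cohort dir."""
    cohort_dir = Path(cohort_dir)
    manifest = load_manifest(cohort_dir / "manifest.csv")
    bags = []
    for pid, grp in manifest.groupby("patient_id", sort=True):
        npz_path = cohort_dir / "arrays" / f"{pid}.npz"
        arrays = np.load(npz_path) if npz_path.exists() else None
        nodes = []
        for _, row in grp.iterrows():
            nid = row["node_id"]
            patch = mask = adc = None
            if arrays is not None and f"{nid}:patch" in arrays:
                patch = arrays[f"{nid}:patch"]
                mask = arrays[f"{nid}:mask"].astype(bool)
                adc = arrays[f"{nid}:adc"] if f"{nid}:adc" in arrays else None
            lm = row.get("latent_met")
            nodes.append(
                LymphNodeInstance(
                    node_id=nid,
                    long_diam_mm=float(row["long_diam_mm"]),
                    short_diam_mm=float(row["short_diam_mm"]),
                    diam_ratio=float(row["diam_ratio"]),
                    mean_adc=(
                        None if pd.isna(row["mean_adc"]) else float(row["mean_adc"])
                    ),
                    latent_met=None if pd.isna(lm) else bool(int(lm)),
                    patch=patch,
                    mask=mask,
                    adc_patch=adc,
                )
            )
        first = grp.iloc[0]
        bags.append(
            PatientBag(
                patient_id=pid,
                nodes=nodes,
                n_resected=int(first["n_resected"]),
                n_metastatic=int(first["n_metastatic"]),
                enroll_key=int(first["enroll_key"]),
            )
        )
    bags.sort(key=lambda b: (b.enroll_key, b.patient_id))
    return bags


def load_manifest(path) -> pd.DataFrame:
    """Read and schema-check a cohort manifest CSV."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest {path}: missing columns {missing}")
    return df


def validate_manifest(manifest: pd.DataFrame) -> list:
    """Collect *every* invariant violation (with row numbers), not just the first.

    Checked per row: counts ordered (0 <= n_metastatic <= n_resected), rho
    equals the count ratio, y = (n_metastatic > 0), stage consistent with
    the staging map. Checked per patient: patient-level fields constant
    across the patient's rows and no patient in two cohort tags.
    """
    violations = []
    for i, row in manifest.iterrows():
        if not 0 <= row["n_metastatic"] <= row["n_resected"]:
            violations.append(
                f"row {i}: n_metastatic={row['n_metastatic']} outside "
                f"[0, n_resected={row['n_resected']}]"
            )
            continue
        expected_rho = row["n_metastatic"] / row["n_resected"]
        if not math.isclose(row["rho"], expected_rho, abs_tol=1e-4):
            violations.append(
                f"row {i}: rho={row['rho']} != n_metastatic/n_resected="
                f"{expected_rho:.6g}"
            )
        if int(row["y"]) != int(row["n_metastatic"] > 0):
            violations.append(f"row {i}: y={row['y']} inconsistent with n_metastatic")
        expected_stage = str(count_to_stage(int(row["n_metastatic"])))
        if str(row["stage_true"]) != expected_stage:
            violations.append(
                f"row {i}: stage_true={row['stage_true']} != {expected_stage}"
            )
        if row["cohort_tag"] not in COHORT_TAGS:
            violations.append(f"row {i}: unknown cohort_tag {row['cohort_tag']!r}")
    patient_fields = ["n_resected", "n_metastatic", "y", "rho", "stage_true", "enroll_key"]
    for pid, grp in manifest.groupby("patient_id"):
        for col in patient_fields:
            if grp[col].nunique(dropna=False) > 1:
                violations.append(
                    f"patient {pid}: field {col} varies across rows "
                    f"{grp.index.tolist()}"
                )
        if grp["cohort_tag"].nunique() > 1:
            violations.append(
                f"patient {pid}: appears in multiple cohort_tags "
                f"{sorted(grp['cohort_tag'].unique())}"
            )
    return violations


def chronological_split(manifest: pd.DataFrame, ratio: float = 4.0):
    """Patient-level chronological split at ``ratio : 1`` (train : test).

    Patients are ordered by their enrollment key; the first
    ``ceil(n * ratio / (ratio + 1))`` become training patients and the
    remainder the test set. A patient is never divided, and neither is an
    enrollment day: patients sharing the boundary enrollment key are all
    carried into the training side (a chronological cutoff cannot separate
    same-day enrollments). Deterministic and invariant to row order.
    """
    if "enroll_key" not in manifest.columns:
        raise ManifestError("chronological_split: manifest lacks 'enroll_key'")
    if ratio <= 0:
        raise ManifestError(f"chronological_split: ratio must be > 0, got {ratio}")
    per_patient = (
        manifest.groupby("patient_id")["enroll_key"].first().reset_index()
    )
    per_patient = per_patient.sort_values(
        ["enroll_key", "patient_id"], kind="mergesort"
    ).reset_index(drop=True)
    n = len(per_patient)
    n_train = min(int(math.ceil(n * ratio / (ratio + 1.0))), n)
    if 0 < n_train < n:
        boundary_key = per_patient.loc[n_train - 1, "enroll_key"]
        while n_train < n and per_patient.loc[n_train, "enroll_key"] == boundary_key:
            n_train += 1
    train_ids = per_patient.loc[: n_train - 1, "patient_id"].tolist()
    test_ids = per_patient.loc[n_train:, "patient_id"].tolist()
    return train_ids, test_ids


# -- model serialization -------------------------------------------------

def save_model(results: WisdomResults, out_dir) -> Path:
    """Serialize a fitted model: weights.npz + meta.json + loss curves CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (p, _) in enumerate(results.intensity_net.params()):
        arrays[f"intensity:{i}"] = p
    if results.fusion is not None:
        for i, (p, _) in enumerate(results.fusion.params()):
            arrays[f"fusion:{i}"] = p
        arrays["feature_mean"] = results.feature_mean
        arrays["feature_scale"] = results.feature_scale
    np.savez_compressed(out / "weights.npz", **arrays)
    write_json(
        out / "meta.json",
        {
            "variant": results.variant,
            "tau": results.tau,
            "config": results.config.to_dict(),
            "n_train_bags": results.n_train_bags,
        },
    )
    rows = []
    for part, hist in results.loss_history.items():
        for h in hist:
            rows.append({"component": part, **h})
    pd.DataFrame(rows).to_csv(
        out / "loss_history.csv", index=False, float_format=FLOAT_FORMAT
    )
    return out


def load_model(model_dir) -> WisdomResults:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "meta.json").read_text())
    arrays = np.load(model_dir / "weights.npz")
    config = WisdomConfig(**meta["config"])
    net = IntensityNet(seed=0)
    net.load_state([arrays[f"intensity:{i}"] for i in range(len(net.params()))])
    fusion = mean = scale = None
    if meta["variant"] != "M_I":
        mean = arrays["feature_mean"]
        scale = arrays["feature_scale"]
        d_in = mean.size
        fusion = FusionMLP(d_in, hidden=config.fusion_hidden, seed=0)
        fusion.load_state([arrays[f"fusion:{i}"] for i in range(len(fusion.params()))])
    hist_path = model_dir / "loss_history.csv"
    loss_history = {}
    if hist_path.exists():
        lh = pd.read_csv(hist_path)
        for part, grp in lh.groupby("component"):
            loss_history[part] = grp.drop(columns="component").to_dict("records")
    return WisdomResults(
        variant=meta["variant"],
        intensity_net=net,
        fusion=fusion,
        feature_mean=mean,
        feature_scale=scale,
        tau=meta["tau"],
        config=config,
        loss_history=loss_history,
        n_train_bags=meta.get("n_train_bags", 0),
    )


def load_yaml_config(path, allowed_fields) -> dict:
    """Load a YAML mapping, rejecting unknown keys (typo guard)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ManifestError(f"config {path}: expected a mapping")
    unknown = sorted(set(data) - set(allowed_fields))
    if unknown:
        raise ManifestError(f"config {path}: unknown keys {unknown}")
    return data
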