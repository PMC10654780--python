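"""Readers and writers for trial containers, feature matrices and models.

Formats are deliberately plain: a JSON manifest plus a raw little-endian
float64 payload for trial sets, delimited text with a metadata sidecar for
feature matrices, and JSON for fitted models (floats at 17 significant
digits so weights round-trip exactly and the selected-feature list stays
auditable).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CSPModel, EEGTrialSet, ExtractionConfig, FeatureMatrix, TimeFrequencyUnit
from .penalties import PenaltySpec
from .pipeline import DecodingModel, Standardizer
from .solver import SolverConfig

__all__ = [
    "FormatError",
    "RunConfig",
    "read_trials",
    "write_trials",
    "read_features",
    "write_features",
    "save_model",
    "load_model",
    "read_config",
    "write_config",
]

MODEL_VERSION = 1
TRIALS_VERSION = 1


class FormatError(ValueError):
    """Malformed container, manifest or model file."""


# ---------------------------------------------------------------------------
# trial container: manifest.json + data.bin + labels.txt


def write_trials(trials: EEGTrialSet, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "sparseeg-trials",
        "version": TRIALS_VERSION,
        "fs": trials.fs,
        "shape": list(trials.data.shape),
        "trial_window": list(trials.trial_window),
        "dtype": "float64",
        "byteorder": "little",
        "data_file": "data.bin",
        "labels_file": "labels.txt",
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    trials.data.astype("<f8").tofile(path / "data.bin")
    np.savetxt(path / "labels.txt", trials.labels, fmt="%d")


def read_trials(path: str | Path) -> EEGTrialSet:
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
    except FileNotFoundError as e:
        raise FormatError(f"missing manifest.json in {path}") from e
    for key in ("fs", "shape", "data_file", "labels_file"):
        if key not in manifest:
            raise FormatError(f"manifest missing field {key!r}")
    if manifest.get("version", 0) != TRIALS_VERSION:
        raise FormatError(
            f"trial container version {manifest.get('version')} "
            f"!= supported {TRIALS_VERSION}"
        )
    shape = tuple(manifest["shape"])
    raw = np.fromfile(path / manifest["data_file"], dtype="<f8")
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"data_file: payload has {raw.size} values, manifest shape "
            f"{shape} needs {int(np.prod(shape))}"
        )
    labels = np.loadtxt(path / manifest["labels_file"], dtype=int, ndmin=1)
    if labels.shape != (shape[0],):
        raise FormatError(
            f"labels_file: {labels.size} labels for {shape[0]} trials"
        )
    return EEGTrialSet(
        data=raw.reshape(shape),
        fs=float(manifest["fs"]),
        labels=labels,
        trial_window=tuple(manifest.get("trial_window", (0.0, shape[2] / manifest["fs"]))),
    )


# ---------------------------------------------------------------------------
# feature matrices: features.csv + meta.csv


def write_features(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fm.X, columns=[f"f{j:04d}" for j in range(fm.X.shape[1])])
    df.insert(0, "y", fm.y)
    df.to_csv(path / "features.csv", index=False, float_format="%.17g")
    meta = pd.DataFrame(fm.meta)
    meta.insert(0, "column", np.arange(len(fm.meta)))
    meta.to_csv(path / "meta.csv", index=False)


def read_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path / "features.csv")
        meta = pd.read_csv(path / "meta.csv")
    except FileNotFoundError as e:
        raise FormatError(f"missing features.csv/meta.csv in {path}") from e
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise FormatError("empty feature matrix")
    y = df["y"].to_numpy(dtype=int)
    X = df.drop(columns="y").to_numpy(dtype=float)
    if len(meta) != X.shape[1]:
        raise FormatError(
            f"metadata rows ({len(meta)}) != feature columns ({X.shape[1]})"
        )
    meta_rows = meta.drop(columns="column").to_dict("records")
    return FeatureMatrix(X=X, y=y, meta=meta_rows)


# ---------------------------------------------------------------------------
# model files (JSON)


def _unit_to_list(u: TimeFrequencyUnit) -> list:
    return [list(u.window), list(u.band)]


def save_model(model: DecodingModel, path: str | Path) -> None:
    doc = {
        "format": "sparseeg-model",
        "version": MODEL_VERSION,
        "spec": {
            "family": model.spec.family,
            "lam": model.spec.lam,
            "gamma": model.spec.gamma,
            "lam_group": model.spec.lam_group,
            "groups": None if model.spec.groups is None else model.spec.groups.tolist(),
        },
        "standardizer": {
            "mean": model.standardizer.mean.tolist(),
            "scale": model.standardizer.scale.tolist(),
        },
        "w": model.w.tolist(),
        "selected": model.selected.tolist(),
        "extraction": (
            dataclasses.asdict(model.extraction) if model.extraction else None
        ),
        "csp": None if model.csp is None else {
            "units": [_unit_to_list(u) for u in model.csp.units],
            "filters": [f.tolist() for f in model.csp.filters],
            "eigvals": [e.tolist() for e in model.csp.eigvals],
            "n_pairs": model.csp.n_pairs,
        },
        "meta": model.meta,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path) -> DecodingModel:
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, FileNotFoundError) as e:
        raise FormatError(f"unreadable model file {path}: {e}") from e
    if doc.get("format") != "sparseeg-model":
        raise FormatError(f"{path} is not a sparseeg model file")
    if doc.get("version") != MODEL_VERSION:
        raise FormatError(
            f"model version {doc.get('version')} != supported {MODEL_VERSION}"
        )
    spec = PenaltySpec(
        family=doc["spec"]["family"],
        lam=doc["spec"]["lam"],
        gamma=doc["spec"]["gamma"],
        lam_group=doc["spec"]["lam_group"],
        groups=None if doc["spec"]["groups"] is None else np.array(doc["spec"]["groups"]),
    )
    csp = None
    if doc.get("csp"):
        csp = CSPModel(
            units=[
                TimeFrequencyUnit(tuple(w), tuple(b)) for w, b in doc["csp"]["units"]
            ],
            filters=[np.array(f) for f in doc["csp"]["filters"]],
            eigvals=[np.array(e) for e in doc["csp"]["eigvals"]],
            n_pairs=doc["csp"]["n_pairs"],
        )
    extraction = (
        ExtractionConfig(**doc["extraction"]) if doc.get("extraction") else None
    )
    return DecodingModel(
        standardizer=Standardizer(
            mean=np.array(doc["standardizer"]["mean"]),
            scale=np.array(doc["standardizer"]["scale"]),
        ),
        spec=spec,
        w=np.array(doc["w"]),
        selected=np.array(doc["selected"], dtype=int),
        extraction=extraction,
        csp=csp,
        meta=doc.get("meta"),
    )


# ---------------------------------------------------------------------------
# flat key=value run configuration


@dataclasses.dataclass
class RunConfig:
    """Flat end-to-end run settings, round-trippable through a text file."""

    family: str = "cauchy"
    lam: float | None = None
    gamma: float | None = None
    lam_group: float = 0.5
    folds: int = 10
    seed: int = 0
    win_len_s: float = 2.0
    win_step_s: float = 0.5
    band_lo: float = 4.0
    band_hi: float = 40.0
    band_width: float = 4.0
    band_step: float = 2.0
    filter_order: int = 6
    n_pairs: int = 1
    max_iter: int = 1000
    tol: float = 1e-6

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            win_len_s=self.win_len_s, win_step_s=self.win_step_s,
            band_lo=self.band_lo, band_hi=self.band_hi,
            band_width=self.band_width, band_step=self.band_step,
            filter_order=self.filter_order, n_pairs=self.n_pairs,
        )

    def solver(self) -> SolverConfig:
        return SolverConfig(max_iter=self.max_iter, tol=self.tol)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        lines.append(f"{f.name} = {'' if v is None else repr(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    kwargs = {}
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in fields:
            raise FormatError(f"line {lineno}: unknown config key {key!r}")
        if val == "" or val == "None":
            kwargs[key] = None
            continue
        ftype = fields[key].type
        if "str" in str(ftype):
            kwargs[key] = val.strip("'\"")
        elif "int" in str(ftype):
            kwargs[key] = int(val)
        else:
            kwargs[key] = float(val)
    return RunConfig(**kwargs)
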