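"""End-to-end workflows: dataset I/O, feature screening, greedy forward
selection, and the exact-vs-approximate experiment runner.

The deployed configuration uses four of the nine candidate features --
conductivity difference, peroxide at 60 degC, peroxide at 25 degC,
conductivity at 60 degC -- a 600-entry ROM, a 60:40 train/test split and
k = 7 neighbors.  ``run_experiment`` evaluates the held-out split under both
an exact multiplier and a chosen approximate one and reports the accuracy gap.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import approx_arith, evalmetrics, knn_core, oilgen

__all__ = [
    "DEPLOYED_FEATURES",
    "MULTIPLIER_CHOICES",
    "FeatureSet",
    "ExperimentConfig",
    "multiplier_fn",
    "multiplier_square_table",
    "read_dataset_csv",
    "write_dataset_csv",
    "single_feature_screen",
    "greedy_forward",
    "run_experiment",
    "compare_classifiers",
]

DEPLOYED_FEATURES: Tuple[str, ...] = ("dvconduc", "60ox", "25ox", "60conduc")
MULTIPLIER_CHOICES = ("exact", "functional", "table10")

_SCHEMA = ("sample_id", "group", "major_id", "minor_id", "ratio", "seasoning_mask") + oilgen.FEATURES + ("label",)


@dataclass(frozen=True)
class FeatureSet:
    """Ordered subset of the nine candidate features with screening provenance."""

    names: Tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError("feature set may not be empty")
        unknown = [n for n in self.names if n not in oilgen.FEATURES]
        if unknown:
            raise ValueError(f"unknown feature names: {unknown}")


@dataclass
class ExperimentConfig:
    """Defaults reproduce the deployed configuration."""

    generator: oilgen.GeneratorConfig = field(default_factory=oilgen.GeneratorConfig)
    split_fraction: float = 0.6
    split_seed: int = 0
    rom_size: int = knn_core.ROM_CAPACITY
    rom_seed: int = 0
    features: Tuple[str, ...] = DEPLOYED_FEATURES
    multiplier: str = "table10"

    def to_dict(self) -> dict:
        return {
            "generator": self.generator.to_dict(),
            "split_fraction": self.split_fraction,
            "split_seed": self.split_seed,
            "rom_size": self.rom_size,
            "rom_seed": self.rom_seed,
            "features": list(self.features),
            "multiplier": self.multiplier,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(
            generator=oilgen.GeneratorConfig.from_dict(d.get("generator", {})),
            split_fraction=d.get("split_fraction", 0.6),
            split_seed=d.get("split_seed", 0),
            rom_size=d.get("rom_size", knn_core.ROM_CAPACITY),
            rom_seed=d.get("rom_seed", 0),
            features=tuple(d.get("features", DEPLOYED_FEATURES)),
            multiplier=d.get("multiplier", "table10"),
        )


def multiplier_fn(name: str) -> Optional[Callable[[int, int], int]]:
    """Scalar 8x8 multiplier by name; None denotes exact native multiplication."""
    if name == "exact":
        return None
    if name in ("functional", "table10"):
        cfg = (
            approx_arith.functional_mult4_config()
            if name == "functional"
            else approx_arith.table10_mult4_config()
        )
        sub = lambda n, m: approx_arith.mult4_table(n, m, cfg)  # noqa: E731
        return lambda a, b: approx_arith.mult8_approx(a, b, sub)
    if os.path.exists(name):  # a serialized custom config
        with open(name) as fh:
            cfg = approx_arith.config_from_json(fh.read())
        sub = lambda n, m: approx_arith.mult4_table(n, m, cfg)  # noqa: E731
        return lambda a, b: approx_arith.mult8_approx(a, b, sub)
    raise ValueError(f"unknown multiplier '{name}' (expected one of {MULTIPLIER_CHOICES} or a config path)")


def multiplier_square_table(name: str) -> np.ndarray:
    """256-entry diagonal table mult(v, v) for vectorized distance evaluation."""
    fn = multiplier_fn(name)
    return knn_core.square_table(fn)


# ---------------------------------------------------------------------------
# dataset I/O

def write_dataset_csv(df: pd.DataFrame, path: str) -> None:
    """Schema-validated, deterministic-column-order CSV write (atomic)."""
    _validate_schema(df)
    out = df[list(_SCHEMA)]
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".csv.tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            out.to_csv(fh, index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_dataset_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"seasoning_mask": str, "minor_id": str}, keep_default_na=False)
    df["seasoning_mask"] = df["seasoning_mask"].astype(str).str.zfill(len(oilgen.SEASONINGS))
    _validate_schema(df)
    for col in oilgen.FEATURES + ("ratio",):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"column '{col}' contains non-numeric cells")
    labels = df["label"].to_numpy()
    if ((labels < 0) | (labels >= evalmetrics.N_CLASSES)).any():
        raise ValueError(f"label column contains values outside 0..{evalmetrics.N_CLASSES - 1}")
    return df


def _validate_schema(df: pd.DataFrame) -> None:
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in _SCHEMA]
    if unknown:
        raise ValueError(f"dataset contains unknown columns: {unknown}")


# ---------------------------------------------------------------------------
# classification helpers

def _fit_and_classify(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: Sequence[str],
    rom_size: int,
    rom_seed: int,
    sq_table: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, knn_core.Rom]:
    X_train = train[list(features)].to_numpy(dtype=float)
    y_train = train["label"].to_numpy(dtype=int)
    params = knn_core.fit_quantizer(X_train, features)
    rom = knn_core.build_rom(X_train, y_train, params, rom_size=rom_size, seed=rom_seed)
    X_test = test[list(features)].to_numpy(dtype=float)
    preds = knn_core.classify_batch(X_test, rom, sq_table)
    return preds, rom


def single_feature_screen(
    df: pd.DataFrame,
    split_seed: int = 0,
    rom_size: int = knn_core.ROM_CAPACITY,
    rom_seed: int = 0,
) -> Dict[str, float]:
    """Held-out k-NN accuracy of each candidate feature alone (exact multiplier)."""
    for f in oilgen.FEATURES:
        if f not in df.columns:
            raise ValueError(f"dataset is missing feature column '{f}'")
    train, test = oilgen.split(df, 0.6, seed=split_seed)
    y_test = test["label"].to_numpy(dtype=int)
    result = {}
    for f in oilgen.FEATURES:
        preds, _ = _fit_and_classify(train, test, (f,), rom_size, rom_seed)
        result[f] = float(np.mean(preds == y_test))
    return result


def greedy_forward(
    df: pd.DataFrame,
    screen_result: Dict[str, float],
    split_seed: int = 0,
    rom_size: int = knn_core.ROM_CAPACITY,
    rom_seed: int = 0,
    max_features: Optional[int] = None,
) -> List[Tuple[Tuple[str, ...], float]]:
    """Accuracy trajectory as features are added in decreasing screened accuracy."""
    ranked = sorted(screen_result, key=lambda f: (-screen_result[f], f))
    if max_features is not None:
        ranked = ranked[:max_features]
    train, test = oilgen.split(df, 0.6, seed=split_seed)
    y_test = test["label"].to_numpy(dtype=int)
    trajectory = []
    for k in range(1, len(ranked) + 1):
        feats = tuple(ranked[:k])
        preds, _ = _fit_and_classify(train, test, feats, rom_size, rom_seed)
        trajectory.append((feats, float(np.mean(preds == y_test))))
    return trajectory


def run_experiment(config: Optional[ExperimentConfig] = None) -> dict:
    """Generate -> split -> fit -> evaluate under exact AND approximate multipliers.

    Returns a JSON-serializable report with both metric bundles, the accuracy
    gap, and the fully resolved configuration (all seeds included).
    """
    cfg = config or ExperimentConfig()
    df = oilgen.generate(cfg.generator)
    train, test = oilgen.split(df, cfg.split_fraction, seed=cfg.split_seed)
    y_test = test["label"].to_numpy(dtype=int)

    preds_exact, rom = _fit_and_classify(
        train, test, cfg.features, cfg.rom_size, cfg.rom_seed, sq_table=None
    )
    sq_approx = multiplier_square_table(cfg.multiplier)
    X_test = test[list(cfg.features)].to_numpy(dtype=float)
    preds_approx = knn_core.classify_batch(X_test, rom, sq_approx)

    report_exact = evalmetrics.evaluate(y_test, preds_exact)
    report_approx = evalmetrics.evaluate(y_test, preds_approx)
    return {
        "config": cfg.to_dict(),
        "n_train": len(train),
        "n_test": len(test),
        "exact": report_exact.to_dict(),
        "approximate": report_approx.to_dict(),
        "accuracy_gap": report_exact.accuracy - report_approx.accuracy,
        "prediction_agreement": float(np.mean(preds_exact == preds_approx)),
    }


def compare_classifiers(
    df: pd.DataFrame, features: Sequence[str] = DEPLOYED_FEATURES, split_seed: int = 0
) -> Dict[str, float]:
    """Optional harness: held-out accuracy of standard scikit-learn classifiers.

    Requires the ``compare`` extra; the core pipeline never depends on it.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    train, test = oilgen.split(df, 0.6, seed=split_seed)
    X_tr = train[list(features)].to_numpy(dtype=float)
    y_tr = train["label"].to_numpy(dtype=int)
    X_te = test[list(features)].to_numpy(dtype=float)
    y_te = test["label"].to_numpy(dtype=int)
    models = {
        "ANN": MLPClassifier(max_iter=500, random_state=split_seed),
        "DT": DecisionTreeClassifier(random_state=split_seed),
        "RF": RandomForestClassifier(random_state=split_seed),
        "SVM": SVC(random_state=split_seed),
    }
    return {name: float(m.fit(X_tr, y_tr).score(X_te, y_te)) for name, m in models.items()}


def write_json(obj: dict, path: str) -> None:
    """Atomic, deterministic JSON write."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".json.tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
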