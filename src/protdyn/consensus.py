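"""Consensus ΔΔG predictor: feature assembly and Random-Forest regression.

Each mutation is described by normal-mode features (vibrational-entropy
change and its ENM stability estimate from the sequence-dependent force
field, fluctuation ratio from the ANM), graph-based signature counts and
pharmacophore deltas, wild-type environment features (RSA, depth, secondary
structure) and a forward/reverse direction flag. External predictor values
(e.g. from other published tools) can be merged as optional columns but are
never computed here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dataset import (MetricsReport, MutationRecord, classify_stability,
                      evaluate, make_splits)
from .dynamics import mutation_dynamics
from .enm import EncomParams
from .signatures import (PHARMACOPHORE_CLASSES, SignatureVector,
                         cutoff_scan_signature, mutation_pharmacophore_delta,
                         relative_solvent_accessibility, residue_depth,
                         secondary_structure)
from .structure import MutationSpec, Structure, build_mutant

__all__ = [
    "SCHEMA_VERSION",
    "RFParams",
    "ConsensusModel",
    "FeaturizeConfig",
    "feature_schema",
    "schema_hash",
    "featurize_mutation",
    "train_consensus",
    "predict_ddg",
    "save_model",
    "load_model",
    "ModelIOError",
]

SCHEMA_VERSION = "1"
_SIG_BINS = (2.0, 4.0, 6.0, 8.0, 10.0)


class ModelIOError(IOError):
    """Raised when a model archive cannot be loaded."""


@dataclass
class FeaturizeConfig:
    signature_radius: float = 10.0
    alpha: float = 1.0
    anm_cutoff: float = 15.0
    anm_gamma: float = 1.0
    encom_params: EncomParams | None = None
    external_columns: tuple[str, ...] = ()
    sasa_points: int = 128


def feature_schema(external_columns: tuple[str, ...] = ()) -> list[str]:
    """Ordered, stable feature-column names."""
    names = ["dds_vib", "enm_ddg", "msf_ratio_site"]
    names += [f"delta_{c}" for c in PHARMACOPHORE_CLASSES]
    names += SignatureVector.feature_names(_SIG_BINS)
    names += ["rsa", "depth", "ss_helix", "ss_strand", "ss_coil", "direction"]
    for col in external_columns:
        names += [f"ext_{col}", f"ext_{col}_present"]
    return names


def schema_hash(columns) -> str:
    payload = f"v{SCHEMA_VERSION}|" + ",".join(columns)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def featurize_mutation(
    wt: Structure,
    mutation: MutationSpec,
    config: FeaturizeConfig | None = None,
    mut: Structure | None = None,
    direction: str = "forward",
    external: dict[str, float] | None = None,
) -> pd.Series:
    """Assemble the feature vector for one mutation on a wild-type structure.

    The sequence-dependent force field supplies ΔΔS_vib and the ENM ΔΔG;
    the ANM supplies the fluctuation ratio at the mutated site; signatures
    and environment features describe the wild-type residue. Upstream
    failures are re-raised with the failing stage named.
    """
    if config is None:
        config = FeaturizeConfig()
    values: dict[str, float] = {}
    try:
        if mut is None:
            mut = build_mutant(wt, mutation)
    except Exception as exc:
        raise RuntimeError(f"mutant building failed: {exc}") from exc
    try:
        dyn_encom = mutation_dynamics(
            wt, mutation, forcefield="encom", mut=mut, alpha=config.alpha,
            encom_params=config.encom_params)
        dyn_anm = mutation_dynamics(
            wt, mutation, forcefield="anm", mut=mut,
            anm_cutoff=config.anm_cutoff, anm_gamma=config.anm_gamma)
    except Exception as exc:
        raise RuntimeError(f"normal-mode analysis failed: {exc}") from exc
    values["dds_vib"] = dyn_encom.dds_vib
    values["enm_ddg"] = dyn_encom.enm_ddg
    values["msf_ratio_site"] = dyn_anm.msf_ratio_site

    delta = mutation_pharmacophore_delta(mutation.wild_aa, mutation.mutant_aa)
    for cls, d in zip(PHARMACOPHORE_CLASSES, delta):
        values[f"delta_{cls}"] = float(d)

    try:
        sig = cutoff_scan_signature(
            wt, mutation.chain_id, mutation.residue_number,
            mutation.insertion_code, radius=config.signature_radius,
            bin_edges=_SIG_BINS)
        for name, count in zip(SignatureVector.feature_names(_SIG_BINS),
                               sig.flat()):
            values[name] = float(count)
    except Exception as exc:
        raise RuntimeError(f"signature computation failed: {exc}") from exc

    try:
        loc = (mutation.chain_id, mutation.residue_number,
               mutation.insertion_code)
        values["rsa"] = relative_solvent_accessibility(
            wt, *loc, n_points=config.sasa_points)
        values["depth"] = residue_depth(wt, *loc, n_points=config.sasa_points)
        ss = secondary_structure(wt, *loc)
    except Exception as exc:
        raise RuntimeError(f"environment features failed: {exc}") from exc
    for cls in ("helix", "strand", "coil"):
        values[f"ss_{cls}"] = 1.0 if ss == cls else 0.0
    values["direction"] = 0.0 if direction == "forward" else 1.0

    external = external or {}
    for col in config.external_columns:
        present = col in external and external[col] is not None
        values[f"ext_{col}"] = float(external[col]) if present else 0.0
        values[f"ext_{col}_present"] = 1.0 if present else 0.0

    schema = feature_schema(config.external_columns)
    return pd.Series([values[c] for c in schema], index=schema, dtype=float)


@dataclass
class RFParams:
    n_trees: int = 500
    max_depth: int | None = None
    max_features: str | float = "sqrt"


@dataclass
class ConsensusModel:
    forest: RandomForestRegressor
    schema: list[str]
    schema_hash: str
    metadata: dict = field(default_factory=dict)


def _dummy_records(targets: np.ndarray, groups: list[str] | None,
                   directions: list[str] | None = None) -> list[MutationRecord]:
    recs = []
    for i, t in enumerate(targets):
        spec = MutationSpec(chain_id="A", wild_aa="A", residue_number=i + 1,
                            mutant_aa="G")
        recs.append(MutationRecord(
            pdb_id="ROW", chain_id="A", mutation=spec, ddg_exp=float(t),
            direction=directions[i] if directions else "forward",
            group_key=groups[i] if groups else str(i)))
    return recs


def train_consensus(
    features: pd.DataFrame,
    targets,
    hyperparams: RFParams | None = None,
    seed: int = 0,
    cv_folds: int = 10,
    groups: list[str] | None = None,
) -> ConsensusModel:
    """Fit the Random-Forest consensus regressor with k-fold CV reporting.

    Cross-validation respects ``groups`` (e.g. forward/reverse pairs of one
    mutation share a group and never straddle folds). The returned model is
    refit on all rows; CV metrics, seed and schema hash are recorded in its
    metadata.
    """
    if hyperparams is None:
        hyperparams = RFParams()
    y = np.asarray(targets, dtype=float)
    if len(features) != len(y):
        raise ValueError("features and targets are not aligned")
    if len(y) < 50:
        raise ValueError("need at least 50 training rows")
    if np.any(~np.isfinite(y)):
        raise ValueError("NaN or infinite target values")
    constant = [c for c in features.columns if features[c].nunique() <= 1]

    def new_forest():
        return RandomForestRegressor(
            n_estimators=hyperparams.n_trees,
            max_depth=hyperparams.max_depth,
            max_features=hyperparams.max_features,
            random_state=seed,
            n_jobs=1,
        )

    x = features.to_numpy(dtype=float)
    directions = None
    if "direction" in features.columns:
        directions = ["reverse" if v else "forward"
                      for v in features["direction"].to_numpy() > 0.5]
    records = _dummy_records(y, groups, directions)
    index_of = {id(r): i for i, r in enumerate(records)}
    folds = make_splits(records, mode="kfold", k=cv_folds, seed=seed)
    oof_pred = np.full(len(y), np.nan)
    for fold in folds:
        test_idx = np.array([index_of[id(r)] for r in fold])
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        forest = new_forest()
        forest.fit(x[train_mask], y[train_mask])
        oof_pred[test_idx] = forest.predict(x[test_idx])
    cv_report = evaluate(oof_pred, records)

    final = new_forest()
    final.fit(x, y)
    columns = list(features.columns)
    return ConsensusModel(
        forest=final,
        schema=columns,
        schema_hash=schema_hash(columns),
        metadata={
            "n_train": len(y),
            "seed": seed,
            "cv_folds": cv_folds,
            "hyperparams": {
                "n_trees": hyperparams.n_trees,
                "max_depth": hyperparams.max_depth,
                "max_features": hyperparams.max_features,
            },
            "cv_metrics": cv_report.to_dict(),
            "constant_features": constant,
        },
    )


def cv_report(model: ConsensusModel) -> MetricsReport:
    m = model.metadata["cv_metrics"]
    return MetricsReport(
        n=m["n"], pearson_r=m["pearson_r"], rmse=m["rmse"],
        pearson_r_trimmed=m["pearson_r_trimmed"],
        rmse_trimmed=m["rmse_trimmed"], n_trimmed=m["n_trimmed"],
        outlier_fraction=m["outlier_fraction"],
    )


def predict_ddg(model: ConsensusModel, features):
    """Predict ΔΔG (kcal/mol) and the stability class for feature rows.

    Accepts a Series (one mutation) or a DataFrame; refuses on schema-hash
    mismatch.
    """
    if isinstance(features, pd.Series):
        frame = features.to_frame().T
    else:
        frame = features
    incoming = schema_hash(list(frame.columns))
    if incoming != model.schema_hash:
        raise ValueError(
            f"feature schema mismatch: model {model.schema_hash}, "
            f"input {incoming}"
        )
    pred = model.forest.predict(frame.to_numpy(dtype=float))
    classes = [classify_stability(v) for v in pred]
    if isinstance(features, pd.Series):
        return float(pred[0]), classes[0]
    return pred, classes


_ARCHIVE_VERSION = 1


def save_model(model: ConsensusModel, path: str | Path) -> None:
    joblib.dump(
        {
            "archive_version": _ARCHIVE_VERSION,
            "schema_version": SCHEMA_VERSION,
            "schema": model.schema,
            "schema_hash": model.schema_hash,
            "forest": model.forest,
            "metadata": model.metadata,
        },
        path,
    )


def load_model(path: str | Path) -> ConsensusModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelIOError(f"cannot read model archive {path}: {exc}") from exc
    if not isinstance(payload, dict) or "archive_version" not in payload:
        raise ModelIOError(f"{path} is not a consensus model archive")
    if payload["archive_version"] != _ARCHIVE_VERSION:
        raise ModelIOError(
            f"archive version {payload['archive_version']} not supported "
            f"(expected {_ARCHIVE_VERSION})"
        )
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ModelIOError("feature schema version mismatch")
    return ConsensusModel(
        forest=payload["forest"],
        schema=payload["schema"],
        schema_hash=payload["schema_hash"],
        metadata=payload["metadata"],
    )
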