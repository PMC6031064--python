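#!/usr/bin/env python
"""Full training/blind-evaluation harness for a user-supplied benchmark.

Expects a curated mutation table (CSV/TSV with columns pdb_id, chain,
mutation, ddg) and a directory of matching PDB files named <pdb_id>.pdb.
Featurizes every mutation (forward, plus the hypothetical reverse
featurized against the modelled mutant structure), trains the Random-Forest
consensus under group-aware 10-fold cross-validation, evaluates on a
held-out blind split, and writes metrics JSON plus the trained model.

Example:
    python scripts/run_benchmark.py \
        --table s2648.csv --structures-dir pdbs/ \
        --out-dir results/benchmark --seed 1

This script is documentation for the full protocol; it is not part of the
test suite and requires the dataset and structures to be provided locally
(nothing is downloaded).
"""

from __future__ import annotations

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from protdyn.consensus import (FeaturizeConfig, RFParams, featurize_mutation,
                               predict_ddg, save_model, train_consensus)
from protdyn.dataset import (augment_reverse, evaluate, make_splits,
                             read_mutation_table)
from protdyn.structure import build_mutant, read_structure


def featurize_records(records, structures_dir: Path, config: FeaturizeConfig):
    """Feature rows for forward and reverse records; reverse records are
    featurized against the modelled mutant structure as 'wild type'."""
    cache: dict[str, object] = {}
    rows, kept, failures = [], [], []
    for rec in records:
        try:
            pdb_path = structures_dir / f"{rec.pdb_id.lower()}.pdb"
            if rec.pdb_id not in cache:
                cache[rec.pdb_id] = read_structure(pdb_path)
            wt = cache[rec.pdb_id]
            if rec.direction == "forward":
                fv = featurize_mutation(wt, rec.mutation, config=config)
            else:
                forward_spec = rec.mutation.reverse()
                mutant = build_mutant(wt, forward_spec)
                fv = featurize_mutation(mutant, rec.mutation, config=config,
                                        mut=wt, direction="reverse")
            rows.append(fv)
            kept.append(rec)
        except Exception as exc:
            failures.append((rec.pdb_id, str(rec.mutation), str(exc)))
    return pd.DataFrame(rows).reset_index(drop=True), kept, failures


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--table", required=True, type=Path)
    parser.add_argument("--structures-dir", required=True, type=Path)
    parser.add_argument("--out-dir", required=True, type=Path)
    parser.add_argument("--sign-convention", default="stabilizing_positive",
                        choices=["stabilizing_positive",
                                 "destabilizing_positive"])
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-trees", type=int, default=500)
    args = parser.parse_args()

    records, rejected = read_mutation_table(args.table,
                                            sign_convention=args.sign_convention)
    if rejected:
        print(f"{len(rejected)} malformed rows rejected", file=sys.stderr)
    missing = sorted({
        r.pdb_id for r in records
        if not (args.structures_dir / f"{r.pdb_id.lower()}.pdb").exists()
    })
    if missing:
        sys.exit(f"missing structure files for: {', '.join(missing)}")

    train_fwd, blind_fwd = make_splits(records, mode="train_blind",
                                       seed=args.seed)
    train_recs, _ = augment_reverse(train_fwd)
    blind_recs, _ = augment_reverse(blind_fwd)

    config = FeaturizeConfig()
    x_train, train_kept, fail_train = featurize_records(
        train_recs, args.structures_dir, config)
    x_blind, blind_kept, fail_blind = featurize_records(
        blind_recs, args.structures_dir, config)
    for pdb, mut, err in fail_train + fail_blind:
        print(f"featurization failed: {pdb} {mut}: {err}", file=sys.stderr)

    y_train = np.array([r.ddg_exp for r in train_kept])
    model = train_consensus(x_train, y_train,
                            hyperparams=RFParams(n_trees=args.n_trees),
                            seed=args.seed,
                            groups=[r.group_key for r in train_kept])
    pred_blind, _ = predict_ddg(model, x_blind)
    blind_report = evaluate(pred_blind, blind_kept)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    save_model(model, args.out_dir / "consensus_model.joblib")
    payload = {
        "seed": args.seed,
        "n_train": len(train_kept),
        "n_blind": len(blind_kept),
        "n_failed": len(fail_train) + len(fail_blind),
        "cv_metrics": model.metadata["cv_metrics"],
        "blind_metrics": blind_report.to_dict(),
    }
    (args.out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))
    print(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
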