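#!/usr/bin/env python
"""Optional reproduction of the CTCF ChIP-seq study on real data.

This script is NOT part of the test suite: it requires the study's
deposited sequence data (FASTA files of ChIP-seq positive and negative
sequences for a cell line, e.g. H1-hESC), which must be downloaded
separately, and a full run takes hours on one CPU.

Given positive and negative FASTA files it
  1. filters ambiguous sequences and splits each class 2:1 (seeded),
  2. trains the order-2 background model on the union of the training data,
  3. optionally cross-validates log2(kappa) on the training split,
  4. trains the PMM (width 20, order 4) and its PWM limit by ZOOPS-EM and
     reports sensitivity at 99% specificity on the test split,
  5. predicts binding sites at a window-level significance alpha and
     reports the count and the total PCT leaf count.

For the H1-hESC data the reference points are roughly: 3,264 / 6,528
sequences, 2,176 training positives, sensitivities near 85% (PMM) and 71%
(PWM), ~3.5k predicted sites (alpha calibrated), and ~132 leaves.

Usage:
    python scripts/reproduce_encode.py --pos positives.fa --neg negatives.fa \
        --out results/encode --seed 1 [--cv] [--log2-kappa -4.5] [--alpha 1e-4]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from parsimotif.evaluation import (
    cross_validate_kappa,
    cv_table,
    sensitivity_at_specificity,
    train_background,
)
from parsimotif.io import filter_ambiguous, make_labeled_dataset, read_fasta
from parsimotif.markov import leaf_statistics
from parsimotif.prediction import compute_threshold, predict_sites, window_likelihoods
from parsimotif.zoops import MotifDiscovery, ZOOPSConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pos", type=Path, required=True)
    ap.add_argument("--neg", type=Path, required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cv", action="store_true", help="cross-validate log2(kappa) first")
    ap.add_argument("--log2-kappa", type=float, default=-4.5)
    ap.add_argument("--alpha", type=float, default=1e-4)
    ap.add_argument("--restarts", type=int, default=10)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pos = filter_ambiguous(read_fasta(args.pos))
    neg = filter_ambiguous(read_fasta(args.neg))
    ds = make_labeled_dataset(pos, neg, (2, 1), seed=args.seed)
    tr_pos, tr_neg = ds.subset("positive", "train"), ds.subset("negative", "train")
    te_pos, te_neg = ds.subset("positive", "test"), ds.subset("negative", "test")
    print(f"{len(pos)} positives / {len(neg)} negatives; {len(tr_pos)} training positives")

    bg = train_background(tr_pos, tr_neg, order=2, ess=4.0)

    kappa = args.log2_kappa
    if args.cv:
        cfg = ZOOPSConfig(restarts=args.restarts)
        results, kappa = cross_validate_kappa(
            tr_pos, tr_neg, folds=10, config=cfg, seed=args.seed
        )
        cv_table(results).to_csv(args.out / "cv.tsv", sep="\t", index=False)
        print(f"selected log2(kappa) = {kappa}")

    bgp = np.array([bg.log_prob(r.seq) for r in te_pos])
    bgn = np.array([bg.log_prob(r.seq) for r in te_neg])
    report = {}
    models = {}
    for name, kw in (
        ("pmm", dict(max_order=4, log2_kappa=kappa)),
        ("pwm", dict(max_order=4, log2_kappa=-1000.0)),
        ("wam", dict(max_order=1, log2_kappa=1000.0)),
    ):
        res = MotifDiscovery(tr_pos, width=20, flanking=bg, **kw).fit(
            restarts=args.restarts, seed=args.seed
        )
        models[name] = res
        sens = sensitivity_at_specificity(
            res.log_likelihood(te_pos) - bgp, res.log_likelihood(te_neg) - bgn, 0.99
        )
        report[f"{name}_sensitivity_pct"] = 100 * sens
        report[f"{name}_total_leaves"] = leaf_statistics(res.motif)[1]
        print(f"{name}: sensitivity@99% = {100 * sens:.1f}%")

    pmm = models["pmm"]
    negw = window_likelihoods(pmm.motif, te_neg)["log_likelihood"].to_numpy()
    thr = compute_threshold(negw, args.alpha)
    sites = predict_sites(pmm.motif, te_pos, thr)
    report["n_predicted_sites"] = len(sites)
    report["alpha"] = args.alpha
    print(f"{len(sites)} predicted sites at alpha = {args.alpha}")

    pmm.zoops.to_json(args.out / "model.json", metadata={"seed": args.seed, "log2_kappa": kappa})
    (args.out / "report.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
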