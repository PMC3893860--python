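"""Fivefold cross-validation, threshold sweeps and ROC summaries.

The evaluation protocol: the positive and negative sets are each divided
randomly into k near-equal parts (stratified); each part is tested once by
a model trained on the remaining parts.  Performance is reported as
sensitivity, specificity and accuracy in percent plus the Matthews
correlation coefficient, at every decision threshold from -1 to +1 in
steps of 0.1.  Both the pooled sweep (all held-out scores tallied
together) and the across-fold average of per-fold metrics are reported;
the pooled sweep is the headline because a threshold means the same thing
in every fold there.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from il4kit.peptide_io import PeptideDataset, ValidationError
from il4kit.features import fit_aap_table
from il4kit.model import IL4Model, SVMConfig, PredictionResult, default_config
from il4kit.motifs import discover_hybrid_motifs

logger = logging.getLogger(__name__)

#: default decision-threshold grid: -1.0, -0.9, ..., +1.0
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def make_folds(
    pos: PeptideDataset, neg: PeptideDataset, k: int = 5, seed: int = 42
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random fold assignment, deterministic given the seed.

    Returns per-class integer arrays of fold ids in 0..k-1; within each
    class the fold sizes differ by at most one.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(pos) < k or len(neg) < k:
        raise ValidationError(f"each class needs at least k={k} members")
    rng = np.random.default_rng(seed)

    def assign(n: int) -> np.ndarray:
        folds = np.empty(n, dtype=int)
        folds[rng.permutation(n)] = np.arange(n) % k
        return folds

    return assign(len(pos)), assign(len(neg))


def _usable(results) -> list[PredictionResult]:
    return [r for r in results if r.ok]


def confusion_at(
    results, threshold: float, use_hybrid: bool = False
) -> ConfusionCounts:
    """Tally predictions (score >= threshold -> positive) against labels."""
    tp = fp = tn = fn = 0
    for r in _usable(results):
        if r.label not in ("positive", "negative"):
            raise ValidationError(f"peptide {r.id!r} is unlabeled")
        pred_pos = r.score(use_hybrid) >= threshold
        if r.label == "positive":
            tp += pred_pos
            fn += not pred_pos
        else:
            fp += pred_pos
            tn += not pred_pos
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(c: ConfusionCounts) -> dict:
    """Sensitivity/specificity/accuracy in percent and the MCC.

    A class absent from the evaluation leaves the corresponding rate
    undefined (NaN, with a warning) rather than silently zero; a zero
    factor in the MCC denominator yields MCC = 0 by convention.
    """
    if c.total == 0:
        raise ValidationError("no peptides evaluated")
    if c.tp + c.fn == 0:
        logger.warning("no positive peptides evaluated: sensitivity undefined")
        sen = math.nan
    else:
        sen = 100.0 * c.tp / (c.tp + c.fn)
    if c.tn + c.fp == 0:
        logger.warning("no negative peptides evaluated: specificity undefined")
        spe = math.nan
    else:
        spe = 100.0 * c.tn / (c.tn + c.fp)
    acc = 100.0 * (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return {"sensitivity": sen, "specificity": spe, "accuracy": acc, "mcc": mcc}


@dataclass
class ThresholdSweep:
    """Per-threshold performance table with the best row flagged by MCC
    (ties: higher accuracy, then lower threshold)."""

    table: pd.DataFrame
    best_index: int

    @property
    def best(self) -> pd.Series:
        return self.table.loc[self.best_index]

    @property
    def best_threshold(self) -> float:
        return float(self.best["threshold"])

    @property
    def best_mcc(self) -> float:
        return float(self.best["mcc"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def threshold_sweep(
    results, thresholds=DEFAULT_THRESHOLDS, use_hybrid: bool = False
) -> ThresholdSweep:
    """Metrics at every threshold of the grid."""
    usable = _usable(results)
    if not usable:
        raise ValidationError("no scorable results to sweep")
    rows = []
    for t in thresholds:
        c = confusion_at(usable, t, use_hybrid)
        m = metrics(c)
        rows.append(
            {
                "threshold": float(t),
                **m,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["mcc", "accuracy", "threshold"], ascending=[False, False, True]
    )
    return ThresholdSweep(table, int(order.index[0]))


def roc_auc(results, use_hybrid: bool = False) -> float:
    """Area under the ROC curve from the full score ranking (equivalent to
    the normalised Mann-Whitney U statistic, ties at half credit)."""
    usable = _usable(results)
    y = [1 if r.label == "positive" else 0 for r in usable]
    if len(set(y)) < 2:
        raise ValidationError("ROC requires both classes present")
    scores = [r.score(use_hybrid) for r in usable]
    return float(roc_auc_score(y, scores))


@dataclass
class CVReport:
    """Everything a cross-validation run produced.

    ``results`` holds one scored :class:`PredictionResult` per peptide
    (each tested exactly once); sweeps and ROC are derived from it, so both
    SVM-only and hybrid views of the same run are available.
    """

    config: SVMConfig
    use_hybrid: bool
    k: int
    seed: int
    results: list = field(default_factory=list)
    fold_of: dict = field(default_factory=dict)  # peptide id -> fold
    thresholds: tuple = DEFAULT_THRESHOLDS
    provenance: dict = field(default_factory=dict)

    def sweep(self, use_hybrid: bool | None = None) -> ThresholdSweep:
        """Pooled threshold sweep over all held-out scores."""
        if use_hybrid is None:
            use_hybrid = self.use_hybrid
        return threshold_sweep(self.results, self.thresholds, use_hybrid)

    @property
    def pooled(self) -> ThresholdSweep:
        return self.sweep()

    def fold_sweeps(self, use_hybrid: bool | None = None) -> list[ThresholdSweep]:
        if use_hybrid is None:
            use_hybrid = self.use_hybrid
        out = []
        for f in range(self.k):
            fold_results = [r for r in self.results if self.fold_of[r.id] == f]
            out.append(threshold_sweep(fold_results, self.thresholds, use_hybrid))
        return out

    def fold_mean(self, use_hybrid: bool | None = None) -> pd.DataFrame:
        """Across-fold average of the per-fold metric tables (the classical
        'average the performance on each set' aggregation)."""
        tables = [s.table for s in self.fold_sweeps(use_hybrid)]
        stacked = pd.concat(tables).groupby("threshold", as_index=False).mean()
        return stacked[["threshold", "sensitivity", "specificity", "accuracy", "mcc"]]

    def roc_auc(self, use_hybrid: bool | None = None) -> float:
        if use_hybrid is None:
            use_hybrid = self.use_hybrid
        return roc_auc(self.results, use_hybrid)

    def summary(self) -> str:
        best = self.pooled.best
        lines = [
            f"{self.k}-fold cross-validation "
            f"({self.config.feature_scheme}"
            + ("+motifs hybrid" if self.use_hybrid else "")
            + f", kernel={self.config.kernel}, g={self.config.g}, "
            f"c={self.config.c}, j={self.config.j}, seed={self.seed})",
            f"  peptides : {len(self.results)} scored once each",
            f"  ROC AUC  : {self.roc_auc():.3f}",
            "  best threshold {:.1f}: Sen {:.2f}%  Spec {:.2f}%  Acc {:.2f}%  MCC {:.2f}".format(
                best["threshold"],
                best["sensitivity"],
                best["specificity"],
                best["accuracy"],
                best["mcc"],
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.pooled.to_tsv(path)

    def to_json(self, path) -> None:
        payload = {
            "config": self.config.as_dict(),
            "use_hybrid": self.use_hybrid,
            "k": self.k,
            "seed": self.seed,
            "roc_auc": self.roc_auc(),
            "pooled": self.pooled.table.to_dict(orient="records"),
            "fold_mean": self.fold_mean().to_dict(orient="records"),
            "best": {k: v for k, v in self.pooled.best.items()},
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def cross_validate(
    pos: PeptideDataset,
    neg: PeptideDataset,
    config: SVMConfig | None = None,
    use_hybrid: bool = False,
    k: int = 5,
    seed: int = 42,
    paper_mode: bool = False,
    thresholds=DEFAULT_THRESHOLDS,
    motif_schemes=("none", "koolman_rohm", "betts_russell"),
    motif_kwargs: dict | None = None,
    motif_top_k: int = 10,
) -> CVReport:
    """Stratified k-fold cross-validation of an SVM (optionally hybrid).

    By default the amino-acid-pair propensity table and the exclusive motif
    sets are fitted inside each training fold, so the held-out peptides
    never inform them.  ``paper_mode=True`` instead fits both once on the
    whole dataset before splitting, replicating the published whole-data
    weighting (and the optimism it introduces).
    """
    if config is None:
        config = default_config("AAC", use_hybrid)
    pos_folds, neg_folds = make_folds(pos, neg, k, seed)

    shared_table = None
    shared_pos_motifs = shared_neg_motifs = None
    if paper_mode:
        if config.feature_scheme.upper() == "AAP":
            shared_table = fit_aap_table(pos, neg)
        if use_hybrid:
            shared_pos_motifs, shared_neg_motifs = discover_hybrid_motifs(
                pos,
                neg,
                schemes=motif_schemes,
                top_k=motif_top_k,
                **{"beam_width": 500, **(motif_kwargs or {})},
            )

    all_results: list[PredictionResult] = []
    fold_of: dict[str, int] = {}
    for f in range(k):
        train_pos = pos.subset(np.nonzero(pos_folds != f)[0])
        train_neg = neg.subset(np.nonzero(neg_folds != f)[0])
        test_pos = pos.subset(np.nonzero(pos_folds == f)[0])
        test_neg = neg.subset(np.nonzero(neg_folds == f)[0])
        model = IL4Model(
            train_pos,
            train_neg,
            config,
            hybrid=use_hybrid,
            motif_schemes=motif_schemes,
            motif_kwargs=motif_kwargs,
            motif_top_k=motif_top_k,
        )
        fitted = model.fit(
            seed=seed,
            aap_table=shared_table,
            pos_motifs=shared_pos_motifs,
            neg_motifs=shared_neg_motifs,
        )
        for test in (test_pos, test_neg):
            for r in fitted.score(test, threshold=0.0, use_hybrid=use_hybrid):
                all_results.append(r)
                fold_of[r.id] = f

    return CVReport(
        config=config,
        use_hybrid=use_hybrid,
        k=k,
        seed=seed,
        results=all_results,
        fold_of=fold_of,
        thresholds=tuple(thresholds),
        provenance={
            "paper_mode": paper_mode,
            "n_pos": len(pos),
            "n_neg": len(neg),
            "motif_schemes": list(motif_schemes) if use_hybrid else [],
        },
    )
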