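"""SVM classifiers and the motif-weighted hybrid score.

The model object follows the statsmodels convention: :class:`IL4Model` is
built from the training data plus an :class:`SVMConfig`, and ``fit()``
returns a :class:`TrainedModel` results object that is fully self-contained
-- it carries the fitted kernel machine, the amino-acid-pair propensity
table and the exclusive motif sets it depends on, so a saved model restores
scoring behaviour exactly.

Scores are signed decision-function values (the SVMlight convention), not
probabilities, so the classical threshold sweep over [-1, +1] applies
directly.  The hybrid score adds +1 when a peptide matches any
positive-exclusive motif and -1 when it matches any negative-exclusive
motif.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.svm import SVC

from il4kit.peptide_io import PeptideDataset, ValidationError, check_disjoint
from il4kit import features as feat
from il4kit.motifs import MotifSet, motif_flag, discover_hybrid_motifs

logger = logging.getLogger(__name__)

_KERNELS = {"linear": "linear", "polynomial": "poly", "poly": "poly", "rbf": "rbf"}

DEFAULT_MOTIF_SCHEMES = ("none", "koolman_rohm", "betts_russell")


@dataclass(frozen=True)
class SVMConfig:
    """Kernel SVM hyperparameters in SVMlight vocabulary.

    ``g`` is the RBF width, ``c`` the regularisation constant and ``j`` the
    cost factor by which training errors on positive examples outweigh
    errors on negatives (mapped to an asymmetric class weight).  Parameters
    irrelevant to the chosen kernel are ignored but recorded.
    """

    kernel: str = "rbf"
    g: float = 0.001
    c: float = 1.0
    j: float = 1.0
    feature_scheme: str = "AAC"
    degree: int = 3
    window: int = 15

    def __post_init__(self):
        if self.kernel not in _KERNELS:
            raise ValidationError(f"unknown kernel {self.kernel!r}")
        if min(self.g, self.c, self.j) <= 0:
            raise ValidationError("g, c and j must be positive")

    def as_dict(self) -> dict:
        return asdict(self)


#: Published optimum per feature scheme (RBF kernel), used as defaults.
DEFAULT_CONFIGS: dict[tuple[str, bool], SVMConfig] = {
    ("AAC", False): SVMConfig("rbf", 0.001, 3.0, 1.0, "AAC"),
    ("DPC", False): SVMConfig("rbf", 0.001, 3.0, 1.0, "DPC"),
    ("AAP", False): SVMConfig("rbf", 0.1, 1.0, 1.0, "AAP"),
    ("AAC", True): SVMConfig("rbf", 0.01, 2.0, 1.0, "AAC"),
    ("DPC", True): SVMConfig("rbf", 0.01, 3.0, 1.0, "DPC"),
    ("AAP", True): SVMConfig("rbf", 0.1, 1.0, 1.0, "AAP"),
}


def default_config(feature_scheme: str, hybrid: bool = False) -> SVMConfig:
    """The default hyperparameters for a feature scheme (RBF kernel)."""
    scheme = feature_scheme.upper()
    key = (scheme, hybrid)
    if key in DEFAULT_CONFIGS:
        return DEFAULT_CONFIGS[key]
    return SVMConfig("rbf", 0.01, 1.0, 1.0, scheme)


def default_grid(feature_scheme: str) -> list[SVMConfig]:
    """The default hyperparameter grid: RBF over the classical bracket of
    widths/costs plus linear and polynomial spot checks."""
    scheme = feature_scheme.upper()
    grid = [
        SVMConfig("rbf", g, c, j, scheme)
        for g in (0.001, 0.01, 0.05, 0.1)
        for c in (1.0, 2.0, 3.0, 4.0, 9.0)
        for j in (1.0, 5.0)
    ]
    grid += [SVMConfig("linear", 0.001, c, 1.0, scheme) for c in (1.0, 3.0)]
    grid += [
        SVMConfig("polynomial", 0.01, 1.0, 1.0, scheme, degree=d) for d in (2, 3)
    ]
    return grid


@dataclass
class PredictionResult:
    """Scores for one peptide at a given decision threshold."""

    id: str
    sequence: str
    label: str
    svm_score: float
    motif_adjustment: int
    hybrid_score: float
    predicted_label: str
    threshold_used: float

    @property
    def ok(self) -> bool:
        return self.predicted_label != "error"

    def score(self, use_hybrid: bool) -> float:
        return self.hybrid_score if use_hybrid else self.svm_score


class IL4Model:
    """An IL4-inducing-peptide classifier specification bound to data.

    Parameters
    ----------
    pos, neg : PeptideDataset
        Positive (inducing) and negative (non-inducing) training peptides;
        the two sets must be sequence-disjoint.
    config : SVMConfig, optional
        Kernel and hyperparameters; defaults to the published optimum for
        the feature scheme.
    hybrid : bool
        Discover exclusive motifs during fitting and add the +-1 motif
        weight to every score.
    motif_schemes : sequence of str
        Classification alphabets searched for exclusive motifs when
        ``hybrid`` is set.
    motif_kwargs : dict, optional
        Extra arguments for motif discovery (``min_support``,
        ``max_elements``, ``beam_width``); the fitting default uses a beam
        of 500 patterns per level, which keeps fivefold cross-validation
        tractable on one CPU.
    """

    def __init__(
        self,
        pos: PeptideDataset,
        neg: PeptideDataset,
        config: SVMConfig | None = None,
        hybrid: bool = False,
        motif_schemes=DEFAULT_MOTIF_SCHEMES,
        motif_kwargs: dict | None = None,
        motif_top_k: int = 10,
    ):
        if len(pos) == 0 or len(neg) == 0:
            raise ValidationError("both training classes must be non-empty")
        check_disjoint(pos, neg)
        self.pos = pos
        self.neg = neg
        self.config = config or default_config("AAC", hybrid)
        self.hybrid = hybrid
        self.motif_schemes = tuple(motif_schemes)
        self.motif_kwargs = {"beam_width": 500}
        self.motif_kwargs.update(motif_kwargs or {})
        self.motif_top_k = motif_top_k

    @classmethod
    def from_fasta(cls, pos_path, neg_path, strict: bool = True, **kwargs) -> "IL4Model":
        from il4kit.peptide_io import load_datasets

        pos, neg = load_datasets(pos_path, neg_path, strict=strict)
        return cls(pos, neg, **kwargs)

    def fit(
        self,
        seed: int = 42,
        aap_table: feat.AAPPropensityTable | None = None,
        pos_motifs: MotifSet | None = None,
        neg_motifs: MotifSet | None = None,
    ) -> "TrainedModel":
        """Fit the SVM (and, if needed, the propensity table and motifs).

        ``aap_table`` / ``pos_motifs`` / ``neg_motifs`` may be supplied
        pre-fitted (e.g. fitted on the whole dataset in paper mode, which
        replicates the published whole-data weighting and its optimism);
        when omitted they are fitted on the training data given here, which
        is leakage-free under cross-validation.
        """
        scheme = self.config.feature_scheme.upper()
        if scheme == "AAP" and aap_table is None:
            aap_table = feat.fit_aap_table(self.pos, self.neg)
        if self.hybrid and pos_motifs is None:
            pos_motifs, neg_motifs = discover_hybrid_motifs(
                self.pos,
                self.neg,
                schemes=self.motif_schemes,
                top_k=self.motif_top_k,
                **self.motif_kwargs,
            )

        Xp = feat.encode(self.pos, scheme, aap_table, self.config.window).values
        Xn = feat.encode(self.neg, scheme, aap_table, self.config.window).values
        X = np.vstack([Xp, Xn])
        y = np.concatenate([np.ones(len(self.pos)), np.zeros(len(self.neg))])

        svc = SVC(
            kernel=_KERNELS[self.config.kernel],
            gamma=self.config.g,
            C=self.config.c,
            degree=self.config.degree,
            class_weight={1: self.config.j, 0: 1.0},
            tol=1e-5,
            random_state=seed,
        )
        svc.fit(X, y)
        return TrainedModel(
            config=self.config,
            svc=svc,
            hybrid=self.hybrid,
            aap_table=aap_table,
            pos_motifs=pos_motifs,
            neg_motifs=neg_motifs,
            provenance={
                "n_pos": len(self.pos),
                "n_neg": len(self.neg),
                "seed": seed,
                "motif_schemes": list(self.motif_schemes) if self.hybrid else [],
            },
        )


@dataclass
class TrainedModel:
    """A fitted classifier together with everything needed to score new
    peptides: the SVM, the propensity table and the motif sets."""

    config: SVMConfig
    svc: SVC
    hybrid: bool = False
    aap_table: feat.AAPPropensityTable | None = None
    pos_motifs: MotifSet | None = None
    neg_motifs: MotifSet | None = None
    provenance: dict = field(default_factory=dict)

    def decision_scores(self, ds: PeptideDataset) -> np.ndarray:
        """Signed SVM decision values (NaN for peptides whose features
        cannot be computed, e.g. length-1 peptides under DPC)."""
        scheme = self.config.feature_scheme.upper()
        scores = np.full(len(ds), np.nan)
        rows, idx = [], []
        for i, p in enumerate(ds):
            try:
                if scheme == "AAC":
                    rows.append(feat.aac(p))
                elif scheme == "DPC":
                    rows.append(feat.dpc(p))
                elif scheme == "AAP":
                    rows.append(feat.aap(p, self.aap_table))
                else:
                    terminus = "N" if scheme == "BINARY_NT" else "C"
                    rows.append(feat.binary_profile(p, self.config.window, terminus))
                idx.append(i)
            except ValidationError as exc:
                logger.warning("cannot score peptide %r: %s", p.id, exc)
        if rows:
            scores[idx] = self.svc.decision_function(np.vstack(rows))
        return scores

    def score(
        self,
        ds: PeptideDataset,
        threshold: float = 0.0,
        use_hybrid: bool | None = None,
    ) -> list[PredictionResult]:
        """Score every peptide; predicted positive iff score >= threshold.

        Peptides failing a feature precondition yield an error entry (NaN
        scores, label ``error``) and the run continues.
        """
        use_hybrid = self.hybrid if use_hybrid is None else use_hybrid
        if use_hybrid and self.pos_motifs is None and self.neg_motifs is None:
            raise ValidationError("hybrid scoring requested but no motif sets fitted")
        svm_scores = self.decision_scores(ds)
        out = []
        for p, s in zip(ds, svm_scores):
            if np.isnan(s):
                out.append(
                    PredictionResult(p.id, p.sequence, p.label, np.nan, 0, np.nan, "error", threshold)
                )
                continue
            adj = motif_flag(p, self.pos_motifs, self.neg_motifs) if use_hybrid else 0
            hybrid_score = float(s) + adj if use_hybrid else float(s)
            applicable = hybrid_score if use_hybrid else float(s)
            out.append(
                PredictionResult(
                    p.id,
                    p.sequence,
                    p.label,
                    float(s),
                    adj,
                    hybrid_score,
                    "positive" if applicable >= threshold else "negative",
                    threshold,
                )
            )
        return out

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, TrainedModel):
            raise ValidationError(f"{path} does not contain a TrainedModel")
        return obj

    def summary(self) -> str:
        lines = [
            "TrainedModel",
            f"  features : {self.config.feature_scheme}",
            f"  kernel   : {self.config.kernel} (g={self.config.g}, c={self.config.c}, j={self.config.j})",
            f"  training : {self.provenance.get('n_pos', '?')} positive / "
            f"{self.provenance.get('n_neg', '?')} negative peptides",
            f"  hybrid   : {self.hybrid}",
        ]
        if self.hybrid and self.pos_motifs is not None:
            lines.append(
                f"  motifs   : {len(self.pos_motifs)} positive-exclusive / "
                f"{len(self.neg_motifs)} negative-exclusive"
            )
        return "\n".join(lines)


def train(
    pos: PeptideDataset,
    neg: PeptideDataset,
    config: SVMConfig | None = None,
    hybrid: bool = False,
    seed: int = 42,
    **kwargs,
) -> TrainedModel:
    """Convenience wrapper: build an :class:`IL4Model` and fit it."""
    return IL4Model(pos, neg, config, hybrid=hybrid, **kwargs).fit(seed=seed)


def grid_search(
    pos: PeptideDataset,
    neg: PeptideDataset,
    grid=None,
    cv_folds: int = 5,
    criterion: str = "mcc",
    seed: int = 42,
    use_hybrid: bool = False,
    feature_scheme: str | None = None,
    **cv_kwargs,
):
    """Evaluate every config by cross-validation; return the best and the
    full per-config report.

    The winner maximises the chosen criterion (``mcc`` or ``accuracy``) at
    its best threshold on the pooled sweep.

    Returns
    -------
    best : SVMConfig
    report : pandas.DataFrame
        One row per config with its best threshold and metrics there.
    """
    import pandas as pd

    from il4kit.evaluation import cross_validate

    if grid is None:
        grid = default_grid(feature_scheme or "AAC")
    grid = list(grid)
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    criterion = criterion.lower()
    if criterion not in ("mcc", "accuracy"):
        raise ValidationError(f"unknown criterion {criterion!r}")

    rows = []
    for cfg in grid:
        report = cross_validate(
            pos, neg, cfg, use_hybrid=use_hybrid, k=cv_folds, seed=seed, **cv_kwargs
        )
        best = report.pooled.best
        rows.append(
            {
                "kernel": cfg.kernel,
                "g": cfg.g,
                "c": cfg.c,
                "j": cfg.j,
                "degree": cfg.degree,
                "feature_scheme": cfg.feature_scheme,
                "threshold": best["threshold"],
                "sensitivity": best["sensitivity"],
                "specificity": best["specificity"],
                "accuracy": best["accuracy"],
                "mcc": best["mcc"],
            }
        )
    report_df = pd.DataFrame(rows)
    crit_col = "mcc" if criterion == "mcc" else "accuracy"
    best_idx = int(report_df[crit_col].idxmax())
    return grid[best_idx], report_df
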