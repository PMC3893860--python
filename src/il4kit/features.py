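"""Fixed-length numeric encodings of peptides.

Five encoding schemes are provided:

``AAC``
    Amino-acid composition: percentage frequency of each residue, a
    20-dimensional vector summing to 100.
``DPC``
    Dipeptide composition: percentage frequency of each ordered residue
    pair among the ``length - 1`` overlapping pairs, a 400-dimensional
    vector summing to 100.
``AAP``
    Amino-acid-pair propensity: the dipeptide composition weighted
    elementwise by a pair-propensity table fitted on a labelled training
    set (log-ratio of smoothed pair frequencies in positives versus
    negatives, rescaled to [-1, 1]).
``BINARY_NT`` / ``BINARY_CT``
    One-hot profile of the first ``window`` residues from the N- or
    C-terminus, 20 components per position (e.g. 300 dimensions for a
    15-residue window); positions beyond a peptide's length are all-zero.

Column order is fixed alphabetical by one-letter code throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from il4kit.alphabet import AMINO_ACIDS, AA_INDEX, PAIRS, PAIR_INDEX
from il4kit.peptide_io import Peptide, PeptideDataset, ValidationError

SCHEMES = ("AAC", "DPC", "AAP", "BINARY_NT", "BINARY_CT")


def _seq_of(peptide) -> str:
    return peptide.sequence if hasattr(peptide, "sequence") else str(peptide)


def aac(peptide) -> np.ndarray:
    """Amino-acid composition in percent, fixed order ACDEFGHIKLMNPQRSTVWY."""
    seq = _seq_of(peptide)
    if not seq:
        raise ValidationError("cannot compute composition of an empty sequence")
    v = np.zeros(20)
    for c in seq:
        v[AA_INDEX[c]] += 1.0
    return v * (100.0 / len(seq))


def dpc(peptide) -> np.ndarray:
    """Dipeptide composition in percent over the 400 ordered pairs."""
    seq = _seq_of(peptide)
    if len(seq) < 2:
        raise ValidationError("dipeptide composition requires length >= 2")
    v = np.zeros(400)
    for i in range(len(seq) - 1):
        v[PAIR_INDEX[seq[i : i + 2]]] += 1.0
    return v * (100.0 / (len(seq) - 1))


@dataclass
class AAPPropensityTable:
    """Propensity of each ordered residue pair for the positive class.

    ``scores[p]`` is ``log((F+ + eps) / (F- + eps))`` linearly rescaled so
    that the maximum absolute score is 1, where ``F+``/``F-`` are the
    relative frequencies of pair ``p`` among all overlapping pairs of the
    positive / negative training set.  Swapping the two sets negates every
    score.
    """

    scores: np.ndarray  # length 400, order = alphabet.PAIRS
    smoothing: float = 1.0
    fitted_on: dict = field(default_factory=dict)

    def score(self, pair: str) -> float:
        return float(self.scores[PAIR_INDEX[pair]])

    def as_dict(self) -> dict[str, float]:
        return {p: float(s) for p, s in zip(PAIRS, self.scores)}


def _pair_counts(ds: PeptideDataset) -> np.ndarray:
    counts = np.zeros(400)
    for p in ds:
        seq = p.sequence
        for i in range(len(seq) - 1):
            counts[PAIR_INDEX[seq[i : i + 2]]] += 1.0
    return counts


def fit_aap_table(
    pos: PeptideDataset, neg: PeptideDataset, pseudocount: float = 1.0
) -> AAPPropensityTable:
    """Fit the pair-propensity table on a labelled training set.

    The additive smoothing constant is ``pseudocount / total_pairs`` of the
    respective set, which keeps the smoothing scale-free while avoiding
    log(0) for unseen pairs.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both datasets must be non-empty to fit propensities")
    cp, cn = _pair_counts(pos), _pair_counts(neg)
    tp, tn = cp.sum(), cn.sum()
    if tp == 0 or tn == 0:
        raise ValidationError("datasets contain no residue pairs (all length-1?)")
    fp = cp / tp + pseudocount / tp
    fn = cn / tn + pseudocount / tn
    raw = np.log(fp / fn)
    m = np.abs(raw).max()
    scores = raw / m if m > 0 else raw
    return AAPPropensityTable(
        scores=scores,
        smoothing=pseudocount,
        fitted_on={"n_pos": len(pos), "n_neg": len(neg)},
    )


def aap(peptide, table: AAPPropensityTable) -> np.ndarray:
    """Propensity-weighted dipeptide composition (400 dimensions)."""
    return dpc(peptide) * table.scores


def binary_profile(peptide, window: int = 15, terminus: str = "N") -> np.ndarray:
    """One-hot profile of ``window`` terminal residues (20 per position).

    Position 1 is the terminal residue itself; for the C-terminus positions
    count inward from the last residue.  Positions beyond the peptide's
    length are all-zero blocks, so every profile has length ``20 * window``
    and row sum ``min(length, window)``.
    """
    if not 1 <= window <= 22:
        raise ValidationError(f"window must be in [1, 22], got {window}")
    if terminus not in ("N", "C"):
        raise ValidationError(f"terminus must be 'N' or 'C', got {terminus!r}")
    seq = _seq_of(peptide)
    residues = seq[:window] if terminus == "N" else seq[::-1][:window]
    v = np.zeros(20 * window)
    for pos, c in enumerate(residues):
        v[20 * pos + AA_INDEX[c]] = 1.0
    return v


@dataclass
class FeatureMatrix:
    """A dataset encoded under one scheme: one row per peptide."""

    scheme: str
    values: np.ndarray
    column_names: list[str]
    row_ids: list[str]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, sep="\t", float_format="%.6f")

    def to_svmlight(self, path, labels=None) -> None:
        """Write sparse ``label idx:val`` lines (1-based feature indices)."""
        if labels is None:
            labels = [0] * len(self.row_ids)
        with open(path, "w") as fh:
            for row, lab in zip(self.values, labels):
                nz = np.nonzero(row)[0]
                feats = " ".join(f"{i + 1}:{row[i]:.6f}" for i in nz)
                fh.write(f"{int(lab)} {feats}\n")


def _column_names(scheme: str, window: int) -> list[str]:
    if scheme == "AAC":
        return list(AMINO_ACIDS)
    if scheme in ("DPC", "AAP"):
        return list(PAIRS)
    return [f"p{pos + 1}_{aa}" for pos in range(window) for aa in AMINO_ACIDS]


def encode(
    ds: PeptideDataset,
    scheme: str,
    aap_table: AAPPropensityTable | None = None,
    window: int = 15,
) -> FeatureMatrix:
    """Encode every peptide of a dataset under one scheme."""
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown feature scheme {scheme!r}")
    if scheme == "AAC":
        rows = [aac(p) for p in ds]
    elif scheme == "DPC":
        rows = [dpc(p) for p in ds]
    elif scheme == "AAP":
        if aap_table is None:
            raise ValidationError("AAP encoding requires a fitted propensity table")
        rows = [aap(p, aap_table) for p in ds]
    else:
        terminus = "N" if scheme == "BINARY_NT" else "C"
        rows = [binary_profile(p, window, terminus) for p in ds]
    values = np.vstack(rows) if rows else np.zeros((0, len(_column_names(scheme, window))))
    return FeatureMatrix(scheme, values, _column_names(scheme, window), ds.ids())


# ---------------------------------------------------------------------------
# Physicochemical property scales
# ---------------------------------------------------------------------------

#: Standard published per-residue scales, shipped as editable tables.
#: hydrophilicity: Hopp & Woods (1981); hydrophobicity: Eisenberg consensus
#: (1984); hydropathy: Kyte & Doolittle (1982); charge: unit side-chain
#: charge at pH 7 (His 0.1); steric: Charton steric parameter (1981);
#: side_bulk: Zamyatnin side-chain volume, A^3 (1972); pI: isoelectric point
#: of the free amino acid; amphipathy: Mitaku amphiphilicity index.
PCP_SCALES: dict[str, dict[str, float]] = {
    "hydrophilicity": {
        "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
        "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
        "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
        "W": -3.4, "Y": -2.3,
    },
    "hydrophobicity": {
        "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
        "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
        "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
        "W": 0.81, "Y": 0.26,
    },
    "hydropathy": {
        "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
        "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
        "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
        "W": -0.9, "Y": -1.3,
    },
    "charge": {
        "A": 0.0, "C": 0.0, "D": -1.0, "E": -1.0, "F": 0.0, "G": 0.0,
        "H": 0.1, "I": 0.0, "K": 1.0, "L": 0.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 0.0, "R": 1.0, "S": 0.0, "T": 0.0, "V": 0.0,
        "W": 0.0, "Y": 0.0,
    },
    "steric": {
        "A": 0.52, "C": 0.62, "D": 0.76, "E": 0.68, "F": 0.70, "G": 0.00,
        "H": 0.70, "I": 1.02, "K": 0.68, "L": 0.98, "M": 0.78, "N": 0.76,
        "P": 0.36, "Q": 0.68, "R": 0.68, "S": 0.53, "T": 0.70, "V": 0.76,
        "W": 0.70, "Y": 0.70,
    },
    "side_bulk": {
        "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
        "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
        "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
        "W": 227.8, "Y": 193.6,
    },
    "pI": {
        "A": 6.00, "C": 5.07, "D": 2.77, "E": 3.22, "F": 5.48, "G": 5.97,
        "H": 7.59, "I": 6.02, "K": 9.74, "L": 5.98, "M": 5.74, "N": 5.41,
        "P": 6.30, "Q": 5.65, "R": 10.76, "S": 5.68, "T": 5.60, "V": 5.96,
        "W": 5.89, "Y": 5.66,
    },
    "amphipathy": {
        "A": 0.0, "C": 0.0, "D": 0.0, "E": 1.27, "F": 0.04, "G": 0.0,
        "H": 1.45, "I": 0.0, "K": 3.67, "L": 0.0, "M": 0.0, "N": 0.0,
        "P": 0.0, "Q": 1.25, "R": 2.45, "S": 0.0, "T": 0.0, "V": 0.0,
        "W": 6.93, "Y": 5.06,
    },
}


def pcp_summaries(
    ds: PeptideDataset,
    scale,
    positions: list[int] | None = None,
    terminus: str = "N",
    profile_window: int = 15,
):
    """Per-peptide property sums and a per-position mean profile.

    Parameters
    ----------
    scale : str or mapping
        Name of a scale in :data:`PCP_SCALES` or a residue -> value mapping
        defined for all 20 residues.
    positions : list of int, optional
        1-based positions (counted from ``terminus``) whose residues enter
        each peptide's sum; when omitted, all residues are summed.
    terminus : 'N' or 'C'
        Which end positions are counted from.

    Returns
    -------
    per_peptide : numpy.ndarray
        Sum of scale values over the selected residues of each peptide.
        Positions beyond a peptide's length contribute nothing.
    per_position : numpy.ndarray
        Mean scale value at each of the first ``profile_window`` terminal
        positions, averaged over the peptides long enough to contribute
        (NaN where no peptide reaches the position).
    """
    if isinstance(scale, str):
        scale = PCP_SCALES[scale]
    missing = [aa for aa in AMINO_ACIDS if aa not in scale]
    if missing:
        raise ValidationError(f"scale missing residues {''.join(missing)}")
    if terminus not in ("N", "C"):
        raise ValidationError(f"terminus must be 'N' or 'C', got {terminus!r}")
    if positions is not None:
        bad = [p for p in positions if p < 1]
        if bad:
            raise ValidationError(f"positions must be 1-based, got {bad}")

    per_peptide = np.zeros(len(ds))
    sums = np.zeros(profile_window)
    counts = np.zeros(profile_window)
    for i, p in enumerate(ds):
        seq = p.sequence if terminus == "N" else p.sequence[::-1]
        if positions is None:
            per_peptide[i] = sum(scale[c] for c in seq)
        else:
            per_peptide[i] = sum(scale[seq[j - 1]] for j in positions if j <= len(seq))
        for j, c in enumerate(seq[:profile_window]):
            sums[j] += scale[c]
            counts[j] += 1
    with np.errstate(invalid="ignore"):
        per_position = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return per_peptide, per_position
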