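"""Dataset characterisation statistics.

The numeric content behind the usual exploratory figures for a two-class
peptide dataset: per-residue composition comparison (which residues are
enriched in inducers vs non-inducers), positional residue enrichment over
the first 15 terminal positions (the table a two-sample logo renders), and
length summaries.  Graphics are out of scope; every function returns a
plain table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from il4kit.alphabet import AMINO_ACIDS
from il4kit.features import aac
from il4kit.peptide_io import PeptideDataset, ValidationError


@dataclass
class CompositionComparison:
    """Per-residue mean composition in each class with Welch-test p-values."""

    table: pd.DataFrame
    alpha: float
    test: str = "welch_t"

    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "residue"])


def compare_composition(
    pos: PeptideDataset,
    neg: PeptideDataset,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> CompositionComparison:
    """Compare mean amino-acid composition (percent) between the classes.

    A Welch two-sample t-test is run per residue on the per-peptide
    composition values.  No multiple-testing correction is applied unless
    ``bonferroni`` is set.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both datasets must be non-empty")
    comp_pos = np.vstack([aac(p) for p in pos])
    comp_neg = np.vstack([aac(p) for p in neg])
    threshold = alpha / 20 if bonferroni else alpha
    rows = []
    for i, residue in enumerate(AMINO_ACIDS):
        a, b = comp_pos[:, i], comp_neg[:, i]
        if np.var(a) == 0 and np.var(b) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        rows.append(
            {
                "residue": residue,
                "mean_pos": float(a.mean()),
                "mean_neg": float(b.mean()),
                "diff": float(a.mean() - b.mean()),
                "p_value": p,
                "significant": p < threshold,
            }
        )
    return CompositionComparison(pd.DataFrame(rows), alpha)


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-proportion z-test; degenerate cells return p = 1."""
    if n1 == 0 or n2 == 0:
        return 1.0
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(2 * stats.norm.sf(abs(z)))


def positional_enrichment(
    pos: PeptideDataset,
    neg: PeptideDataset,
    window: int = 15,
    terminus: str = "N",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position, per-residue frequency difference between the classes.

    For each 1-based position (counted from the chosen terminus) and each
    residue: the residue's frequency at that position within each class
    (among peptides long enough to reach the position), the difference
    (positive minus negative) and a two-proportion z-test p-value.  This is
    the numeric table a two-sample sequence logo encodes.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both datasets must be non-empty")
    if terminus not in ("N", "C"):
        raise ValidationError(f"terminus must be 'N' or 'C', got {terminus!r}")

    def counts(ds: PeptideDataset) -> tuple[np.ndarray, np.ndarray]:
        table = np.zeros((window, 20))
        n_at = np.zeros(window)
        for p in ds:
            seq = p.sequence if terminus == "N" else p.sequence[::-1]
            for j, c in enumerate(seq[:window]):
                table[j, AMINO_ACIDS.index(c)] += 1
                n_at[j] += 1
        return table, n_at

    cp, np_at = counts(pos)
    cn, nn_at = counts(neg)
    rows = []
    for j in range(window):
        for i, residue in enumerate(AMINO_ACIDS):
            f_pos = cp[j, i] / np_at[j] if np_at[j] else 0.0
            f_neg = cn[j, i] / nn_at[j] if nn_at[j] else 0.0
            p = _two_proportion_p(int(cp[j, i]), int(np_at[j]), int(cn[j, i]), int(nn_at[j]))
            rows.append(
                {
                    "position": j + 1,
                    "residue": residue,
                    "freq_pos": f_pos,
                    "freq_neg": f_neg,
                    "diff": f_pos - f_neg,
                    "p_value": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def length_summary(ds: PeptideDataset) -> dict:
    """Five-number summary plus mean of the peptide lengths."""
    if len(ds) == 0:
        raise ValidationError("dataset is empty")
    lengths = np.array([len(p) for p in ds], dtype=float)
    q1, med, q3 = np.percentile(lengths, [25, 50, 75])
    return {
        "min": float(lengths.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(lengths.max()),
        "mean": float(lengths.mean()),
    }
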