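"""Reading, validating, filtering and writing peptide datasets.

Peptides live in plain FASTA files, one record per peptide; the class label
comes from which file a record was read from (a positive and a negative
file), never from header parsing.  Sequences are restricted to the 20
standard residue letters: non-standard codes (B, J, O, U, X, Z, gaps) are
rejected in strict mode or dropped with a warning in lenient mode, because
every downstream encoding is defined only on the 20-letter alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from il4kit.alphabet import AA_INDEX

logger = logging.getLogger(__name__)

LABELS = ("positive", "negative", "unlabeled")


class ValidationError(ValueError):
    """Raised when input data violates a documented precondition."""


@dataclass(frozen=True)
class Peptide:
    """A labelled peptide sequence.

    Parameters
    ----------
    id : str
        Record identifier, unique within a dataset.
    sequence : str
        Uppercase sequence over the 20 standard residue letters.
    label : str
        One of ``positive``, ``negative``, ``unlabeled``.
    """

    id: str
    sequence: str
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"peptide {self.id!r}: empty sequence")
        if self.label not in LABELS:
            raise ValidationError(f"peptide {self.id!r}: unknown label {self.label!r}")
        bad = sorted({c for c in self.sequence if c not in AA_INDEX})
        if bad:
            raise ValidationError(
                f"peptide {self.id!r}: non-standard residue(s) {''.join(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class PeptideDataset:
    """An ordered collection of peptides with provenance metadata.

    Record ids must be unique within the dataset; sequence-level uniqueness
    is established separately by :func:`deduplicate`.
    """

    def __init__(self, peptides: Iterable[Peptide], provenance: dict | None = None):
        self.peptides: list[Peptide] = list(peptides)
        self.provenance: dict = dict(provenance or {})
        seen: set[str] = set()
        for p in self.peptides:
            if p.id in seen:
                raise ValidationError(f"duplicate peptide id {p.id!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PeptideDataset(self.peptides[i], self.provenance)
        return self.peptides[i]

    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    def ids(self) -> list[str]:
        return [p.id for p in self.peptides]

    def labels(self) -> list[str]:
        return [p.label for p in self.peptides]

    def subset(self, indices: Sequence[int]) -> "PeptideDataset":
        return PeptideDataset([self.peptides[i] for i in indices], self.provenance)

    def with_provenance(self, **kwargs) -> "PeptideDataset":
        prov = dict(self.provenance)
        prov.update(kwargs)
        return PeptideDataset(self.peptides, prov)

    def __repr__(self) -> str:
        return f"PeptideDataset(n={len(self)}, provenance={self.provenance})"


def read_fasta(path, label: str = "unlabeled", strict: bool = True) -> PeptideDataset:
    """Read a FASTA file into a :class:`PeptideDataset`.

    Sequences are uppercased.  Records containing residues outside the
    standard 20-letter alphabet raise :class:`ValidationError` in strict
    mode (naming the offending record) and are dropped with a logged
    warning otherwise.  An empty file yields an empty dataset.
    """
    peptides: list[Peptide] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(rec.seq).upper()
        bad = sorted({c for c in seq if c not in AA_INDEX})
        if bad:
            if strict:
                raise ValidationError(
                    f"record {rec.id!r}: non-standard residue(s) {''.join(bad)}"
                )
            logger.warning(
                "dropping record %r: non-standard residue(s) %s", rec.id, "".join(bad)
            )
            continue
        if not seq:
            if strict:
                raise ValidationError(f"record {rec.id!r}: empty sequence")
            logger.warning("dropping record %r: empty sequence", rec.id)
            continue
        peptides.append(Peptide(rec.id, seq, label))
    if n_records == 0:
        logger.warning("no FASTA records found in %s", path)
    return PeptideDataset(
        peptides, {"source": str(path), "label": label, "strict": strict}
    )


def write_fasta(ds: PeptideDataset, path) -> None:
    """Write a dataset to FASTA, one record per peptide."""
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in ds
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def filter_by_length(
    ds: PeptideDataset, min_len: int = 8, max_len: int = 22
) -> PeptideDataset:
    """Keep peptides with ``min_len <= length <= max_len``, preserving order.

    The defaults are the standard MHC class II epitope window of 8-22
    residues used to build the reference dataset.
    """
    if min_len < 1 or max_len < min_len:
        raise ValidationError(f"invalid length window [{min_len}, {max_len}]")
    kept = [p for p in ds if min_len <= len(p) <= max_len]
    removed = len(ds) - len(kept)
    if removed:
        logger.info(
            "length filter [%d, %d] removed %d of %d peptides",
            min_len,
            max_len,
            removed,
            len(ds),
        )
    prov = dict(ds.provenance)
    prov["length_window"] = (min_len, max_len)
    return PeptideDataset(kept, prov)


def deduplicate(ds: PeptideDataset) -> PeptideDataset:
    """Keep the first occurrence of each distinct sequence, preserving order."""
    seen: set[str] = set()
    kept: list[Peptide] = []
    for p in ds:
        if p.sequence not in seen:
            seen.add(p.sequence)
            kept.append(p)
    removed = len(ds) - len(kept)
    if removed:
        logger.info("deduplication removed %d of %d peptides", removed, len(ds))
    prov = dict(ds.provenance)
    prov["deduplicated"] = True
    return PeptideDataset(kept, prov)


def check_disjoint(pos: PeptideDataset, neg: PeptideDataset) -> None:
    """Raise if any sequence occurs in both the positive and negative set.

    The two classes are disjoint by construction; a sequence appearing on
    both sides is a conflicting label and treated as an input error rather
    than resolved by guessing.
    """
    overlap = set(pos.sequences()) & set(neg.sequences())
    if overlap:
        example = sorted(overlap)[0]
        raise ValidationError(
            f"{len(overlap)} sequence(s) occur in both classes "
            f"(conflicting labels), e.g. {example!r}"
        )


def load_datasets(
    pos_path,
    neg_path,
    min_len: int = 8,
    max_len: int = 22,
    strict: bool = True,
) -> tuple[PeptideDataset, PeptideDataset]:
    """Read positive/negative FASTA files, length-filter, deduplicate.

    Convenience wrapper applying the full dataset-construction pipeline:
    read, length window, within-class deduplication and a cross-class
    conflicting-label check.
    """
    pos = deduplicate(filter_by_length(read_fasta(pos_path, "positive", strict), min_len, max_len))
    neg = deduplicate(filter_by_length(read_fasta(neg_path, "negative", strict), min_len, max_len))
    check_disjoint(pos, neg)
    return pos, neg


PREDICTION_COLUMNS = (
    "id",
    "sequence",
    "svm_score",
    "motif_adjustment",
    "hybrid_score",
    "predicted_label",
    "threshold_used",
)


def write_predictions(results, path) -> None:
    """Write prediction results to TSV with 6-decimal float precision.

    ``results`` is any iterable of objects with the attributes named in
    :data:`PREDICTION_COLUMNS`; an empty iterable yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.sequence,
                        f"{r.svm_score:.6f}",
                        str(int(r.motif_adjustment)),
                        f"{r.hybrid_score:.6f}",
                        r.predicted_label,
                        f"{r.threshold_used:.6f}",
                    ]
                )
                + "\n"
            )
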