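"""Seeded generator of synthetic peptide benchmarks.

Real IL4 assay data cannot be redistributed here, so every stage of the
toolkit is exercised on generated datasets that mimic the statistical
structure the method assumes: two classes of 8-22-mer peptides with a mild
compositional bias (E/F/K/I enriched in inducers, G/D/L in non-inducers)
and class-exclusive degenerate motifs planted into a fraction of each
class.  The generator emulates statistical structure only -- no MHC-binding
biology, allele restriction or assay noise.

Everything is driven by one integer seed: the same seed yields
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from il4kit.alphabet import AMINO_ACIDS
from il4kit.motifs import MotifPattern, Gap, Literal, parse_motif
from il4kit.peptide_io import Peptide, PeptideDataset, ValidationError, write_fasta

#: Average amino-acid composition of the UniProtKB/Swiss-Prot database
#: (release-statistics values, in percent), used to emulate random
#: protein-derived negatives without a download.
SWISSPROT_COMPOSITION = {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """A fully stated synthetic-benchmark scenario.

    ``background`` is ``"uniform"``, ``"swissprot"`` or a residue->frequency
    mapping; ``pos_bias``/``neg_bias`` are additive frequency deltas applied
    to the background of the respective class (then renormalised);
    ``pos_motifs``/``neg_motifs`` are ``(motif_text, scheme, insertion
    probability)`` triples -- with the given probability one realisation of
    the motif (gaps instantiated uniformly at random in 1-5) overwrites a
    random window of the peptide.
    """

    n_pos: int = 500
    n_neg: int = 500
    length_range: tuple = (8, 22)
    background: object = "uniform"
    pos_bias: tuple = (("E", 0.02), ("F", 0.02), ("K", 0.02), ("I", 0.02))
    neg_bias: tuple = (("G", 0.02), ("D", 0.02), ("L", 0.02))
    pos_motifs: tuple = (("[charged]K-K", "betts_russell", 0.35),)
    neg_motifs: tuple = (("L-L-L", "none", 0.35),)
    seed: int = 42

    def __post_init__(self):
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValidationError(f"invalid length range {self.length_range}")
        for text, scheme, prob in self.pos_motifs + self.neg_motifs:
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(f"insertion probability {prob} not in [0, 1]")
            m = parse_motif(text, scheme)
            if m.min_span() > hi:
                raise ValidationError(
                    f"motif {text!r} (min span {m.min_span()}) cannot fit length {hi}"
                )


def default_benchmark_scenario() -> GeneratorSpec:
    """The canonical benchmark: 500 peptides per class, lengths 8-22,
    +2 percentage points on E/F/K/I (positives) and G/D/L (negatives),
    planted exclusive motifs ``[charged]K-K`` / ``L-L-L`` at insertion
    probability 0.35, seed 42."""
    return GeneratorSpec()


def null_scenario(seed: int = 42, n: int = 500) -> GeneratorSpec:
    """Bias and motifs disabled: the two classes are exchangeable."""
    return GeneratorSpec(
        n_pos=n, n_neg=n, pos_bias=(), neg_bias=(), pos_motifs=(), neg_motifs=(),
        seed=seed,
    )


class GeneratedData(NamedTuple):
    pos: PeptideDataset
    neg: PeptideDataset
    manifest: pd.DataFrame


def _frequencies(background, bias) -> np.ndarray:
    if isinstance(background, str):
        if background == "uniform":
            freqs = np.full(20, 1.0 / 20)
        elif background == "swissprot":
            freqs = np.array([SWISSPROT_COMPOSITION[a] for a in AMINO_ACIDS])
            freqs = freqs / freqs.sum()
        else:
            raise ValidationError(f"unknown background {background!r}")
    else:
        freqs = np.array([float(background[a]) for a in AMINO_ACIDS])
        freqs = freqs / freqs.sum()
    freqs = freqs.copy()
    for residue, delta in dict(bias).items():
        freqs[AMINO_ACIDS.index(residue)] += delta
    freqs = np.clip(freqs, 0.0, None)
    return freqs / freqs.sum()


def _realize(motif: MotifPattern, max_len: int, freqs: np.ndarray, rng) -> str | None:
    """One random realisation of the motif, at most ``max_len`` long.

    Gap lengths are drawn uniformly from 1-5; if the draw does not fit the
    window it is retried, falling back to minimal gaps, and ``None`` is
    returned when even the minimal span does not fit.
    """
    if motif.min_span() > max_len:
        return None

    def draw(minimal: bool) -> str:
        out = []
        for el in motif.elements:
            if isinstance(el, Gap):
                g = el.min_len if minimal else int(rng.integers(el.min_len, el.max_len + 1))
                out.append("".join(rng.choice(list(AMINO_ACIDS), size=g, p=freqs)))
            elif isinstance(el, Literal):
                out.append(el.residue)
            else:
                members = sorted(el.members)
                out.append(str(rng.choice(members)))
        return "".join(out)

    for _ in range(20):
        s = draw(minimal=False)
        if len(s) <= max_len:
            return s
    return draw(minimal=True)


def _generate_class(
    label: str, n: int, spec: GeneratorSpec, bias, motifs, rng
) -> tuple[list[Peptide], list[dict]]:
    freqs = _frequencies(spec.background, bias)
    lo, hi = spec.length_range
    residues = list(AMINO_ACIDS)
    peptides, manifest = [], []
    prefix = "pos" if label == "positive" else "neg"
    parsed = [(parse_motif(t, s), t, p) for t, s, p in motifs]
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(residues, size=length, p=freqs))
        planted = []
        for motif, text, prob in parsed:
            if rng.random() >= prob:
                continue
            realization = _realize(motif, length, freqs, rng)
            if realization is None:
                continue
            start = int(rng.integers(0, length - len(realization) + 1))
            seq[start : start + len(realization)] = list(realization)
            planted.append(text)
        pid = f"{prefix}_{i + 1:04d}"
        peptides.append(Peptide(pid, "".join(seq), label))
        manifest.append(
            {
                "id": pid,
                "label": label,
                "length": length,
                "planted_motifs": ";".join(planted),
            }
        )
    return peptides, manifest


def generate(spec: GeneratorSpec) -> GeneratedData:
    """Draw a synthetic (positive, negative) dataset pair from a scenario.

    Peptides are i.i.d. per-residue draws from the class-specific
    distribution with lengths uniform on the range; planted motifs
    overwrite a random window (preserving the length distribution).  Fully
    deterministic given ``spec.seed``; the manifest records which peptides
    carry which planted motif.
    """
    rng = np.random.default_rng(spec.seed)
    pos_peps, pos_manifest = _generate_class(
        "positive", spec.n_pos, spec, spec.pos_bias, spec.pos_motifs, rng
    )
    neg_peps, neg_manifest = _generate_class(
        "negative", spec.n_neg, spec, spec.neg_bias, spec.neg_motifs, rng
    )
    # a sequence drawn in both classes would be a conflicting label downstream
    pos_seqs = {p.sequence for p in pos_peps}
    neg_peps = [
        p if p.sequence not in pos_seqs else replace_sequence(p, rng)
        for p in neg_peps
    ]
    prov = {"generator": "il4kit.synthetic_data", "seed": spec.seed}
    manifest = pd.DataFrame(pos_manifest + neg_manifest)
    return GeneratedData(
        PeptideDataset(pos_peps, {**prov, "label": "positive"}),
        PeptideDataset(neg_peps, {**prov, "label": "negative"}),
        manifest,
    )


def replace_sequence(p: Peptide, rng) -> Peptide:
    """Re-draw a colliding sequence uniformly (vanishingly rare)."""
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=len(p.sequence)))
    return Peptide(p.id, seq, p.label)


def write_benchmark(spec: GeneratorSpec, out_dir) -> GeneratedData:
    """Generate and write positive.fasta, negative.fasta and manifest.tsv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate(spec)
    write_fasta(data.pos, out / "positive.fasta")
    write_fasta(data.neg, out / "negative.fasta")
    data.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return data
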