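"""Exclusive degenerate-motif discovery and matching.

A motif is an ordered pattern of literal residues, residue-class symbols
(e.g. ``[charged]``) and gaps of 1-5 arbitrary residues (written ``-``).
A motif is *exclusive* for one class of peptides when it matches at least
``min_support`` peptides of that class and none of the other class on the
discovery data.  Two residue-classification alphabets are shipped besides
plain literals: the Koolman-Rohm and the Betts-Russell groupings of the 20
residues into physicochemical classes.

Discovery is a breadth-first pattern-growth search: level-1 patterns are
single literals/class symbols supported in the positives; each frontier
pattern is extended on the right by a literal, a class symbol, or a gap
followed by either; positive support is anti-monotone under extension and
prunes the search.  Patterns that reach exclusivity are emitted and not
extended further (any specialization can only cover fewer peptides), and
the frontier is capped at a beam width for tractability.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from il4kit.alphabet import AMINO_ACIDS, AA_INDEX
from il4kit.peptide_io import PeptideDataset, ValidationError

logger = logging.getLogger(__name__)

GAP_MIN, GAP_MAX = 1, 5


# ---------------------------------------------------------------------------
# Classification schemes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationScheme:
    """A named grouping of the 20 residues into physicochemical classes."""

    name: str
    classes: tuple  # tuple of (class_name, frozenset of residues)

    def class_map(self) -> dict[str, frozenset]:
        return dict(self.classes)

    def __post_init__(self):
        for cname, members in self.classes:
            if not members or not all(r in AA_INDEX for r in members):
                raise ValidationError(f"class {cname!r} is not a subset of the alphabet")


def _scheme(name: str, classes: dict[str, str]) -> ClassificationScheme:
    return ClassificationScheme(
        name, tuple((k, frozenset(v)) for k, v in classes.items())
    )


#: Default residue groupings (editable: build your own ClassificationScheme).
#: The Betts-Russell classes follow the standard amino-acid property Venn
#: diagram; the Koolman-Rohm classes follow the biochemistry-atlas grouping.
SCHEMES: dict[str, ClassificationScheme] = {
    "none": ClassificationScheme("none", ()),
    "koolman_rohm": _scheme(
        "koolman_rohm",
        {
            "acidic": "DE",
            "basic": "HKR",
            "neutral": "NQSTCGY",
            "aliphatic": "AGILVP",
            "aromatic": "FWY",
            "sulfur": "CM",
        },
    ),
    "betts_russell": _scheme(
        "betts_russell",
        {
            "hydrophobic": "ACFGHIKLMRTVWY",
            "polar": "CDEHKNQRSTWY",
            "small": "ACDGNPSTV",
            "charged": "DEHKR",
            "aromatic": "FHWY",
            "aliphatic": "ILV",
        },
    ),
}


# ---------------------------------------------------------------------------
# Motif patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Literal:
    residue: str

    def residues(self) -> frozenset:
        return frozenset(self.residue)

    def render(self) -> str:
        return self.residue


@dataclass(frozen=True)
class ClassSymbol:
    name: str
    members: frozenset

    def residues(self) -> frozenset:
        return self.members

    def render(self) -> str:
        return f"[{self.name}]"


@dataclass(frozen=True)
class Gap:
    min_len: int = GAP_MIN
    max_len: int = GAP_MAX

    def render(self) -> str:
        return "-"


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: literals, class symbols and bounded gaps."""

    elements: tuple
    scheme: str = "none"

    def __post_init__(self):
        if not self.elements:
            raise ValidationError("motif has no elements")
        if isinstance(self.elements[0], Gap) or isinstance(self.elements[-1], Gap):
            raise ValidationError("motif may not start or end with a gap")
        for a, b in zip(self.elements, self.elements[1:]):
            if isinstance(a, Gap) and isinstance(b, Gap):
                raise ValidationError("motif may not contain adjacent gaps")

    @property
    def text(self) -> str:
        return "".join(el.render() for el in self.elements)

    def n_symbols(self) -> int:
        """Number of non-gap elements."""
        return sum(1 for el in self.elements if not isinstance(el, Gap))

    def min_span(self) -> int:
        """Shortest substring length the motif can match."""
        return sum(
            el.min_len if isinstance(el, Gap) else 1 for el in self.elements
        )

    def __str__(self) -> str:
        return self.text


def parse_motif(text: str, scheme: ClassificationScheme | str = "none") -> MotifPattern:
    """Parse motif notation: letters are literals, ``[name]`` a class symbol
    of the scheme, ``-`` a gap of 1-5 residues.  Whitespace is ignored."""
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    cmap = scheme.class_map()
    elements: list = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "-":
            elements.append(Gap())
            i += 1
        elif c == "[":
            j = text.find("]", i)
            if j < 0:
                raise ValidationError(f"unclosed '[' at position {i} in {text!r}")
            name = text[i + 1 : j]
            if name not in cmap:
                raise ValidationError(
                    f"unknown class {name!r} at position {i} in scheme {scheme.name!r}"
                )
            elements.append(ClassSymbol(name, cmap[name]))
            i = j + 1
        elif c in AA_INDEX:
            elements.append(Literal(c))
            i += 1
        else:
            raise ValidationError(f"unexpected character {c!r} at position {i} in {text!r}")
    if not elements:
        raise ValidationError(f"empty motif {text!r}")
    return MotifPattern(tuple(elements), scheme.name)


def to_regex(motif: MotifPattern) -> str:
    """Equivalent regular expression (used for export; matching itself is
    done by direct end-position propagation, see :func:`matches`)."""
    parts = []
    for el in motif.elements:
        if isinstance(el, Gap):
            parts.append(f".{{{el.min_len},{el.max_len}}}")
        elif isinstance(el, Literal):
            parts.append(re.escape(el.residue))
        else:
            parts.append("[" + "".join(sorted(el.members)) + "]")
    return "".join(parts)


def matches(motif: MotifPattern, peptide) -> bool:
    """True iff the motif matches anywhere in the peptide (unanchored).

    Literals match exactly, class symbols any member residue, gaps 1-5
    arbitrary residues.  Implemented by propagating the set of match end
    positions through the element list.
    """
    seq = peptide.sequence if hasattr(peptide, "sequence") else str(peptide)
    n = len(seq)
    # ends[i] true: a match of the prefix processed so far ends before index i
    ends = set(range(n + 1))
    for el in motif.elements:
        if isinstance(el, Gap):
            new = set()
            for e in ends:
                new.update(range(e + el.min_len, min(e + el.max_len, n) + 1))
            ends = new
        else:
            allowed = el.residues()
            ends = {e + 1 for e in ends if e < n and seq[e] in allowed}
        if not ends:
            return False
    return True


# ---------------------------------------------------------------------------
# Motif sets
# ---------------------------------------------------------------------------


@dataclass
class MotifSet:
    """Ordered discovered motifs with their training coverage.

    ``coverage[i]`` is the number of same-side discovery peptides matched by
    ``motifs[i]``; ``match_ids[i]`` the frozenset of their ids (retained so
    that greedy unique-coverage selection needs no re-matching).
    """

    motifs: list = field(default_factory=list)
    side: str = "positive_exclusive"
    coverage: list = field(default_factory=list)
    match_ids: list = field(default_factory=list)
    unique_coverage: int | None = None

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def covered_ids(self) -> frozenset:
        out: set = set()
        for ids in self.match_ids:
            out |= ids
        return frozenset(out)

    def to_records(self) -> list[dict]:
        return [
            {
                "text": m.text,
                "scheme": m.scheme,
                "side": self.side,
                "coverage": c,
            }
            for m, c in zip(self.motifs, self.coverage)
        ]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.to_records(), columns=["text", "scheme", "side", "coverage"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Discovery engine
# ---------------------------------------------------------------------------


def _base_symbols(scheme: ClassificationScheme) -> list:
    symbols: list = [Literal(aa) for aa in AMINO_ACIDS]
    symbols.extend(ClassSymbol(n, m) for n, m in scheme.classes)
    return symbols


def _occurrence_bits(seqs: list[str], symbol) -> np.ndarray:
    """Per-peptide bitmask: bit i set iff residue i matches the symbol.

    Peptides are short (at most 57 residues once the maximum gapped-extension
    shift is added), so one uint64 per peptide holds the whole profile and a
    pattern extension becomes a shift-and-AND on integer vectors.
    """
    allowed = symbol.residues()
    out = np.zeros(len(seqs), dtype=np.uint64)
    for i, s in enumerate(seqs):
        bits = 0
        for j, c in enumerate(s):
            if c in allowed:
                bits |= 1 << j
        out[i] = bits
    return out


def _sort_key(entry):
    # entry: (elements, support, E) -> rank by coverage desc, fewer elements,
    # then lexicographic text (deterministic, input-order invariant)
    elements, support = entry[0], entry[1]
    text = "".join(el.render() for el in elements)
    return (-support, len(elements), text)


def discover_exclusive_motifs(
    pos: PeptideDataset,
    neg: PeptideDataset,
    scheme: ClassificationScheme | str = "none",
    max_motifs: int = 100,
    min_support: int = 3,
    max_elements: int = 7,
    beam_width: int = 5000,
    side: str = "positive_exclusive",
) -> MotifSet:
    """Find degenerate motifs exclusive to ``pos`` against ``neg``.

    Returns up to ``max_motifs`` motifs, each matching at least
    ``min_support`` peptides of ``pos`` and zero of ``neg``, ranked by
    positive coverage descending (ties: fewer elements, then lexicographic
    text).  ``max_elements`` bounds the number of non-gap symbols; the
    frontier of the breadth-first search is capped at ``beam_width``
    patterns per level, highest-support first.

    To obtain motifs exclusive to the negative class, swap the arguments
    and pass ``side="negative_exclusive"``.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both datasets must be non-empty")
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")

    pos_ids = pos.ids()
    seqs = pos.sequences() + neg.sequences()
    longest = max(len(s) for s in seqs)
    if longest > 57:
        raise ValidationError(
            f"discovery supports peptides up to 57 residues (got {longest})"
        )
    n_pos = len(pos)

    symbols = _base_symbols(scheme)
    occ = {s: _occurrence_bits(seqs, s) for s in symbols}
    gap_shifts = [np.uint64(g + 1) for g in range(GAP_MIN, GAP_MAX + 1)]

    emitted: list[tuple] = []  # (elements, coverage, matched pos-row bools)
    seen: set = set()

    # level 1
    frontier: list[tuple] = []
    for s in symbols:
        E = occ[s]
        matched = E != 0
        psup = int(matched[:n_pos].sum())
        if psup < min_support:
            continue
        seen.add((s,))
        if not matched[n_pos:].any():
            emitted.append(((s,), psup, matched[:n_pos].copy()))
        else:
            frontier.append(((s,), psup, E))

    one = np.uint64(1)
    level = 1
    while frontier and level < max_elements:
        frontier.sort(key=_sort_key)
        frontier = frontier[:beam_width]
        Estack = np.stack([e[2] for e in frontier])  # (F, n) end-position bits
        parents = [e[0] for e in frontier]

        # parent ends shifted across a gap of 1-5 residues plus one symbol
        Edirect = Estack << one
        Egap = Estack << gap_shifts[0]
        for shift in gap_shifts[1:]:
            Egap |= Estack << shift

        new_frontier: list[tuple] = []
        for s in symbols:
            occ_s = occ[s]
            for gapped, Esrc in ((False, Edirect), (True, Egap)):
                E2 = Esrc & occ_s[None, :]
                matched = E2 != 0
                psup = matched[:, :n_pos].sum(axis=1)
                ok = np.nonzero(psup >= min_support)[0]
                if ok.size == 0:
                    continue
                neg_any = matched[ok][:, n_pos:].any(axis=1)
                for k, idx in enumerate(ok):
                    new_el = (
                        parents[idx] + (Gap(), s) if gapped else parents[idx] + (s,)
                    )
                    if new_el in seen:
                        continue
                    seen.add(new_el)
                    if not neg_any[k]:
                        emitted.append(
                            (new_el, int(psup[idx]), matched[idx, :n_pos].copy())
                        )
                    else:
                        new_frontier.append((new_el, int(psup[idx]), E2[idx]))
        frontier = new_frontier
        level += 1

    if not emitted:
        logger.warning(
            "no exclusive motif reached min_support=%d (scheme %s)",
            min_support,
            scheme.name,
        )

    emitted.sort(key=_sort_key)
    emitted = emitted[:max_motifs]
    motifs = [MotifPattern(el, scheme.name) for el, _, _ in emitted]
    coverage = [c for _, c, _ in emitted]
    match_ids = [
        frozenset(pos_ids[i] for i in np.nonzero(rows)[0]) for _, _, rows in emitted
    ]
    return MotifSet(motifs, side, coverage, match_ids)


def select_top_by_unique_coverage(ms: MotifSet, k: int = 10) -> MotifSet:
    """Greedy top-k selection by unique sequence coverage.

    Repeatedly picks the motif covering the most not-yet-covered peptides
    of its side; stops after ``k`` motifs or when no motif adds new
    coverage.  The returned set records the cumulative unique coverage.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    remaining = list(range(len(ms.motifs)))
    covered: set = set()
    picked: list[int] = []
    while remaining and len(picked) < k:
        best, best_gain = None, 0
        for i in remaining:
            gain = len(ms.match_ids[i] - covered)
            if gain > best_gain:
                best, best_gain = i, gain
        if best is None:
            break
        picked.append(best)
        covered |= ms.match_ids[best]
        remaining.remove(best)
    return MotifSet(
        [ms.motifs[i] for i in picked],
        ms.side,
        [ms.coverage[i] for i in picked],
        [ms.match_ids[i] for i in picked],
        unique_coverage=len(covered),
    )


def motif_flag(peptide, pos_motifs: MotifSet | None, neg_motifs: MotifSet | None) -> int:
    """Hybrid weight: +1 for a positive-exclusive motif hit, -1 for a
    negative-exclusive hit, summed (a peptide matching both sides nets 0)."""
    flag = 0
    if pos_motifs is not None and any(matches(m, peptide) for m in pos_motifs):
        flag += 1
    if neg_motifs is not None and any(matches(m, peptide) for m in neg_motifs):
        flag -= 1
    return flag


def discover_hybrid_motifs(
    pos: PeptideDataset,
    neg: PeptideDataset,
    schemes=("none", "koolman_rohm", "betts_russell"),
    top_k: int = 10,
    **discover_kwargs,
) -> tuple[MotifSet, MotifSet]:
    """Discover the motif sets used by the hybrid score.

    For each classification scheme, exclusive motifs are discovered for
    both classes and the top ``top_k`` by unique sequence coverage are
    kept; the per-scheme selections are concatenated into one positive and
    one negative motif set (mirroring the published two-step procedure of
    pooling the top-10 motifs of every classification).
    """
    pos_all: list[MotifSet] = []
    neg_all: list[MotifSet] = []
    for scheme in schemes:
        ms_pos = discover_exclusive_motifs(pos, neg, scheme, **discover_kwargs)
        ms_neg = discover_exclusive_motifs(
            neg, pos, scheme, side="negative_exclusive", **discover_kwargs
        )
        pos_all.append(select_top_by_unique_coverage(ms_pos, top_k))
        neg_all.append(select_top_by_unique_coverage(ms_neg, top_k))

    def _concat(sets: list[MotifSet], side: str) -> MotifSet:
        motifs, cov, ids = [], [], []
        for s in sets:
            motifs.extend(s.motifs)
            cov.extend(s.coverage)
            ids.extend(s.match_ids)
        out = MotifSet(motifs, side, cov, ids)
        out.unique_coverage = len(out.covered_ids())
        return out

    return _concat(pos_all, "positive_exclusive"), _concat(neg_all, "negative_exclusive")
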