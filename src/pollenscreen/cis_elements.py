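"""Promoter extraction and 3–8-mer word enrichment.

Candidate regulatory words are short DNA words (3–8 nt) counted in the
upstream regions (nominally 2 kb, 5′ of the start codon, strand-resolved) of
a gene set.  Enrichment is tested gene-level: for each word, the number of
target promoters containing at least one occurrence is compared with the
word's presence probability in a background promoter collection by a
binomial upper-tail test, with Benjamini–Hochberg correction within each
word length (word counts differ by orders of magnitude across k).  Enriched
words are annotated against a user-supplied known-element catalogue with
IUPAC ambiguity support, else reported "unknown".  Scanning is single-strand:
promoters are already strand-resolved by :func:`extract_promoters`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSet:
    """Strand-resolved upstream sequences, with truncations recorded.

    ``truncated`` maps gene id → actual length for promoters shorter than the
    requested window (chromosome edge).
    """

    sequences: dict[str, str]
    length: int = 2000
    truncated: dict[str, int] = field(default_factory=dict)


@dataclass
class BackgroundModel:
    """Per-word presence counts over a background promoter collection.

    ``presence_prob(word)`` returns the fraction of background promoters
    containing ≥1 occurrence, optionally with a +0.5 pseudo-count so that
    unseen words keep a nonzero probability.
    """

    counts: dict[int, dict[str, int]]
    n_promoters: int
    k_range: tuple[int, int]
    pseudocount: bool = True

    def presence_prob(self, word: str) -> float:
        k = len(word)
        if not self.k_range[0] <= k <= self.k_range[1]:
            raise ValueError(f"word length {k} outside background range {self.k_range}")
        count = self.counts.get(k, {}).get(word, 0)
        if self.pseudocount:
            return (count + 0.5) / (self.n_promoters + 1.0)
        return count / self.n_promoters


@dataclass
class WordEnrichment:
    word: str
    k: int
    target_count: int
    target_size: int
    background_prob: float
    p_value: float
    adjusted_p: float
    enriched: bool
    known_element: str = "unknown"


def _word_regex(word: str) -> re.Pattern[str]:
    parts = []
    for letter in word.upper():
        if letter not in IUPAC:
            raise ValueError(f"invalid IUPAC letter {letter!r} in word {word!r}")
        allowed = IUPAC[letter]
        parts.append(next(iter(allowed)) if len(allowed) == 1 else f"[{''.join(sorted(allowed))}]")
    # lookahead so overlapping occurrences all count; N in the sequence
    # matches nothing because character classes never include N
    return re.compile(f"(?={''.join(parts)})")


def count_word(sequence: str, word: str) -> int:
    """Overlapping occurrence count of an IUPAC word in an ACGTN sequence."""
    if not 3 <= len(word) <= 8:
        raise ValueError("word length must be 3-8")
    return sum(1 for _ in _word_regex(word).finditer(sequence.upper()))


def contains_word(sequence: str, word: str) -> bool:
    return _word_regex(word).search(sequence.upper()) is not None


def _present_words(sequence: str, k: int) -> set[str]:
    seq = sequence.upper()
    return {
        seq[i:i + k]
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    }


def build_background(
    promoters: Mapping[str, str] | Iterable[str],
    k_range: tuple[int, int] = (3, 8),
    pseudocount: bool = True,
) -> BackgroundModel:
    """Presence counts of every observed word in a background collection."""
    seqs = list(promoters.values()) if isinstance(promoters, Mapping) else list(promoters)
    if not seqs:
        raise ValueError("empty background promoter collection")
    lo, hi = k_range
    if not (3 <= lo <= hi <= 8):
        raise ValueError(f"k_range must lie within 3-8, got {k_range}")
    counts: dict[int, dict[str, int]] = {k: {} for k in range(lo, hi + 1)}
    for seq in seqs:
        for k in range(lo, hi + 1):
            for word in _present_words(seq, k):
                counts[k][word] = counts[k].get(word, 0) + 1
    return BackgroundModel(counts=counts, n_promoters=len(seqs),
                           k_range=(lo, hi), pseudocount=pseudocount)


def annotate_word(word: str, known_elements: Mapping[str, str]) -> str:
    """Name of the first catalogue element the word matches, else 'unknown'.

    A concrete word matches a (possibly IUPAC-ambiguous) element pattern when
    it contains an instance of the pattern, or — for patterns longer than the
    word — when the word fits inside the pattern letter-by-letter.
    """
    w = word.upper()
    for name in sorted(known_elements):
        pattern = known_elements[name].upper()
        if len(pattern) <= len(w):
            if _word_regex(pattern).search(w):
                return name
        else:
            for off in range(len(pattern) - len(w) + 1):
                if all(c in IUPAC[p] for c, p in zip(w, pattern[off:off + len(w)])):
                    return name
    return "unknown"


def scan_enriched_words(
    target_promoters: Mapping[str, str] | PromoterSet,
    background: BackgroundModel,
    k_range: tuple[int, int] | None = None,
    alpha: float = 0.05,
    known_elements: Mapping[str, str] | None = None,
) -> list[WordEnrichment]:
    """Binomial word-enrichment scan of a target promoter set.

    For every word present in ≥1 target promoter: x = number of targets
    containing it, n = target-set size, p0 = background presence probability;
    p = P(X ≥ x | Binomial(n, p0)).  BH adjustment is applied within each
    word length; ``enriched`` flags adjusted p < alpha.  Results are sorted
    by (k, adjusted p, p, word).
    """
    if isinstance(target_promoters, PromoterSet):
        target_promoters = target_promoters.sequences
    seqs = list(target_promoters.values())
    n = len(seqs)
    if n == 0:
        raise ValueError("empty target promoter set")
    k_range = k_range or background.k_range
    if not (background.k_range[0] <= k_range[0] and k_range[1] <= background.k_range[1]):
        raise ValueError(
            f"scan range {k_range} not covered by background {background.k_range}"
        )
    results: list[WordEnrichment] = []
    for k in range(k_range[0], k_range[1] + 1):
        target_counts: dict[str, int] = {}
        for seq in seqs:
            for word in _present_words(seq, k):
                target_counts[word] = target_counts.get(word, 0) + 1
        words = sorted(target_counts)
        if not words:
            continue
        pvals = np.array([
            stats.binom.sf(target_counts[w] - 1, n, background.presence_prob(w))
            for w in words
        ])
        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
        for w, p, a in zip(words, pvals, adjusted):
            results.append(WordEnrichment(
                word=w, k=k, target_count=target_counts[w], target_size=n,
                background_prob=background.presence_prob(w),
                p_value=float(p), adjusted_p=float(a),
                enriched=bool(a < alpha),
                known_element=(
                    annotate_word(w, known_elements) if known_elements else "unknown"
                ),
            ))
    results.sort(key=lambda r: (r.k, r.adjusted_p, r.p_value, r.word))
    return results


def _parse_bed_line(fields: list[str]) -> tuple[str, int, int, str, str]:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
    strand = fields[5] if len(fields) > 5 else "+"
    return chrom, start, end, name, strand


def _parse_gff_line(fields: list[str]) -> tuple[str, int, int, str, str]:
    chrom = fields[0]
    start, end, strand = int(fields[3]) - 1, int(fields[4]), fields[6]
    name = f"{chrom}:{start}-{end}"
    for part in fields[8].split(";"):
        key, _, value = part.partition("=")
        if key.strip() in ("ID", "Name", "gene_id"):
            name = value.strip()
            break
    return chrom, start, end, name, strand


def extract_promoters(
    sequence_file: str | Path,
    coordinates_file: str | Path,
    length: int = 2000,
    coordinate_format: str = "bed",
) -> PromoterSet:
    """Extract strand-resolved upstream windows from a FASTA reference.

    Coordinates are read as BED (0-based half-open) or GFF3 (1-based
    inclusive, converted internally).  For a + strand gene the promoter is
    the ``length`` bases 5′ of the interval start; for a − strand gene, the
    reverse complement of the ``length`` bases 3′ of the interval end.
    Windows clipped at sequence edges are recorded in ``truncated``; a gene
    whose window is empty raises.
    """
    from Bio import SeqIO

    if coordinate_format not in ("bed", "gff"):
        raise ValueError("coordinate_format must be 'bed' or 'gff'")
    parse = _parse_bed_line if coordinate_format == "bed" else _parse_gff_line
    min_fields = 3 if coordinate_format == "bed" else 9

    reference = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(sequence_file), "fasta")
    }
    sequences: dict[str, str] = {}
    truncated: dict[str, int] = {}
    with open(coordinates_file) as handle:
        for line in handle:
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ValueError(f"coordinate line with too few fields: {line!r}")
            chrom, start, end, name, strand = parse(fields)
            if chrom not in reference:
                raise ValueError(f"gene {name!r} on missing sequence {chrom!r}")
            seq = reference[chrom]
            if strand == "-":
                window = seq[end:end + length]
                promoter = reverse_complement(window)
            else:
                window = seq[max(0, start - length):start]
                promoter = window
            if not promoter:
                raise ValueError(f"zero-length promoter for gene {name!r}")
            if len(promoter) < length:
                truncated[name] = len(promoter)
            sequences[name] = promoter
    return PromoterSet(sequences=sequences, length=length, truncated=truncated)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name in sequences:
            handle.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


def read_known_elements(path: str | Path) -> dict[str, str]:
    """Two-column tab-delimited catalogue: element name, IUPAC pattern."""
    table = pd.read_csv(path, sep="\t", header=None, names=["name", "pattern"],
                        dtype=str, comment="#")
    return dict(zip(table["name"], table["pattern"]))
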