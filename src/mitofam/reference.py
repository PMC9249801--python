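"""Reference model of the human mitochondrial genome.

Coordinates follow the rCRS "m." convention: 1-based, inclusive, over a
circular 16,569-bp molecule.  The packaged reference sequence is synthetic
(seeded, deterministic) but carries the standard human mtDNA gene map, so
positional annotation — gene membership, OXPHOS complex, tRNA/rRNA/D-loop
category, low-complexity masking — behaves like the real genome.  Users may
substitute a true rCRS FASTA; no downstream statistic depends on the packaged
sequence's bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

MT_LENGTH = 16569
DLOOP_WRAP_LEN = 150

#: Low-complexity regions excluded from heteroplasmy calling
#: (homopolymeric stretches around m.302-316, m.512-526, m.16184-16193).
DEFAULT_MASK = ((302, 316), (512, 526), (16184, 16193))

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
BASES = ("A", "C", "G", "T")

# Standard human mtDNA gene map (1-based inclusive rCRS coordinates).
# category: OXPHOS / tRNA / rRNA / D-loop; complex label for OXPHOS genes;
# strand -1 marks light-strand genes (ND6 and eight tRNAs).
_GENE_ROWS = [
    ("MT-DLOOP1", 1, 576, "D-loop", None, 1),
    ("MT-TF", 577, 647, "tRNA", None, 1),
    ("MT-RNR1", 648, 1601, "rRNA", None, 1),
    ("MT-TV", 1602, 1670, "tRNA", None, 1),
    ("MT-RNR2", 1671, 3229, "rRNA", None, 1),
    ("MT-TL1", 3230, 3304, "tRNA", None, 1),
    ("MT-ND1", 3307, 4262, "OXPHOS", "I", 1),
    ("MT-TI", 4263, 4331, "tRNA", None, 1),
    ("MT-TQ", 4329, 4400, "tRNA", None, -1),
    ("MT-TM", 4402, 4469, "tRNA", None, 1),
    ("MT-ND2", 4470, 5511, "OXPHOS", "I", 1),
    ("MT-TW", 5512, 5579, "tRNA", None, 1),
    ("MT-TA", 5587, 5655, "tRNA", None, -1),
    ("MT-TN", 5657, 5729, "tRNA", None, -1),
    ("MT-TC", 5761, 5826, "tRNA", None, -1),
    ("MT-TY", 5826, 5891, "tRNA", None, -1),
    ("MT-CO1", 5904, 7445, "OXPHOS", "IV", 1),
    ("MT-TS1", 7446, 7514, "tRNA", None, -1),
    ("MT-TD", 7518, 7585, "tRNA", None, 1),
    ("MT-CO2", 7586, 8269, "OXPHOS", "IV", 1),
    ("MT-TK", 8295, 8364, "tRNA", None, 1),
    ("MT-ATP8", 8366, 8572, "OXPHOS", "V", 1),
    ("MT-ATP6", 8527, 9207, "OXPHOS", "V", 1),
    ("MT-CO3", 9207, 9990, "OXPHOS", "IV", 1),
    ("MT-TG", 9991, 10058, "tRNA", None, 1),
    ("MT-ND3", 10059, 10404, "OXPHOS", "I", 1),
    ("MT-TR", 10405, 10469, "tRNA", None, 1),
    ("MT-ND4L", 10470, 10766, "OXPHOS", "I", 1),
    ("MT-ND4", 10760, 12137, "OXPHOS", "I", 1),
    ("MT-TH", 12138, 12206, "tRNA", None, 1),
    ("MT-TS2", 12207, 12265, "tRNA", None, 1),
    ("MT-TL2", 12266, 12336, "tRNA", None, 1),
    ("MT-ND5", 12337, 14148, "OXPHOS", "I", 1),
    ("MT-ND6", 14149, 14673, "OXPHOS", "I", -1),
    ("MT-TE", 14674, 14742, "tRNA", None, -1),
    ("MT-CYB", 14747, 15887, "OXPHOS", "III", 1),
    ("MT-TT", 15888, 15953, "tRNA", None, 1),
    ("MT-TP", 15956, 16023, "tRNA", None, -1),
    ("MT-DLOOP2", 16024, 16569, "D-loop", None, 1),
]

GENE_CATEGORIES = ("OXPHOS", "tRNA", "rRNA", "D-loop", "noncoding")


@dataclass(frozen=True)
class MaskedRegions:
    """Set of 1-based inclusive intervals excluded from calling."""

    intervals: tuple[tuple[int, int], ...] = DEFAULT_MASK

    def contains(self, pos) -> np.ndarray | bool:
        """Vectorised membership test for 1-based positions."""
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        for lo, hi in self.intervals:
            out |= (pos >= lo) & (pos <= hi)
        return out if out.ndim else bool(out)


@dataclass(frozen=True)
class MitoReference:
    """A mitochondrial reference sequence with circular D-loop support."""

    sequence: str
    dloop_wrap_len: int = DLOOP_WRAP_LEN

    def __post_init__(self):
        if set(self.sequence) - set("ACGTN"):
            raise ValueError("reference alphabet restricted to {A,C,G,T,N}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= pos <= self.length:
            raise ValueError(f"position {pos} outside [1, {self.length}]")
        return self.sequence[pos - 1]


def load_reference(seed: int = 20177) -> MitoReference:
    """The packaged synthetic 16,569-bp reference.

    Bases are drawn i.i.d. from realistic mtDNA composition; a few anchor
    positions are pinned to their true rCRS alleles so canonical example
    variants (m.3243A>G, m.8313G>A) carry their real reference base.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=MT_LENGTH, p=[0.31, 0.31, 0.13, 0.25])
    for pos, base in ((310, "T"), (3243, "A"), (8313, "G")):
        seq[pos - 1] = base
    return MitoReference("".join(seq))


def gene_table() -> pd.DataFrame:
    """The packaged gene annotation (standard human mtDNA map)."""
    return pd.DataFrame(
        _GENE_ROWS, columns=["gene", "start", "end", "category", "complex", "strand"]
    )


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a gene annotation table (1-based inclusive start/end columns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "start", "end", "category"}
    if missing := required - set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if "strand" not in df.columns:
        df["strand"] = 1
    if "complex" not in df.columns:
        df["complex"] = None
    bad = df[(df.start < 1) | (df.end > MT_LENGTH) | (df.start > df.end)]
    if len(bad):
        raise ValueError(f"annotation intervals outside [1, {MT_LENGTH}]")
    return df


def read_fasta_reference(path) -> MitoReference:
    record = next(SeqIO.parse(str(path), "fasta"))
    return MitoReference(str(record.seq).upper())


def is_transition(ref: str, alt: str) -> bool:
    """True iff the change is purine<->purine or pyrimidine<->pyrimidine."""
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"bases must be in ACGT, got {ref}>{alt}")
    return ({ref, alt} <= PURINES) or ({ref, alt} <= PYRIMIDINES)


def genes_at(pos: int, annotation: pd.DataFrame) -> pd.DataFrame:
    """All genes overlapping a 1-based position (may be empty or several)."""
    return annotation[(annotation.start <= pos) & (annotation.end >= pos)]


def _revcomp(b: str) -> str:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}[b]


def _coding_effect(pos, ref, alt, gene_row, reference: MitoReference) -> str:
    """Synonymous/nonsynonymous status under the vertebrate mito code."""
    start, end, strand = gene_row.start, gene_row.end, gene_row.strand
    if strand >= 0:
        offset = pos - start
    else:
        offset = end - pos
    codon_idx = offset // 3
    within = offset % 3
    if strand >= 0:
        cstart = start + 3 * codon_idx
        codon = [reference.base(p) if 1 <= p <= reference.length else "N"
                 for p in range(cstart, cstart + 3)]
        mut = list(codon)
        mut[within] = alt
    else:
        cstart = end - 3 * codon_idx
        codon = [_revcomp(reference.base(p)) if 1 <= p <= reference.length else "N"
                 for p in range(cstart, cstart - 3, -1)]
        mut = list(codon)
        mut[within] = _revcomp(alt)
    if "N" in codon or "N" in mut:
        return "other"
    aa_ref = str(Seq("".join(codon)).translate(table=2))
    aa_alt = str(Seq("".join(mut)).translate(table=2))
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def annotate_variant(pos: int, ref: str, alt: str,
                     annotation: pd.DataFrame | None = None,
                     reference: MitoReference | None = None,
                     masks: MaskedRegions | None = None) -> dict:
    """Annotate a single-nucleotide change with gene/category/consequence.

    Returns a dict with ``genes`` (all memberships, one consequence each),
    ``category`` and ``coding_effect`` of the first (primary) membership,
    ``masked`` flag and ``is_transition``.  Variants in overlapping genes
    report every membership; downstream consumers deduplicate.
    """
    reference = reference if reference is not None else load_reference()
    annotation = annotation if annotation is not None else gene_table()
    masks = masks if masks is not None else MaskedRegions()
    if not 1 <= pos <= reference.length:
        raise ValueError(f"position {pos} outside [1, {reference.length}]")
    refbase = reference.base(pos)
    if ref != refbase:
        raise ValueError(
            f"ref allele {ref} does not match reference base {refbase} at m.{pos}")
    hits = genes_at(pos, annotation)
    memberships = []
    for row in hits.itertuples():
        if row.category == "OXPHOS":
            effect = _coding_effect(pos, ref, alt, row, reference)
        elif row.category in ("tRNA", "rRNA", "D-loop"):
            effect = row.category
        else:
            effect = "other"
        memberships.append({"gene": row.gene, "category": row.category,
                            "complex": row.complex, "coding_effect": effect})
    if not memberships:
        memberships = [{"gene": None, "category": "noncoding",
                        "complex": None, "coding_effect": "other"}]
    primary = memberships[0]
    return {
        "pos": pos, "ref": ref, "alt": alt,
        "genes": memberships,
        "gene": primary["gene"],
        "category": primary["category"],
        "coding_effect": primary["coding_effect"],
        "masked": bool(masks.contains(pos)),
        "is_transition": is_transition(ref, alt),
    }


def category_positions(annotation: pd.DataFrame, category: str) -> np.ndarray:
    """Sorted unique 1-based positions belonging to a gene category."""
    if category not in GENE_CATEGORIES:
        raise ValueError(f"unknown gene category: {category!r}")
    rows = annotation[annotation.category == category]
    pos = np.concatenate(
        [np.arange(r.start, r.end + 1) for r in rows.itertuples()]
    ) if len(rows) else np.array([], dtype=int)
    return np.unique(pos)


def enumerate_changes(annotation: pd.DataFrame, category: str,
                      reference: MitoReference | None = None,
                      masks: MaskedRegions | None = None) -> pd.DataFrame:
    """All possible single-nucleotide changes in a gene category.

    Exactly three alternative alleles per position; each entry carries an
    ``is_transition`` flag and a ``masked`` flag (excludable downstream).
    """
    reference = reference if reference is not None else load_reference()
    masks = masks if masks is not None else MaskedRegions()
    positions = category_positions(annotation, category)
    if positions.size == 0:
        return pd.DataFrame(columns=["pos", "ref", "alt", "is_transition",
                                     "category", "masked"])
    seq = np.frombuffer(reference.sequence.encode(), dtype="S1").astype("U1")
    refs = seq[positions - 1]
    rows = {"pos": np.repeat(positions, 3),
            "ref": np.repeat(refs, 3),
            "alt": np.concatenate([[b for b in BASES if b != r] for r in refs])}
    df = pd.DataFrame(rows)
    transition_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    df["is_transition"] = df.alt == df.ref.map(transition_partner)
    df["category"] = category
    df["masked"] = masks.contains(df.pos.to_numpy())
    return df


@lru_cache(maxsize=4)
def _default_universe_cached(category: str):
    return enumerate_changes(gene_table(), category)


def default_universe(category: str) -> pd.DataFrame:
    """Packaged change universe for a category (cached; copy returned)."""
    return _default_universe_cached(category).copy()
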