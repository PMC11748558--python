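"""Best-hit taxonomy classification and parent/pseudo-read concordance.

Amplicon sequence variants (ASVs) are classified by their best local
(infix) alignment against an annotated reference database; hits below the
identity threshold — 75% by default, the conventional cut-off for gyrB
marker assignment — are reported as ``Unclassified``.  The alignment
backend is edlib with IUPAC base sets declared equal, so ambiguity codes in
either sequence never count as differences; a 6-frame translated mode is
available for protein-level identity.

Pseudo-short reads cut from long amplicons are matched back to their
parent long-read ASVs: a unique compatible parent wins outright, multiple
compatible parents are separated by read-count similarity (the parent
minimising the relative count difference), and orphans below a 0.1%
relative-abundance floor are declared ``unassigned``.  Matched pairs are
then binned into the four concordance categories used to compare
taxonomic resolution between amplicon lengths: same species, different
classification, less specific, unassigned.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import edlib

from . import seqcore

__all__ = [
    "RANKS",
    "ClassifierParams",
    "ClassificationResult",
    "ParentMatch",
    "ConcordanceTable",
    "classify_best_hit",
    "classify_all",
    "match_pseudo_to_parent",
    "concordance_categories",
]

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

# every IUPAC pair with intersecting base sets is declared equal to edlib
_IUPAC_EQUALITIES = [
    (a, b)
    for a in seqcore.IUPAC_BASES
    for b in seqcore.IUPAC_BASES
    if a < b and seqcore.IUPAC_BASES[a] & seqcore.IUPAC_BASES[b]
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ClassifierParams:
    """``min_identity`` is the percent identity an alignment must reach
    for its taxonomy to be assigned; ``mode`` selects nucleotide or
    6-frame translated comparison."""

    min_identity: float = 75.0
    mode: str = "nucleotide"

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 100.0:
            raise ValueError("min_identity must be in (0, 100]")
        if self.mode not in ("nucleotide", "translated"):
            raise ValueError("mode must be nucleotide or translated")


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    best_ref_id: str | None
    pct_identity: float
    taxonomy: tuple[str, ...] | None  # None => "Unclassified"

    @property
    def label(self) -> str:
        if self.taxonomy is None:
            return "Unclassified"
        return ";".join(self.taxonomy)

    @property
    def rank_depth(self) -> str | None:
        """Deepest assigned rank name, or None when unclassified."""
        if not self.taxonomy:
            return None
        return RANKS[len(self.taxonomy) - 1]


@dataclass(frozen=True)
class ParentMatch:
    pseudo_id: str
    parent_id: str  # "unassigned" when no parent
    method: str  # unique | count_tiebreak | none
    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method == "count_tiebreak" and len(self.candidates) <= 1:
            raise ValueError("count_tiebreak implies multiple candidates")


@dataclass
class ConcordanceTable:
    same_species: int = 0
    different_classification: int = 0
    less_specific: int = 0
    unassigned: int = 0
    excluded: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            self.same_species
            + self.different_classification
            + self.less_specific
            + self.unassigned
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "same_species": self.same_species,
            "different_classification": self.different_classification,
            "less_specific": self.less_specific,
            "unassigned": self.unassigned,
            "total": self.total,
        }


def _identity(query: str, target: str) -> tuple[float, int]:
    """Infix percent identity of query within target: matched columns over
    alignment columns (indels included).  Returns (identity, aln_len)."""
    if not query or not target:
        raise ValueError("empty sequence")
    res = edlib.align(
        query.upper(), target.upper(), mode="HW", task="path",
        additionalEqualities=_IUPAC_EQUALITIES,
    )
    cigar = res["cigar"] or ""
    matched = aln_len = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        aln_len += n
        if op == "=":
            matched += n
    if aln_len == 0:
        return 0.0, 0
    return 100.0 * matched / aln_len, aln_len


_CODON = {}


def _translate(seq: str, frame: int) -> str:
    from Bio.Seq import Seq

    s = seq if frame < 3 else seqcore.revcomp(seq)
    f = frame % 3
    trimmed = s[f : f + 3 * ((len(s) - f) // 3)]
    return str(Seq(trimmed).translate())


def _best_identity(query: str, ref: str, mode: str) -> tuple[float, int]:
    if mode == "nucleotide":
        return _identity(query, ref)
    best = (0.0, 0)
    ref_aa = _translate(ref, 0)
    for frame in range(6):
        q = _translate(query, frame)
        if not q:
            continue
        res = edlib.align(q, ref_aa, mode="HW", task="path")
        matched = aln_len = 0
        for n, op in _CIGAR_RE.findall(res["cigar"] or ""):
            n = int(n)
            aln_len += n
            if op == "=":
                matched += n
        if aln_len:
            cand = (100.0 * matched / aln_len, aln_len)
            if cand > best:
                best = cand
    return best


def classify_best_hit(
    query: tuple[str, str],
    refdb: list[tuple[str, str, tuple[str, ...]]],
    params: ClassifierParams | None = None,
) -> ClassificationResult:
    """Assign the taxonomy of the best reference hit above the threshold.

    ``refdb`` rows are ``(ref_id, sequence, lineage)``.  Ties break
    deterministically: higher identity, then longer alignment, then
    lexicographically smaller reference ID.  Below-threshold best hits
    yield an Unclassified result that still records the best reference.
    """
    params = params or ClassifierParams()
    if not refdb:
        raise ValueError("empty reference database")
    qid, qseq = query
    best = None
    for rid, rseq, lineage in refdb:
        pid, alen = _best_identity(qseq, rseq, params.mode)
        key = (-pid, -alen, rid)
        if best is None or key < best[0]:
            best = (key, rid, pid, lineage)
    _, rid, pid, lineage = best
    if pid < params.min_identity:
        return ClassificationResult(qid, rid, pid, None)
    return ClassificationResult(qid, rid, pid, tuple(lineage))


def classify_all(
    queries: list[tuple[str, str]],
    refdb: list[tuple[str, str, tuple[str, ...]]],
    params: ClassifierParams | None = None,
) -> dict[str, ClassificationResult]:
    return {
        qid: classify_best_hit((qid, qseq), refdb, params)
        for qid, qseq in queries
    }


def match_pseudo_to_parent(
    pseudo: list[tuple[str, str, float]],
    parents: list[tuple[str, str, float]],
    params: ClassifierParams | None = None,
    abundance_floor: float = 0.001,
) -> list[ParentMatch]:
    """Match each pseudo read to its parent long-read ASV.

    Compatibility is infix alignment identity at or above the classifier
    threshold (an exact substring scores 100).  A unique compatible parent
    is taken directly; among several, the parent minimising the relative
    count difference ``|c_p - c_q| / max(c_p, c_q)`` wins (ties: higher
    identity, then smaller ID).  A pseudo read with no compatible parent
    is ``unassigned``; when its relative abundance is at or above
    ``abundance_floor`` (default 0.1%) this is unexpected and a warning is
    logged.
    """
    params = params or ClassifierParams()
    if any(c < 0 for _, _, c in pseudo) or any(c < 0 for _, _, c in parents):
        raise ValueError("negative counts")
    total_pseudo = sum(c for _, _, c in pseudo)
    out: list[ParentMatch] = []
    for pid, pseq, pcount in pseudo:
        cands = []
        for qid, qseq, qcount in parents:
            ident, _ = _identity(pseq, qseq)
            if ident >= params.min_identity:
                cands.append((qid, qcount, ident))
        if len(cands) == 1:
            out.append(ParentMatch(pid, cands[0][0], "unique", (cands[0][0],)))
        elif len(cands) > 1:
            def relative_diff(c):
                _, qc, _ = c
                denom = max(qc, pcount)
                return abs(qc - pcount) / denom if denom else 0.0

            cands.sort(key=lambda c: (relative_diff(c), -c[2], c[0]))
            out.append(
                ParentMatch(
                    pid, cands[0][0], "count_tiebreak",
                    tuple(c[0] for c in cands),
                )
            )
        else:
            rel = pcount / total_pseudo if total_pseudo else 0.0
            if rel >= abundance_floor:
                logger.warning(
                    "pseudo read %s (relative abundance %.3f%%) has no "
                    "compatible parent", pid, 100.0 * rel,
                )
            out.append(ParentMatch(pid, "unassigned", "none"))
    return out


def _effective(lineage: tuple[str, ...] | None) -> tuple[str, ...]:
    if lineage is None:
        return ()
    out = list(lineage)
    while out and not out[-1]:
        out.pop()
    return tuple(out)


def concordance_categories(
    matches: list[ParentMatch],
    pseudo_class: dict[str, ClassificationResult],
    parent_class: dict[str, ClassificationResult],
) -> ConcordanceTable:
    """Bin matched pseudo/parent pairs into the four concordance
    categories.

    ``same_species`` — identical assigned lineages (agreement down to the
    deepest assigned rank); a pseudo lineage that is a strict ancestor of
    its parent's is ``less_specific`` (an Unclassified pseudo read with a
    matched parent falls here: the empty lineage is an ancestor of any);
    any disagreement at a shared rank is ``different_classification``;
    unmatched pseudo reads pass through as ``unassigned``.  Pairs whose
    *parent* is Unclassified carry no reference lineage to compare against
    and are excluded (logged).  Category counts sum to the number of
    categorised pseudo reads.
    """
    table = ConcordanceTable()
    for m in matches:
        if m.parent_id == "unassigned":
            table.unassigned += 1
            continue
        pc = pseudo_class[m.pseudo_id]
        qc = parent_class[m.parent_id]
        q = _effective(qc.taxonomy)
        if not q:
            table.excluded.append(m.pseudo_id)
            logger.warning(
                "parent %s of %s is Unclassified; pair excluded",
                m.parent_id, m.pseudo_id,
            )
            continue
        p = _effective(pc.taxonomy)
        shared = min(len(p), len(q))
        if p[:shared] != q[:shared]:
            table.different_classification += 1
        elif len(p) < len(q):
            table.less_specific += 1
        else:
            # identical, or pseudo deeper but consistent with the parent
            table.same_species += 1
    return table
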