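"""Pairwise and progressive nucleotide alignment, and percent-identity maps.

The clade-selection stage of primer design needs an all-vs-all percent
identity matrix over a 16S-like marker (the *identity map*), and the window
scan needs a multiple alignment of the in-group gene family.  Both are
served by one dynamic-programming engine that aligns *profiles* — per-column
base-frequency vectors — under affine gap costs (a gap of length L costs
``gap_open + (L-1) * gap_extend``).  Single sequences are one-hot profiles,
so pairwise alignment and profile-profile merging share the same code and
the same deterministic tie-breaking (diagonal, then up, then left).

The forward pass is vectorised row-wise: vertical gap scores follow from
the previous row, and horizontal gap scores within a row are a running
maximum of ``H[k] - extend*k``, so no inner Python loop over cells is
needed.

Users with a trusted external aligner can bypass all of this: every
consumer accepts a ready-made :class:`Alignment` or :class:`IdentityMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqcore

__all__ = [
    "ScoringParams",
    "Alignment",
    "IdentityMap",
    "pairwise_align",
    "percent_identity",
    "build_identity_map",
    "progressive_align",
]

_NEG = -1e30  # effectively -inf, safe under addition


@dataclass(frozen=True)
class ScoringParams:
    """Nucleotide alignment scores.

    Defaults are conventional DNA values: match +1, mismatch -2, gap open
    -5, gap extend -2.  ``free_end_gaps`` switches to the semi-global
    convention (terminal gaps cost nothing), appropriate when comparing
    near-full-length marker genes of unequal length.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be at least as costly as gap_extend")

    @property
    def substitution_matrix(self) -> np.ndarray:
        m = np.full((4, 4), self.mismatch, dtype=float)
        np.fill_diagonal(m, self.match)
        return m


@dataclass
class Alignment:
    """A gapped alignment: ordered taxon IDs and equal-length rows.

    Removing gaps from any row reproduces the corresponding input sequence
    exactly; this round-trip is an invariant every producer must keep.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row IDs")
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("rows are not all the same length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace("-", "")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def gap_fraction(self, j: int) -> float:
        col = self.column(j)
        return col.count("-") / len(col)

    def subset(self, taxa: list[str]) -> "Alignment":
        return Alignment(list(taxa), [self.row(t) for t in taxa])


@dataclass
class IdentityMap:
    """Symmetric all-vs-all percent-identity matrix over taxon IDs."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon IDs")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        if not np.allclose(m, m.T):
            raise ValueError("identity matrix is not symmetric")
        if not np.allclose(np.diag(m), 100.0):
            raise ValueError("diagonal must be 100")
        if m.min() < 0 or m.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        self.matrix = m

    def identity(self, a: str, b: str) -> float:
        return float(self.matrix[self.taxa.index(a), self.taxa.index(b)])

    def to_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa).to_csv(
            path, sep="\t", index_label="taxon"
        )

    def to_long_tsv(self, path: str | Path) -> None:
        recs = [
            (self.taxa[i], self.taxa[j], self.matrix[i, j])
            for i in range(len(self.taxa))
            for j in range(i + 1, len(self.taxa))
        ]
        pd.DataFrame(recs, columns=["taxon_a", "taxon_b", "pct_identity"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_square_tsv(cls, path: str | Path) -> "IdentityMap":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path: str | Path) -> "IdentityMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        taxa = sorted(set(df["taxon_a"].astype(str)) | set(df["taxon_b"].astype(str)))
        idx = {t: i for i, t in enumerate(taxa)}
        m = np.full((len(taxa), len(taxa)), np.nan)
        np.fill_diagonal(m, 100.0)
        for a, b, v in df.itertuples(index=False):
            m[idx[str(a)], idx[str(b)]] = v
            m[idx[str(b)], idx[str(a)]] = v
        if np.isnan(m).any():
            raise ValueError("long-format identity map is missing pairs")
        return cls(taxa, m)


# ---------------------------------------------------------------------------
# profile DP engine
# ---------------------------------------------------------------------------

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 4) base-frequency profile; gap mass is simply absent."""
    L = len(rows[0])
    p = np.zeros((L, 4))
    for r in rows:
        for j, ch in enumerate(r):
            if ch == "-":
                continue
            bs = seqcore.bases(ch)
            w = 1.0 / len(bs)
            for b in bs:
                p[j, _BASE_INDEX[b]] += w
    return p / len(rows)


def _align_profiles(
    pa: np.ndarray, pb: np.ndarray, scoring: ScoringParams
) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Affine-gap global (or semi-global) alignment of two profiles.

    Returns the optimal score and the alignment path as a list of
    ``(i, j)`` column-index pairs, ``None`` marking a gap.  Tie-breaking in
    the traceback prefers diagonal, then up (gap in b), then left.
    """
    la, lb = len(pa), len(pb)
    mat = scoring.substitution_matrix
    S = pa @ mat @ pb.T  # (la, lb) expected column-vs-column score
    go, ge = scoring.gap_open, scoring.gap_extend
    free = scoring.free_end_gaps

    H = np.full((la + 1, lb + 1), _NEG)
    Hng = np.full((la + 1, lb + 1), _NEG)  # H restricted to diag/vertical moves
    E = np.full((la + 1, lb + 1), _NEG)  # gap in a (consumes b, "left")
    F = np.full((la + 1, lb + 1), _NEG)  # gap in b (consumes a, "up")
    H[0, 0] = 0.0
    j = np.arange(1, lb + 1)
    i_ax = np.arange(1, la + 1)
    if free:
        H[0, 1:] = 0.0
        H[1:, 0] = 0.0
    else:
        H[0, 1:] = go + ge * (j - 1)
        H[1:, 0] = go + ge * (i_ax - 1)
        E[0, 1:] = H[0, 1:]
        F[1:, 0] = H[1:, 0]

    for i in range(1, la + 1):
        F[i, 1:] = np.maximum(F[i - 1, 1:] + ge, H[i - 1, 1:] + go)
        h = np.maximum(H[i - 1, :-1] + S[i - 1], F[i, 1:])
        Hng[i, 1:] = h
        # horizontal gaps: E[j] = max_{k<j} Hng[k] + go + (j-k-1)*ge, via a
        # running max of Hng[k] - ge*k over the row built so far.  A gap
        # opening at a cell that itself ends in a horizontal gap is never
        # optimal (it would merge into one longer gap), so Hng suffices.
        c0 = H[i, 0] - ge * 0
        run = np.maximum.accumulate(np.concatenate(([c0], h[:-1] - ge * j[:-1])))
        e = run + go - ge + ge * j
        E[i, 1:] = e
        H[i, 1:] = np.maximum(h, e)

    if free:
        # best cell on the last row or column; pad with terminal gaps
        jr = int(np.argmax(H[la, :]))
        ir = int(np.argmax(H[:, lb]))
        if H[la, jr] >= H[ir, lb]:
            start, score = (la, jr), float(H[la, jr])
            tail = [(None, k) for k in range(jr, lb)]
        else:
            start, score = (ir, lb), float(H[ir, lb])
            tail = [(k, None) for k in range(ir, la)]
    else:
        start, score, tail = (la, lb), float(H[la, lb]), []

    # Traceback state machine.  The E matrix above is filled by an
    # algebraic reformulation whose floating-point grouping differs from
    # the naive recurrence, so branch decisions use a tolerance rather
    # than exact equality.  Tie preference: diagonal, then up, then left.
    def close(x: float, y: float) -> bool:
        return abs(x - y) <= 1e-6

    path: list[tuple[int | None, int | None]] = []
    i, jj = start
    state = "H"
    while i > 0 or jj > 0:
        if state in ("H", "Hng") and (i == 0 or jj == 0):
            # forced boundary gaps (free of charge in semi-global mode)
            while i > 0:
                i -= 1
                path.append((i, None))
            while jj > 0:
                jj -= 1
                path.append((None, jj))
            break
        if state == "H":
            state = "Hng" if close(H[i, jj], Hng[i, jj]) else "E"
        elif state == "Hng":
            if close(Hng[i, jj], H[i - 1, jj - 1] + S[i - 1, jj - 1]):
                i -= 1
                jj -= 1
                path.append((i, jj))
                state = "H"
            elif close(Hng[i, jj], F[i, jj]):
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed in Hng state")
        elif state == "F":
            path.append((i - 1, None))
            closing = close(F[i, jj], H[i - 1, jj] + go)
            i -= 1
            if closing:
                state = "H"
        else:  # E
            path.append((None, jj - 1))
            closing = close(E[i, jj], Hng[i, jj - 1] + go)
            jj -= 1
            if jj == 0:
                state = "H"  # boundary flush handles the rest
            elif closing:
                state = "Hng"
    path.reverse()
    return score, path + tail


def _merge_rows(
    rows_a: list[str], rows_b: list[str], path: list[tuple[int | None, int | None]]
) -> tuple[list[str], list[str]]:
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in path:
        for k, r in enumerate(rows_a):
            out_a[k] += r[i] if i is not None else "-"
        for k, r in enumerate(rows_b):
            out_b[k] += r[j] if j is not None else "-"
    return out_a, out_b


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def pairwise_align(
    a: str,
    b: str,
    scoring: ScoringParams | None = None,
    ids: tuple[str, str] = ("seq_a", "seq_b"),
) -> Alignment:
    """Optimal global pairwise alignment of two concrete sequences."""
    scoring = scoring or ScoringParams()
    a = seqcore.normalize(a)
    b = seqcore.normalize(b)
    _, path = _align_profiles(_profile([a]), _profile([b]), scoring)
    ra, rb = _merge_rows([a], [b], path)
    return Alignment(list(ids), [ra[0], rb[0]])


def alignment_score(a: str, b: str, scoring: ScoringParams | None = None) -> float:
    """Score of the optimal global alignment (without building rows)."""
    scoring = scoring or ScoringParams()
    score, _ = _align_profiles(
        _profile([seqcore.normalize(a)]), _profile([seqcore.normalize(b)]), scoring
    )
    return score


def percent_identity(aln: Alignment, exclude_terminal_gaps: bool = True) -> float:
    """Percent identity of a two-row alignment.

    Matches divided by alignment columns; by default terminal-gap-only
    overhangs (columns before both rows have started or after either has
    ended) are excluded from the denominator, the semi-global convention.
    Internal gap columns always count as differences.
    """
    if aln.n_rows != 2:
        raise ValueError("percent_identity requires exactly two rows")
    r0, r1 = aln.rows
    n = aln.n_cols
    if exclude_terminal_gaps:
        first = max(
            min(j for j in range(n) if r0[j] != "-"),
            min(j for j in range(n) if r1[j] != "-"),
        )
        last = min(
            max(j for j in range(n) if r0[j] != "-"),
            max(j for j in range(n) if r1[j] != "-"),
        )
    else:
        first, last = 0, n - 1
    cols = last - first + 1
    if cols <= 0:
        raise ValueError("alignment has no overlapping columns")
    m = sum(
        1 for j in range(first, last + 1) if r0[j] == r1[j] and r0[j] != "-"
    )
    return 100.0 * m / cols


def build_identity_map(
    records: list[tuple[str, str]],
    scoring: ScoringParams | None = None,
    convention: str = "semiglobal",
) -> IdentityMap:
    """All-vs-all percent identity over a set of sequences.

    ``convention`` selects how terminal overhangs are treated: the default
    ``"semiglobal"`` aligns with free end gaps and excludes terminal
    overhang columns from the identity denominator; ``"global"`` penalises
    end gaps and counts every column.
    """
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs")
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    if convention not in ("semiglobal", "global"):
        raise ValueError(f"unknown identity convention {convention!r}")
    semi = convention == "semiglobal"
    base = scoring or ScoringParams()
    sc = ScoringParams(
        base.match, base.mismatch, base.gap_open, base.gap_extend, free_end_gaps=semi
    )
    n = len(records)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(records[i][1], records[j][1], sc)
            try:
                pid = percent_identity(aln, exclude_terminal_gaps=semi)
            except ValueError:
                pid = 0.0  # no overlapping columns: wholly dissimilar pair
            m[i, j] = m[j, i] = pid
    return IdentityMap(ids, m)


def _kmer_distance(seqs: list[str], k: int = 6) -> np.ndarray:
    """Fractional shared-k-mer distance, the usual quick guide-tree metric."""
    k = max(1, min(k, min(len(s) for s in seqs)))
    sets = []
    for s in seqs:
        kmers: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            kmers[w] = kmers.get(w, 0) + 1
        sets.append(kmers)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(
                min(c, sets[j].get(w, 0)) for w, c in sets[i].items()
            )
            denom = min(len(seqs[i]), len(seqs[j])) - k + 1
            d[i, j] = d[j, i] = 1.0 - shared / max(denom, 1)
    return d


def progressive_align(
    records: list[tuple[str, str]], scoring: ScoringParams | None = None
) -> Alignment:
    """Progressive multiple alignment.

    Guide order comes from neighbor joining on shared-k-mer distances;
    clusters are merged by profile-profile dynamic programming, so each
    input sequence is recoverable from its row by deleting gaps.
    """
    from .phylo import DistanceMatrix, nj_joins  # lazy: avoid import cycle

    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence IDs")
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    scoring = scoring or ScoringParams()
    seqs = [seqcore.normalize(r[1]) for r in records]
    if len(records) == 2:
        return Alignment(ids, pairwise_align(seqs[0], seqs[1], scoring).rows)

    d = _kmer_distance(seqs)
    joins = nj_joins(DistanceMatrix(ids, d))
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(len(ids))
    }
    nxt = len(ids)
    for a, b in joins:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        _, path = _align_profiles(_profile(rows_a), _profile(rows_b), scoring)
        out_a, out_b = _merge_rows(rows_a, rows_b, path)
        clusters[nxt] = (ids_a + ids_b, out_a + out_b)
        nxt += 1
    (_, (final_ids, final_rows)), = clusters.items()
    order = {t: i for i, t in enumerate(ids)}
    pairs = sorted(zip(final_ids, final_rows), key=lambda p: order[p[0]])
    return Alignment([p[0] for p in pairs], [p[1] for p in pairs])
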