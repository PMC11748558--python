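"""Clade-specific degenerate primer design from a gene-family alignment.

The design stage mirrors the identity-map / codon-window workflow used to
build the published long-read gyrB primer sets:

1. pick a family *in-group* — every taxon whose 16S-like percent identity
   to a chosen reference organism falls in ``[idlow, idhigh]``;
2. slide a window of ``3 * codons`` nucleotides across the in-group
   multiple alignment (every column when ``greedy``, codon steps anchored
   to the reference frame otherwise);
3. per window column, emit the majority base when its frequency reaches the
   ``consensus`` threshold, otherwise the minimal IUPAC code covering the
   observed bases — the window consensus is the candidate primer, and its
   degeneracy is the size of the concrete primer pool it encodes;
4. pair forward and reverse candidates by predicted amplicon size and a
   degeneracy ceiling, then rank pairs by off-target amplification against
   an annotated template database.

Coordinates are 0-based half-open internally; report tables add 1-based
inclusive columns.  Adapter overhangs are concatenated only when writing
reports and never enter matching or degeneracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqcore
from .alignment import Alignment, IdentityMap

__all__ = [
    "CladeSelectionParams",
    "DesignParams",
    "CandidatePrimer",
    "PrimerPair",
    "select_ingroup",
    "consensus_column",
    "scan_windows",
    "degeneracy_profile",
    "pair_primers",
    "rank_pairs_by_offtarget",
    "primer_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CladeSelectionParams:
    """16S-identity bounds defining a primer's target clade."""

    reference_id: str
    idlow: float
    idhigh: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.idlow <= self.idhigh <= 100.0:
            raise ValueError("need 0 <= idlow <= idhigh <= 100")


@dataclass(frozen=True)
class DesignParams:
    """Window-scan parameters.

    ``codons`` sets the primer length (3 nt per codon); ``consensus`` is
    the percent frequency a single base needs to be written verbatim;
    ``min_base_freq`` is the frequency floor below which an observed base
    is left out of the ambiguity code (0 = every observed base enters —
    raise it to tolerate sequencing errors in the database).  Windows with
    any column gappier than ``max_gap_fraction`` are discarded: primers
    cannot span indels.
    """

    codons: int = 7
    consensus: float = 90.0
    greedy: bool = True
    max_gap_fraction: float = 0.0
    min_base_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.codons < 1:
            raise ValueError("codons must be >= 1")
        if not 50.0 < self.consensus <= 100.0:
            raise ValueError("consensus must be in (50, 100]")
        if not 0.0 <= self.max_gap_fraction < 1.0:
            raise ValueError("max_gap_fraction must be in [0, 1)")
        if not 0.0 <= self.min_base_freq <= 1.0:
            raise ValueError("min_base_freq must be in [0, 1]")

    @property
    def window(self) -> int:
        return 3 * self.codons


@dataclass(frozen=True)
class CandidatePrimer:
    """A window consensus in one orientation.

    ``aln_*`` are alignment-column coordinates, ``ref_*`` coordinates on
    the reference organism's ungapped gene; both 0-based half-open.
    Reverse candidates carry the reverse complement of the consensus but
    keep the window coordinates of the plus strand.
    """

    sequence: str
    aln_start: int
    aln_end: int
    ref_start: int
    ref_end: int
    orientation: str
    degeneracy: int

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward or reverse")
        if len(self.sequence) != self.aln_end - self.aln_start:
            raise ValueError("sequence length does not match window")
        if self.degeneracy != seqcore.degeneracy(self.sequence):
            raise ValueError("stored degeneracy disagrees with sequence")


@dataclass(frozen=True)
class PrimerPair:
    forward: CandidatePrimer
    reverse: CandidatePrimer
    predicted_size_min: int
    predicted_size_max: int
    target_family: str | None = None

    def __post_init__(self) -> None:
        if self.forward.ref_start >= self.reverse.ref_end:
            raise ValueError("forward primer must lie upstream of reverse")
        if self.predicted_size_min > self.predicted_size_max:
            raise ValueError("size range inverted")

    @property
    def combined_degeneracy(self) -> int:
        return self.forward.degeneracy + self.reverse.degeneracy


def select_ingroup(imap: IdentityMap, params: CladeSelectionParams) -> set[str]:
    """Taxa whose identity to the reference lies within [idlow, idhigh]."""
    if params.reference_id not in imap.taxa:
        raise KeyError(f"reference {params.reference_id!r} not in identity map")
    i = imap.taxa.index(params.reference_id)
    row = imap.matrix[i]
    return {
        t for t, v in zip(imap.taxa, row) if params.idlow <= v <= params.idhigh
    }


def consensus_column(
    counts: dict[str, float], consensus: float, min_base_freq: float = 0.0
) -> str:
    """IUPAC consensus symbol for one alignment column.

    ``counts`` are per-base weights over A/C/G/T with gaps already
    excluded.  If the most frequent base reaches ``consensus`` percent it
    is used verbatim; otherwise the minimal ambiguity code covering every
    base at frequency >= ``min_base_freq`` (and > 0) is returned.
    """
    total = sum(counts.get(b, 0.0) for b in "ACGT")
    if total <= 0:
        raise ValueError("all-gap column has no consensus")
    freqs = {b: counts.get(b, 0.0) / total for b in "ACGT"}
    top = max("ACGT", key=lambda b: freqs[b])
    if freqs[top] * 100.0 >= consensus:
        return top
    kept = {b for b, f in freqs.items() if f > 0 and f >= min_base_freq}
    if not kept:
        kept = {top}
    return seqcore.symbol_for_bases(kept)


def _column_counts(msa: Alignment, j: int) -> dict[str, float]:
    counts = {b: 0.0 for b in "ACGT"}
    for r in msa.rows:
        ch = r[j]
        if ch == "-":
            continue
        bs = seqcore.bases(ch)
        for b in bs:
            counts[b] += 1.0 / len(bs)
    return counts


def scan_windows(
    msa: Alignment, params: DesignParams, reference_id: str
) -> list[CandidatePrimer]:
    """All admissible window consensi, in both orientations.

    A window is admissible when every column satisfies the gap-fraction
    limit and the reference row is ungapped across it (reference
    coordinates would otherwise be undefined).  ``greedy`` slides by one
    alignment column; otherwise starts are restricted to reference codon
    boundaries.
    """
    w = params.window
    if w > msa.n_cols:
        raise ValueError("window is wider than the alignment")
    ref = msa.row(reference_id)
    ref_gap = np.array([c == "-" for c in ref])
    # ungapped reference position at each alignment column
    ref_pos = np.cumsum(~ref_gap) - 1

    col_ok = np.array(
        [msa.gap_fraction(j) <= params.max_gap_fraction for j in range(msa.n_cols)]
    )
    consensi = {}

    def col_symbol(j: int) -> str:
        if j not in consensi:
            consensi[j] = consensus_column(
                _column_counts(msa, j), params.consensus, params.min_base_freq
            )
        return consensi[j]

    out: list[CandidatePrimer] = []
    for start in range(msa.n_cols - w + 1):
        span = slice(start, start + w)
        if ref_gap[span].any() or not col_ok[span].all():
            continue
        if not params.greedy and ref_pos[start] % 3 != 0:
            continue
        seq = "".join(col_symbol(j) for j in range(start, start + w))
        deg = seqcore.degeneracy(seq)
        rs, re = int(ref_pos[start]), int(ref_pos[start + w - 1]) + 1
        out.append(
            CandidatePrimer(seq, start, start + w, rs, re, "forward", deg)
        )
        out.append(
            CandidatePrimer(
                seqcore.revcomp(seq), start, start + w, rs, re, "reverse", deg
            )
        )
    return out


def degeneracy_profile(candidates: list[CandidatePrimer]) -> pd.Series:
    """Minimum window degeneracy per reference start position.

    Indexed by the 0-based reference coordinate a window starts at; the
    value is the lowest degeneracy among windows starting there (one per
    start in a greedy scan).  Serialisable straight to TSV for plotting.
    """
    fwd = [c for c in candidates if c.orientation == "forward"]
    if not fwd:
        raise ValueError("no forward candidates to profile")
    best: dict[int, int] = {}
    for c in fwd:
        best[c.ref_start] = min(best.get(c.ref_start, c.degeneracy), c.degeneracy)
    s = pd.Series(best, name="min_degeneracy").sort_index()
    s.index.name = "ref_start"
    return s


def pair_primers(
    candidates: list[CandidatePrimer],
    min_amplicon: int,
    max_amplicon: int,
    max_degeneracy: int = 96,
    target_family: str | None = None,
) -> list[PrimerPair]:
    """All forward/reverse combinations passing size and degeneracy limits.

    Predicted amplicon size spans both primer footprints
    (``reverse.ref_end - forward.ref_start`` on the reference).  Sorted by
    descending predicted size, then ascending combined degeneracy, then
    coordinates.
    """
    if min_amplicon > max_amplicon:
        raise ValueError("min_amplicon exceeds max_amplicon")
    fwd = [
        c for c in candidates
        if c.orientation == "forward" and c.degeneracy <= max_degeneracy
    ]
    rev = [
        c for c in candidates
        if c.orientation == "reverse" and c.degeneracy <= max_degeneracy
    ]
    pairs = []
    for f in fwd:
        for r in rev:
            if r.ref_start < f.ref_end:
                continue
            size = r.ref_end - f.ref_start
            if min_amplicon <= size <= max_amplicon:
                pairs.append(PrimerPair(f, r, size, size, target_family))
    pairs.sort(
        key=lambda p: (
            -p.predicted_size_max,
            p.combined_degeneracy,
            p.forward.ref_start,
            p.reverse.ref_start,
        )
    )
    return pairs


def rank_pairs_by_offtarget(
    pairs: list[PrimerPair],
    templates: list[tuple[str, str]],
    taxonomy,
    target_family: str,
    pcr_params=None,
):
    """Screen pairs against an annotated template database and rank them.

    Each pair is amplified in silico against every template; predicted
    amplicons are labelled on-/off-target by the template's family.  Pairs
    are ranked by ascending off-target rate (ties: descending predicted
    size); pairs that amplify nothing at all sort last — a primer with no
    on-target products is useless however specific.  Returns
    ``[(pair, OfftargetSummary | None), ...]``.
    """
    from . import insilico_pcr  # lazy: insilico_pcr imports this module's types

    if not templates:
        raise ValueError("empty template database")
    params = pcr_params or insilico_pcr.PcrParams()
    ranked = []
    for pair in pairs:
        hits = insilico_pcr.amplify(pair, templates, params, taxonomy, target_family)
        if hits:
            summary = insilico_pcr.offtarget_summary(
                [h.family for h in hits], target_family
            )
        else:
            summary = None
        ranked.append((pair, summary))
    ranked.sort(
        key=lambda ps: (
            ps[1] is None,
            ps[1].off_target_rate if ps[1] else 0.0,
            -ps[0].predicted_size_max,
        )
    )
    return ranked


def primer_report(
    pairs: list[PrimerPair],
    name_prefix: str = "pair",
    overhang_fwd: str = "",
    overhang_rev: str = "",
) -> pd.DataFrame:
    """Report table for candidate pairs (1-based inclusive coordinates).

    Overhang adapter strings are prepended for ordering convenience only.
    """
    rows = []
    for i, p in enumerate(pairs, start=1):
        rows.append(
            {
                "name": f"{name_prefix}_{i}",
                "forward_primer": overhang_fwd + p.forward.sequence,
                "reverse_primer": overhang_rev + p.reverse.sequence,
                "forward_degeneracy": p.forward.degeneracy,
                "reverse_degeneracy": p.reverse.degeneracy,
                "predicted_size": p.predicted_size_max,
                "fwd_window_ref": f"{p.forward.ref_start + 1}-{p.forward.ref_end}",
                "rev_window_ref": f"{p.reverse.ref_start + 1}-{p.reverse.ref_end}",
                "fwd_window_aln": f"{p.forward.aln_start + 1}-{p.forward.aln_end}",
                "rev_window_aln": f"{p.reverse.aln_start + 1}-{p.reverse.aln_end}",
                "target_family": p.target_family or "",
            }
        )
    return pd.DataFrame(rows)
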