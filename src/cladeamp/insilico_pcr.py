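"""Degenerate-aware in-silico PCR and on-/off-target accounting.

Primer sites are located by base-set compatibility (a template ``N`` never
counts against a primer), with a per-primer mismatch budget and a
zero-mismatch requirement over the 3'-terminal positions — the polymerase
extends from the 3' end, so mismatches there are the ones that kill a
reaction.  Every forward/reverse site combination whose product falls in
the size window is reported on both template strands; no shortest-product
heuristic is applied, because off-target screening wants the complete
picture.

``cut_pseudo_reads`` re-amplifies long amplicons with a short-read primer
pair, yielding the pseudo-short reads used to compare taxonomic resolution
between amplicon lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqcore
from .primer_design import PrimerPair

__all__ = [
    "PcrParams",
    "AmpliconHit",
    "OfftargetSummary",
    "find_primer_sites",
    "amplify",
    "cut_pseudo_reads",
    "offtarget_summary",
    "summary_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PcrParams:
    """Site-matching tolerances and the accepted product size window.

    Defaults allow two mismatches per primer outside an exactly matching
    3-nt 3' terminus.
    """

    max_mismatch: int = 2
    three_prime_exact: int = 3
    size_min: int = 50
    size_max: int = 5000

    def __post_init__(self) -> None:
        if self.max_mismatch < 0 or self.three_prime_exact < 0:
            raise ValueError("mismatch settings must be nonnegative")
        if self.size_min > self.size_max:
            raise ValueError("size_min exceeds size_max")


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted product.  Coordinates are 0-based half-open on the
    plus strand of the template; ``sequence`` is exactly the template
    substring between the outermost footprint bounds."""

    template_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    strand: str
    length: int
    fwd_mismatches: int
    rev_mismatches: int
    sequence: str
    family: str = "Unknown"
    on_target: bool = False


@dataclass(frozen=True)
class OfftargetSummary:
    """Read- or ASV-level on-/off-target accounting for one primer set.

    ``off_target_rate`` is 100 * off_target / total, the percent of
    off-target reads among all counted (QC-passing) reads.
    """

    total: float
    on_target: float
    off_target: float
    off_target_rate: float

    def __post_init__(self) -> None:
        if abs(self.on_target + self.off_target - self.total) > 1e-9:
            raise ValueError("on_target + off_target must equal total")
        if not 0.0 <= self.off_target_rate <= 100.0:
            raise ValueError("rate outside [0, 100]")


def _scan(
    primer: str, template_mask: np.ndarray, max_mismatch: int, exact_positions
) -> list[tuple[int, int]]:
    """Degenerate sliding-window scan; returns (start, mismatches) hits."""
    pmask = seqcore.encode_mask(primer)
    plen = len(pmask)
    nwin = len(template_mask) - plen + 1
    if nwin <= 0:
        return []
    mm = np.zeros(nwin, dtype=np.int32)
    mm_exact = np.zeros(nwin, dtype=np.int32)
    exact = set(exact_positions)
    for j in range(plen):
        bad = (template_mask[j : j + nwin] & pmask[j]) == 0
        mm += bad
        if j in exact:
            mm_exact += bad
    ok = np.flatnonzero((mm <= max_mismatch) & (mm_exact == 0))
    return [(int(s), int(mm[s])) for s in ok]


def find_primer_sites(
    primer: str, template: str, params: PcrParams
) -> list[tuple[int, int, str]]:
    """All annealing sites of a degenerate primer on both template strands.

    A ``+`` site means the primer reads along the plus strand (3' end at
    ``start + len - 1``); a ``-`` site means the primer anneals to the
    plus strand itself, i.e. its reverse complement appears in the plus
    text starting at ``start`` (3' end at ``start``).  The
    ``three_prime_exact`` terminal positions must be compatible with zero
    mismatches.
    """
    primer = seqcore.normalize(primer)
    tmask = seqcore.encode_mask(template)
    plen = len(primer)
    if len(tmask) < plen:
        return []
    k = min(params.three_prime_exact, plen)
    plus = _scan(primer, tmask, params.max_mismatch, range(plen - k, plen))
    minus = _scan(
        seqcore.revcomp(primer), tmask, params.max_mismatch, range(k)
    )
    hits = [(s, mm, "+") for s, mm in plus] + [(s, mm, "-") for s, mm in minus]
    hits.sort(key=lambda h: (h[0], h[2]))
    return hits


def amplify(
    pair: PrimerPair,
    templates: list[tuple[str, str]],
    params: PcrParams,
    taxonomy=None,
    target_family: str | None = None,
) -> list[AmpliconHit]:
    """Predict all products of a primer pair over annotated templates.

    Products are formed by a forward-primer site and a downstream
    reverse-primer site (on the opposite strand) whose span falls inside
    the size window; both template orientations are considered.  A
    template absent from the taxonomy is labelled family ``Unknown``,
    counted off-target, and logged.
    """
    target_family = target_family or pair.target_family
    fwd, rev = pair.forward.sequence, pair.reverse.sequence
    lf, lr = len(fwd), len(rev)
    out: list[AmpliconHit] = []
    for tid, seq in templates:
        seq = seqcore.normalize(seq)
        family = None
        if taxonomy is not None:
            try:
                family = taxonomy.family(tid) if hasattr(taxonomy, "family") else taxonomy[tid]
            except KeyError:
                family = None
        if family is None:
            if taxonomy is not None:
                logger.warning("template %s has no taxonomy; labelling Unknown", tid)
            family = "Unknown"
        on = target_family is not None and family == target_family

        sites = find_primer_sites(fwd, seq, params)
        f_plus = [(s, m) for s, m, st in sites if st == "+"]
        f_minus = [(s, m) for s, m, st in sites if st == "-"]
        rsites = find_primer_sites(rev, seq, params)
        r_plus = [(s, m) for s, m, st in rsites if st == "+"]
        r_minus = [(s, m) for s, m, st in rsites if st == "-"]

        # plus-strand product: forward reads plus strand, reverse anneals
        # downstream on the minus strand
        for sf, mf in f_plus:
            for sr, mr in r_minus:
                if sr < sf + lf:
                    continue
                length = sr + lr - sf
                if params.size_min <= length <= params.size_max:
                    out.append(
                        AmpliconHit(
                            tid, sf, sf + lf, sr, sr + lr, "+", length,
                            mf, mr, seq[sf : sr + lr], family, on,
                        )
                    )
        # minus-strand product: gene on the other strand — reverse primer
        # reads the plus strand, forward primer anneals downstream
        for sr, mr in r_plus:
            for sf, mf in f_minus:
                if sf < sr + lr:
                    continue
                length = sf + lf - sr
                if params.size_min <= length <= params.size_max:
                    out.append(
                        AmpliconHit(
                            tid, sf, sf + lf, sr, sr + lr, "-", length,
                            mf, mr, seq[sr : sf + lf], family, on,
                        )
                    )
    return out


def cut_pseudo_reads(
    long_amplicons: list[tuple[str, str]],
    short_pair: PrimerPair,
    params: PcrParams,
    suffix: str = "_pseudo",
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Trim long amplicons to the region a short-read pair would amplify.

    Each long amplicon with exactly one internal short-primer product
    yields one pseudo read (primers included, an exact substring of its
    parent).  Amplicons with zero or multiple products are dropped and
    logged with reasons ``no_site`` / ``multiple_products``.  Returns
    ``(pseudo_records, drop_log)``; pseudo IDs are the parent ID plus
    ``suffix``.
    """
    reads: list[tuple[str, str]] = []
    drops: list[tuple[str, str]] = []
    for pid, seq in long_amplicons:
        hits = amplify(short_pair, [(pid, seq)], params)
        if len(hits) == 1:
            reads.append((pid + suffix, hits[0].sequence))
        elif not hits:
            drops.append((pid, "no_site"))
            logger.info("dropping %s: no internal short-primer site pair", pid)
        else:
            drops.append((pid, "multiple_products"))
            logger.info("dropping %s: %d internal products", pid, len(hits))
    return reads, drops


def offtarget_summary(
    labels: list[str],
    target_family: str,
    weights: list[float] | None = None,
) -> OfftargetSummary:
    """On-/off-target accounting over per-read (or per-ASV) family labels.

    ``weights`` are read counts for read-weighted rates; omit them for
    unweighted ASV mode (weight 1 each).
    """
    if not labels:
        raise ValueError("no labels to summarise")
    if weights is None:
        weights = [1.0] * len(labels)
    if len(weights) != len(labels):
        raise ValueError("labels and weights differ in length")
    if any(w < 0 for w in weights):
        raise ValueError("negative weights")
    total = float(sum(weights))
    on = float(sum(w for l, w in zip(labels, weights) if l == target_family))
    off = total - on
    rate = 100.0 * off / total if total else 0.0
    return OfftargetSummary(total, on, off, rate)


def summary_table(entries: list[tuple[str, dict]]) -> pd.DataFrame:
    """Combined per-primer-set accounting table.

    ``entries`` are ``(primer_set_name, fields)`` where fields may carry
    ASV-level and read-level :class:`OfftargetSummary` objects under keys
    ``asv`` and ``reads`` plus an optional ``total_reads``.
    """
    rows = []
    for name, fields in entries:
        asv: OfftargetSummary | None = fields.get("asv")
        rd: OfftargetSummary | None = fields.get("reads")
        rate = rd if rd is not None else asv
        rows.append(
            {
                "primer_set": name,
                "total_asvs": int(asv.total) if asv else "",
                "on_target_asvs": int(asv.on_target) if asv else "",
                "off_target_asvs": int(asv.off_target) if asv else "",
                "total_reads": fields.get("total_reads", ""),
                "total_qc_reads": int(rd.total) if rd else "",
                "on_target_reads": int(rd.on_target) if rd else "",
                "off_target_reads": int(rd.off_target) if rd else "",
                "off_target_rate_pct": round(rate.off_target_rate, 2) if rate else "",
            }
        )
    return pd.DataFrame(rows)
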