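"""Endogenous target-mimic (eTM) detection.

A target mimic is a transcript region nearly complementary to a miRNA
but with a short transcript-side insertion bulge opposite the slicing
register (miRNA positions ~10–11), the architecture of IPS1/pilncr1
relative to miR399.  The bulge prevents cleavage, so the transcript
sequesters the miRNA instead of being sliced.

The scan is rule-based: one insertion bulge of 1..max_insert transcript
bases between two adjacent miRNA positions within the cleavage region,
at most ``max_mismatch_outside`` mismatches in the paired flanks, and
exclusion of any region that also contains a perfectly complementary
(cleavable) ungapped window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .degradome_targets import (
    BindingSite,
    TargetCall,
    _encode,
    _gu_cost,
    _wobble_pattern,
    find_sites,
    revcomp,
)
from .preprocess import normalize_seq

__all__ = ["MimicHit", "scan_mimics", "mimic_report", "pairing_diagram"]


@dataclass(frozen=True)
class MimicHit:
    """A candidate mimic locus (1-based closed transcript interval).

    ``bulge_after`` is the miRNA position after which the unpaired
    transcript insertion sits (e.g. 10 for a bulge between positions 10
    and 11); ``inserted_bases`` are the transcript bases of the bulge.
    """

    transcript_id: str
    mirna_id: str
    start: int
    end: int
    bulge_after: int
    inserted_bases: str
    mismatches_outside_bulge: float
    pairing_string: str


def _segment_scores(
    enc: np.ndarray, pat: np.ndarray, wob: np.ndarray, cost: float
) -> np.ndarray:
    """Mismatch score of ``pat`` against every window start of ``enc``."""
    if enc.size < pat.size:
        return np.zeros(0)
    win = np.lib.stride_tricks.sliding_window_view(enc, pat.size)
    neq = win != pat
    score = neq.sum(axis=1).astype(float)
    if cost != 1.0:
        wobble = (neq & (win == wob)).sum(axis=1)
        score -= (1.0 - cost) * wobble
    return score


def scan_mimics(
    transcripts: Mapping[str, str],
    mirna_seq: str,
    mirna_id: str = "",
    max_insert: int = 3,
    max_mismatch_outside: float = 3,
    min_insert: int = 1,
    bulge_positions: tuple[int, ...] = (10, 9),
    gu_policy: str = "mismatch",
    exclude_cleavable: bool = True,
) -> list[MimicHit]:
    """Scan transcripts for miRNA target-mimic loci.

    For each bulge placement (after miRNA position ``j`` for ``j`` in
    ``bulge_positions``) and insertion length ``b`` in
    ``min_insert..max_insert``, a locus matches when the two paired
    flanks carry at most ``max_mismatch_outside`` mismatches in total.
    Overlapping interpretations of one locus are collapsed to the one
    with fewest mismatches, then shortest bulge.  Loci containing a
    perfectly complementary ungapped window are cleavable sites, not
    mimics, and are excluded unless ``exclude_cleavable=False``.
    """
    mirna = normalize_seq(mirna_seq)
    L = len(mirna)
    if L < 18:
        raise ValueError("miRNA shorter than 18 nt")
    cost = _gu_cost(gu_policy)
    rc = revcomp(mirna)
    rc_enc = _encode(rc)
    wob = _wobble_pattern(mirna)
    hits: dict[tuple[str, int], MimicHit] = {}
    for tid, seq in transcripts.items():
        tx = normalize_seq(seq)
        enc = _encode(tx)
        perfect = None
        if exclude_cleavable:
            perfect = _segment_scores(enc, rc_enc, wob, cost) == 0
        for j in bulge_positions:
            # transcript 5'->3': flank1 pairs miRNA L..j+1, then the
            # bulge, then flank2 pairs miRNA j..1
            len1 = L - j
            pat1, wob1 = rc_enc[:len1], wob[:len1]
            pat2, wob2 = rc_enc[len1:], wob[len1:]
            s1 = _segment_scores(enc, pat1, wob1, cost)
            s2 = _segment_scores(enc, pat2, wob2, cost)
            for b in range(min_insert, max_insert + 1):
                span = L + b
                n_windows = len(tx) - span + 1
                if n_windows <= 0:
                    continue
                total = s1[:n_windows] + s2[len1 + b: len1 + b + n_windows]
                for t in np.flatnonzero(total <= max_mismatch_outside):
                    t = int(t)
                    if b == 0 and total[t] == 0 and exclude_cleavable:
                        continue
                    if perfect is not None:
                        lo = max(0, t)
                        hi = min(perfect.size, t + span - L + 1)
                        if hi > lo and perfect[lo:hi].any():
                            continue
                    hit = MimicHit(
                        transcript_id=tid,
                        mirna_id=mirna_id,
                        start=t + 1,
                        end=t + span,
                        bulge_after=j,
                        inserted_bases=tx[t + len1: t + len1 + b],
                        mismatches_outside_bulge=float(total[t])
                        if cost == 0.5
                        else int(total[t]),
                        pairing_string=_pairing(mirna, tx, t, j, b, cost),
                    )
                    key = (tid, t)
                    old = hits.get(key)
                    if old is None or (
                        hit.mismatches_outside_bulge,
                        len(hit.inserted_bases),
                    ) < (old.mismatches_outside_bulge, len(old.inserted_bases)):
                        hits[key] = hit
    return sorted(
        hits.values(), key=lambda h: (h.transcript_id, h.start, h.mirna_id)
    )


def _pairing(tx_mirna: str, tx: str, t: int, j: int, b: int, cost: float) -> str:
    """Pairing string in miRNA 5'->3' order; '-' spans the bulge."""
    L = len(tx_mirna)
    out = []
    for i in range(1, L + 1):
        # transcript index (0-based) paired to miRNA position i
        if i <= j:
            idx = t + (L - j) + b + (j - i)
        else:
            idx = t + (L - i)
        base = tx[idx]
        comp = revcomp(tx_mirna[i - 1])
        if base == comp:
            out.append("|")
        elif (tx_mirna[i - 1] == "G" and base == "T") or (
            tx_mirna[i - 1] == "T" and base == "G"
        ):
            out.append("o" if cost < 1.0 else "x")
        else:
            out.append("x")
        if i == j and b > 0:
            out.append("-" * b)
    return "".join(out)


def pairing_diagram(hit: MimicHit, mirna_seq: str, transcript_seq: str) -> str:
    """Plain-text alignment of a mimic locus, miRNA 3'->5' on top of the
    transcript region 5'->3', with the bulge spelled out."""
    mirna = normalize_seq(mirna_seq)
    tx = normalize_seq(transcript_seq)
    L = len(mirna)
    j, b = hit.bulge_after, len(hit.inserted_bases)
    top = mirna[::-1]  # 3'->5'
    top_line = "3'-" + top[: L - j] + "-" * b + top[L - j:] + "-5' miRNA"
    region = tx[hit.start - 1: hit.end]
    bottom_line = "5'-" + region + "-3' transcript"
    pairs = hit.pairing_string[::-1]
    return "\n".join([top_line, "   " + pairs, bottom_line]) + "\n"


def mimic_report(
    hits: Iterable[MimicHit],
    target_calls: Iterable[TargetCall] = (),
    transcript_de: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join mimic loci with degradome and transcript-abundance evidence.

    For each hit, reports whether any valid degradome cleavage call
    overlaps the locus for the same miRNA (a true mimic should show
    none) and the transcript's differential-abundance statistics when a
    DE table (indexed by transcript id, columns log2FC/FDR) is given.
    """
    calls = list(target_calls)
    rows = []
    for h in hits:
        overlapping = [
            c
            for c in calls
            if c.site.transcript_id == h.transcript_id
            and c.site.start <= h.end
            and c.site.end >= h.start
        ]
        cleaved = any(c.valid for c in overlapping)
        row = {
            "transcript_id": h.transcript_id,
            "mirna_id": h.mirna_id,
            "start": h.start,
            "end": h.end,
            "bulge_after": h.bulge_after,
            "insert_len": len(h.inserted_bases),
            "mismatches_outside_bulge": h.mismatches_outside_bulge,
            "degradome_cleaved": cleaved,
            "transcript_log2FC": np.nan,
            "transcript_FDR": np.nan,
        }
        if transcript_de is not None and h.transcript_id in transcript_de.index:
            row["transcript_log2FC"] = float(
                transcript_de.loc[h.transcript_id, "log2FC"]
            )
            row["transcript_FDR"] = float(transcript_de.loc[h.transcript_id, "FDR"])
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "mirna_id",
            "start",
            "end",
            "bulge_after",
            "insert_len",
            "mismatches_outside_bulge",
            "degradome_cleaved",
            "transcript_log2FC",
            "transcript_FDR",
        ],
    )
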