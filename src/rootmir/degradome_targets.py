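"""Degradome (PARE) validation of miRNA-guided transcript cleavage.

A miRNA binding site is a transcript window whose antiparallel pairing
to the miRNA carries fewer than 4 mismatches.  Degradome tag 5' ends
piled up on the transcript evidence cleavage: a target call is valid
when at least one tag 5' end falls on a transcript base paired to miRNA
positions 9–11 (the canonical slicing register opposite positions
10–11).

Transcript coordinates are 1-based closed throughout; miRNA positions
are numbered 1..L from the miRNA 5' end, so position ``i`` pairs with
transcript base ``site_end - i + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import normalize_seq

__all__ = [
    "BindingSite",
    "TagPileup",
    "TargetCall",
    "find_sites",
    "pileup_tags",
    "pileup_from_table",
    "call_targets",
    "targets_table",
    "tplot_text",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


def _gu_cost(policy: str) -> float:
    try:
        return {"mismatch": 1.0, "match": 0.0, "half": 0.5}[policy]
    except KeyError:
        raise ValueError(f"unknown gu_policy {policy!r}") from None


@dataclass(frozen=True)
class BindingSite:
    """A miRNA binding window on a transcript (1-based closed interval)."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    mismatch_count: float
    pairing_string: str  # miRNA 5'->3'; '|' WC pair, 'o' G:U, 'x' mismatch

    def paired_base(self, mirna_position: int) -> int:
        """Transcript coordinate paired to the given miRNA position."""
        return self.end - mirna_position + 1


def _window_scores(
    tx: str, pattern: str, gu_wobble_mask_fwd: np.ndarray, gu_cost: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch and wobble counts of ``pattern`` against every window.

    ``pattern`` is the expected transcript-strand sequence (the reverse
    complement of the miRNA); ``gu_wobble_mask_fwd`` marks, per pattern
    position, which transcript base would make a G:U pair instead of a
    clean mismatch (G opposite miRNA U, or U/T opposite miRNA G).
    """
    L = len(pattern)
    enc = _encode(tx)
    if enc.size < L:
        return np.zeros(0), np.zeros(0)
    win = np.lib.stride_tricks.sliding_window_view(enc, L)
    pat = _encode(pattern)
    neq = win != pat
    wobble = np.zeros(win.shape[0])
    if gu_cost != 1.0:
        wob = win == gu_wobble_mask_fwd
        wobble = (neq & wob).sum(axis=1)
    mism = neq.sum(axis=1) - wobble
    return mism, wobble


def _wobble_pattern(mirna: str) -> np.ndarray:
    """Per-position transcript base that forms a G:U pair, in the
    transcript-strand frame of revcomp(miRNA); 255 where no wobble
    exists."""
    out = []
    for b in reversed(mirna):  # transcript 5'->3' pairs miRNA 3'->5'
        if b == "G":
            out.append(ord("T"))
        elif b == "T":
            out.append(ord("G"))
        else:
            out.append(255)
    return np.array(out, dtype=np.uint8)


def find_sites(
    mirna_seq: str,
    transcript_seq: str,
    mirna_id: str = "",
    transcript_id: str = "",
    max_mismatch: float = 3,
    gu_policy: str = "mismatch",
) -> list[BindingSite]:
    """All transcript windows pairing the miRNA with <= ``max_mismatch``
    mismatch score.

    Pairing is antiparallel Watson–Crick; a G:U wobble costs 1, 0 or 0.5
    under ``gu_policy`` "mismatch" (default), "match" or "half".
    """
    mirna = normalize_seq(mirna_seq)
    tx = normalize_seq(transcript_seq)
    L = len(mirna)
    if L > len(tx):
        return []
    cost = _gu_cost(gu_policy)
    pattern = revcomp(mirna)
    wob_pat = _wobble_pattern(mirna)
    mism, wobble = _window_scores(tx, pattern, wob_pat, cost)
    score = mism + cost * wobble
    sites = []
    for t in np.flatnonzero(score <= max_mismatch):
        start, end = int(t) + 1, int(t) + L
        pairing = []
        for i in range(1, L + 1):
            b = tx[end - i]  # 0-based index of base paired to position i
            if b == pattern[L - i]:
                pairing.append("|")
            elif (mirna[i - 1] == "G" and b == "T") or (
                mirna[i - 1] == "T" and b == "G"
            ):
                pairing.append("o" if cost < 1.0 else "x")
            else:
                pairing.append("x")
        sites.append(
            BindingSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                start=start,
                end=end,
                mismatch_count=float(score[t]) if cost == 0.5 else int(score[t]),
                pairing_string="".join(pairing),
            )
        )
    return sites


@dataclass
class TagPileup:
    """Histogram of degradome tag 5' ends along one transcript."""

    transcript_id: str
    counts: np.ndarray  # 1-based position p -> counts[p-1]
    multi_tags: set = field(default_factory=set)

    def at(self, position: int) -> int:
        if 1 <= position <= self.counts.size:
            return int(self.counts[position - 1])
        return 0


def pileup_tags(
    tags: Mapping[str, int],
    transcripts: Mapping[str, str],
    unique_only: bool = False,
) -> dict[str, TagPileup]:
    """Exact-substring map degradome tags onto transcripts.

    A tag matching several loci is counted at every locus and flagged in
    ``multi_tags`` (or dropped entirely with ``unique_only=True``).
    """
    seqs = {tid: normalize_seq(s) for tid, s in transcripts.items()}
    pileups = {
        tid: TagPileup(tid, np.zeros(len(s), dtype=np.int64))
        for tid, s in seqs.items()
    }
    for tag, count in tags.items():
        tag = normalize_seq(tag)
        hits = []
        for tid, s in seqs.items():
            p = s.find(tag)
            while p >= 0:
                hits.append((tid, p))
                p = s.find(tag, p + 1)
        if not hits:
            continue
        if len(hits) > 1:
            if unique_only:
                continue
            for tid, _ in hits:
                pileups[tid].multi_tags.add(tag)
        for tid, p in hits:
            pileups[tid].counts[p] += count
    return pileups


def pileup_from_table(
    table: pd.DataFrame, transcripts: Mapping[str, str]
) -> dict[str, TagPileup]:
    """Build pileups from a pre-mapped tag table with columns
    transcript_id, position (1-based 5' end), count."""
    pileups = {
        tid: TagPileup(tid, np.zeros(len(s), dtype=np.int64))
        for tid, s in transcripts.items()
    }
    for row in table.itertuples(index=False):
        pu = pileups[row.transcript_id]
        if not 1 <= row.position <= pu.counts.size:
            raise ValueError(
                f"position {row.position} outside {row.transcript_id}"
            )
        pu.counts[row.position - 1] += row.count
    return pileups


@dataclass
class TargetCall:
    """A binding site scored against the degradome pileup."""

    site: BindingSite
    valid_reads_9_11: int
    total_reads_in_site: int
    peak_position: int | None
    category: str  # dominant-peak | co-dominant | minor
    valid: bool


def call_targets(
    sites: Iterable[BindingSite], pileups: Mapping[str, TagPileup]
) -> list[TargetCall]:
    """Validity calls: >= 1 tag 5' end opposite miRNA positions 9–11 and
    fewer than 4 mismatches.

    The category compares the site's best 9–11 position against the
    transcript-wide modal 5' position: dominant-peak when it is the
    strict mode, co-dominant on a tie, minor otherwise.
    """
    calls = []
    for site in sites:
        if site.transcript_id not in pileups:
            raise KeyError(f"no pileup for transcript {site.transcript_id}")
        pu = pileups[site.transcript_id]
        window_positions = [site.paired_base(i) for i in (9, 10, 11)]
        window_counts = {p: pu.at(p) for p in window_positions}
        valid_reads = sum(window_counts.values())
        total_in_site = sum(
            pu.at(p) for p in range(site.start, site.end + 1)
        )
        peak_position = None
        if valid_reads > 0:
            peak_position = max(window_counts, key=window_counts.get)
        max_in_window = max(window_counts.values())
        outside = np.delete(
            pu.counts, [p - 1 for p in window_positions if 1 <= p <= pu.counts.size]
        )
        max_outside = int(outside.max()) if outside.size else 0
        if valid_reads == 0:
            category = "minor"
        elif max_in_window > max_outside:
            category = "dominant-peak"
        elif max_in_window == max_outside:
            category = "co-dominant"
        else:
            category = "minor"
        calls.append(
            TargetCall(
                site=site,
                valid_reads_9_11=int(valid_reads),
                total_reads_in_site=int(total_in_site),
                peak_position=peak_position,
                category=category,
                valid=valid_reads >= 1 and site.mismatch_count < 4,
            )
        )
    return calls


def targets_table(calls: Sequence[TargetCall]) -> pd.DataFrame:
    """Flatten target calls to a tidy frame."""
    return pd.DataFrame(
        [
            {
                "mirna_id": c.site.mirna_id,
                "transcript_id": c.site.transcript_id,
                "site_start": c.site.start,
                "site_end": c.site.end,
                "mismatch_count": c.site.mismatch_count,
                "valid_reads_9_11": c.valid_reads_9_11,
                "total_reads_in_site": c.total_reads_in_site,
                "peak_position": c.peak_position,
                "category": c.category,
                "valid": c.valid,
            }
            for c in calls
        ],
        columns=[
            "mirna_id",
            "transcript_id",
            "site_start",
            "site_end",
            "mismatch_count",
            "valid_reads_9_11",
            "total_reads_in_site",
            "peak_position",
            "category",
            "valid",
        ],
    )


def tplot_text(pileup: TagPileup, site: BindingSite | None = None) -> str:
    """Plain-text t-plot: tab-separated position/count lines, with the
    site's 9–11 cleavage window marked by '*'."""
    marked = set()
    if site is not None:
        marked = {site.paired_base(i) for i in (9, 10, 11)}
    lines = [f"# transcript {pileup.transcript_id}", "position\tcount\tcleavage_window"]
    for p in np.flatnonzero(pileup.counts) + 1:
        flag = "*" if p in marked else ""
        lines.append(f"{p}\t{pileup.counts[p - 1]}\t{flag}")
    return "\n".join(lines) + "\n"
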