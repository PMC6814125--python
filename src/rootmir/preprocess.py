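"""Read cleaning for small-RNA and degradome libraries.

Raw reads are adapter-trimmed, quality-filtered on their 5' window and
collapsed to unique counted tags.  Small-RNA tags keep the full insert
(>= 18 nt); degradome tags are the 20-nt 5' segment of the read, which is
where the uncapped cleavage product's 5' end lies.

Sequences are normalised to uppercase DNA (U -> T) at the parsing
boundary; all downstream modules work in that alphabet.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "parse_fastq",
    "trim_adapter",
    "quality_filter",
    "collapse_unique",
    "degradome_prepare",
    "process_srna_library",
    "process_degradome_library",
    "write_tag_table",
    "read_tag_table",
]

PHRED_OFFSET = 33


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA to the DNA alphabet."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class Read:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    quality: tuple[int, ...]

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def parse_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate Phred+33 FASTQ records as :class:`Read` objects."""
    with open(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield Read(
                id=title.split()[0],
                sequence=normalize_seq(seq),
                quality=tuple(ord(c) - PHRED_OFFSET for c in qual),
            )


def trim_adapter(read: Read, adapter: str, min_overlap: int = 8) -> Read:
    """Truncate a read at the first exact match of the 3' adapter prefix.

    The full adapter, or any of its prefixes of length >= ``min_overlap``
    ending at the 3' end of the read, triggers truncation.  Reads without
    a detectable adapter pass through unchanged; matching is exact.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    adapter = normalize_seq(adapter)
    seq = read.sequence
    cut = seq.find(adapter)
    if cut < 0:
        # partial adapter running off the 3' end
        for k in range(min(len(adapter), len(seq)) - 1, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut < 0:
        return read
    return replace(read, sequence=seq[:cut], quality=read.quality[:cut])


def quality_filter(read: Read, min_q: int = 25, window_nt: int = 25) -> bool:
    """Keep/drop decision on the 5' quality window.

    A read is dropped iff any of its first ``window_nt`` bases scores
    strictly below ``min_q`` (the threshold itself passes).  Reads shorter
    than the window are evaluated over their full length; the separate
    length filter handles short inserts.  Returns True to keep.
    """
    window = read.quality[:window_nt]
    return all(q >= min_q for q in window)


def collapse_unique(reads: Iterable[Read | str], min_len: int = 18) -> Counter:
    """Collapse reads to unique-sequence counts, dropping short tags.

    Accepts Read objects or bare sequences.  Tags shorter than ``min_len``
    nucleotides are removed; the remaining total count equals the number
    of surviving reads.
    """
    tags: Counter = Counter()
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        if len(seq) >= min_len:
            tags[seq] += 1
    return tags


def degradome_prepare(
    reads: Iterable[Read | str], tag_len: int = 20, mode: str = "retain"
) -> Counter:
    """Collapse degradome reads to unique 20-nt tags.

    ``mode="retain"`` (default) keeps the first ``tag_len`` nucleotides as
    the tag — the 5' end of a degradome read marks the cleavage product.
    ``mode="literal"`` instead removes the first ``tag_len`` nucleotides
    and keeps the remainder.  Reads shorter than ``tag_len`` (or, in
    literal mode, not extending past it) are dropped.
    """
    if mode not in ("retain", "literal"):
        raise ValueError(f"unknown degradome trim mode: {mode!r}")
    tags: Counter = Counter()
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        if mode == "retain":
            if len(seq) >= tag_len:
                tags[seq[:tag_len]] += 1
        else:
            if len(seq) > tag_len:
                tags[seq[tag_len:]] += 1
    return tags


def process_srna_library(
    fastq_path: str | Path,
    adapter: str,
    min_q: int = 25,
    window_nt: int = 25,
    min_len: int = 18,
    min_overlap: int = 8,
) -> Counter:
    """Full small-RNA cleaning chain: trim -> quality filter -> collapse."""
    kept = (
        trim_adapter(r, adapter, min_overlap)
        for r in parse_fastq(fastq_path)
        if quality_filter(r, min_q=min_q, window_nt=window_nt)
    )
    return collapse_unique(kept, min_len=min_len)


def process_degradome_library(
    fastq_path: str | Path,
    min_q: int = 25,
    window_nt: int = 20,
    tag_len: int = 20,
    mode: str = "retain",
) -> Counter:
    """Degradome cleaning chain: quality filter (20-nt window) -> 20-nt tags."""
    kept = (
        r
        for r in parse_fastq(fastq_path)
        if quality_filter(r, min_q=min_q, window_nt=window_nt)
    )
    return degradome_prepare(kept, tag_len=tag_len, mode=mode)


def write_tag_table(tags: Counter, path: str | Path, library_id: str) -> None:
    """Write a unique-tag count table as TSV (sequence, count, library_id)."""
    df = pd.DataFrame(
        {"sequence": list(tags), "count": list(tags.values())}
    ).sort_values(["count", "sequence"], ascending=[False, True])
    df["library_id"] = library_id
    df.to_csv(path, sep="\t", index=False)


def read_tag_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
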