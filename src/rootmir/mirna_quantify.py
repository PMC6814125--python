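"""Tag-to-miRNA assignment, isomiR classification and RPTM abundance.

Unique small-RNA tags are matched exactly against a set of canonical
mature miRNAs; family members with identical mature sequences are merged
into one grouped identifier (e.g. ``zma-miR399e,i,j-3p``) and counted
once.  Tags that are not exact matches are interpreted as isomiRs — 5',
3' or internal sequence variants of the closest canonical miRNA — under a
smallest-edit rule, with 3' extensions checked against the hairpin to
distinguish templated from untemplated additions.

Abundances are expressed in RPTM (reads per ten million mapped tags) and
a retention filter keeps miRNAs with >= 1 RPTM in at least 3 of the 4
libraries of some treatment group.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import normalize_seq

__all__ = [
    "MiRNARecord",
    "MiRNAReference",
    "EditBounds",
    "IsomiRCall",
    "MatchResult",
    "classify_isomir",
    "match_tags",
    "quantify_libraries",
    "rptm_normalize",
    "retention_filter",
    "merge_ids",
]

CANONICAL = "canonical"
VARIANT_5P = "5p-variant"
VARIANT_3P = "3p-variant"
VARIANT_5P3P = "5p3p-variant"
VARIANT_INTERNAL = "internal-variant"
VARIANT_NOVEL = "variant-novel"


@dataclass(frozen=True)
class MiRNARecord:
    """One canonical mature miRNA with its precursor hairpin."""

    mirna_id: str
    mature_seq: str
    hairpin_seq: str
    arm: str = ""
    family: str = ""

    def __post_init__(self):
        object.__setattr__(self, "mature_seq", normalize_seq(self.mature_seq))
        object.__setattr__(self, "hairpin_seq", normalize_seq(self.hairpin_seq))
        if self.mature_seq not in self.hairpin_seq:
            raise ValueError(
                f"{self.mirna_id}: mature sequence not found in hairpin"
            )
        if not self.family:
            m = re.search(r"miR(\d+)", self.mirna_id, flags=re.IGNORECASE)
            object.__setattr__(
                self, "family", f"miR{m.group(1)}" if m else self.mirna_id
            )
        if not self.arm:
            m = re.search(r"-(5p|3p)$", self.mirna_id)
            object.__setattr__(self, "arm", m.group(1) if m else "")

    @property
    def hairpin_offset(self) -> int:
        return self.hairpin_seq.index(self.mature_seq)


def merge_ids(ids: Sequence[str]) -> str:
    """Collapse identifiers of identical-sequence family members.

    ``["zma-miR399e-3p", "zma-miR399i-3p", "zma-miR399j-3p"]`` becomes
    ``"zma-miR399e,i,j-3p"``.  Falls back to a ``;`` join when the ids do
    not share a prefix/suffix frame.
    """
    ids = sorted(set(ids))
    if len(ids) == 1:
        return ids[0]
    prefix = ids[0]
    for s in ids[1:]:
        while not s.startswith(prefix):
            prefix = prefix[:-1]
    suffix = ids[0]
    for s in ids[1:]:
        while not s.endswith(suffix):
            suffix = suffix[1:]
    middles = [s[len(prefix): len(s) - len(suffix)] for s in ids]
    if all(middles) and all(len(m) <= 3 for m in middles):
        return prefix + ",".join(middles) + suffix
    return ";".join(ids)


class MiRNAReference:
    """Canonical mature miRNAs with hairpins; the coordinate frame for
    isomiR and target calls.

    Identical mature sequences are grouped under a merged identifier so
    that a tag matching several indistinguishable family members is
    counted exactly once.
    """

    def __init__(self, records: Iterable[MiRNARecord]):
        self.records: list[MiRNARecord] = list(records)
        if not self.records:
            raise ValueError("empty miRNA reference")
        ids = [r.mirna_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in reference")
        by_seq: dict[str, list[str]] = {}
        for r in self.records:
            by_seq.setdefault(r.mature_seq, []).append(r.mirna_id)
        self.group_of_seq: dict[str, str] = {
            seq: merge_ids(members) for seq, members in by_seq.items()
        }
        self.group_ids: list[str] = sorted(set(self.group_of_seq.values()))
        self._by_id = {r.mirna_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, mirna_id: str) -> MiRNARecord:
        return self._by_id[mirna_id]

    def group_for(self, mirna_id: str) -> str:
        return self.group_of_seq[self._by_id[mirna_id].mature_seq]

    def to_fasta(self, mature_path: str | Path, hairpin_path: str | Path) -> None:
        mat, hp = [], []
        for r in self.records:
            desc = f"family={r.family} arm={r.arm}"
            mat.append(SeqRecord(Seq(r.mature_seq), id=r.mirna_id, description=desc))
            hp.append(
                SeqRecord(Seq(r.hairpin_seq), id=r.mirna_id, description="hairpin")
            )
        SeqIO.write(mat, str(mature_path), "fasta")
        SeqIO.write(hp, str(hairpin_path), "fasta")

    @classmethod
    def from_fasta(
        cls, mature_path: str | Path, hairpin_path: str | Path
    ) -> "MiRNAReference":
        hairpins = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(hairpin_path), "fasta")
        }
        records = []
        for rec in SeqIO.parse(str(mature_path), "fasta"):
            fields = dict(
                tok.split("=", 1) for tok in rec.description.split() if "=" in tok
            )
            if rec.id not in hairpins:
                raise ValueError(f"no hairpin for mature miRNA {rec.id}")
            records.append(
                MiRNARecord(
                    mirna_id=rec.id,
                    mature_seq=str(rec.seq),
                    hairpin_seq=hairpins[rec.id],
                    arm=fields.get("arm", ""),
                    family=fields.get("family", ""),
                )
            )
        return cls(records)


@dataclass(frozen=True)
class EditBounds:
    """Edit limits separating an isomiR from a novel variant."""

    max_offset5: int = 2
    max_offset3: int = 3
    max_substitutions: int = 2


@dataclass
class IsomiRCall:
    """A tag interpreted relative to its best-matching canonical miRNA.

    ``offset5`` is the shift of the 5' start (+1 = first canonical base
    trimmed, −1 = one-base 5' extension); ``offset3`` is the shift of the
    3' end (+1 = one-base 3' extension, −1 = last base trimmed).
    ``substitutions`` are internal polymorphisms as (1-based canonical
    position, tag base).  ``templated3`` records whether every 3'
    extension base continues the hairpin sequence.
    """

    tag_seq: str
    canonical_id: str | None
    variant_class: str
    offset5: int = 0
    offset3: int = 0
    templated3: bool = False
    substitutions: tuple[tuple[int, str], ...] = ()
    untemplated_end_bases: int = 0

    @property
    def edit_cost(self) -> tuple[int, int, int]:
        return (
            len(self.substitutions),
            self.untemplated_end_bases,
            abs(self.offset5) + abs(self.offset3),
        )


def _align_tag(tag: str, record: MiRNARecord, offset5: int) -> IsomiRCall | None:
    """Interpret ``tag`` against one canonical at a fixed 5' offset."""
    mature, hairpin = record.mature_seq, record.hairpin_seq
    L = len(mature)
    offset3 = len(tag) - L + offset5
    h = record.hairpin_offset
    subs: list[tuple[int, str]] = []
    untemplated = 0
    ext3_templated = True
    for idx, base in enumerate(tag):
        c = h + offset5 + idx  # hairpin coordinate
        in_canonical = h <= c <= h + L - 1
        expected = hairpin[c] if 0 <= c < len(hairpin) else None
        if in_canonical:
            if base != expected:
                subs.append((c - h + 1, base))
        else:
            if expected is None or base != expected:
                untemplated += 1
                if c > h + L - 1:
                    ext3_templated = False
    call = IsomiRCall(
        tag_seq=tag,
        canonical_id=record.mirna_id,
        variant_class="",
        offset5=offset5,
        offset3=offset3,
        templated3=offset3 > 0 and ext3_templated,
        substitutions=tuple(subs),
        untemplated_end_bases=untemplated,
    )
    if subs:
        call.variant_class = VARIANT_INTERNAL
    elif offset5 != 0 and offset3 != 0:
        call.variant_class = VARIANT_5P3P
    elif offset5 != 0:
        call.variant_class = VARIANT_5P
    elif offset3 != 0:
        call.variant_class = VARIANT_3P
    else:
        call.variant_class = CANONICAL
    return call


def classify_isomir(
    tag: str,
    reference: MiRNAReference,
    bounds: EditBounds = EditBounds(),
    abundance: Mapping[str, float] | None = None,
) -> IsomiRCall:
    """Smallest-edit isomiR interpretation of a tag.

    The best canonical is the one minimising (internal substitutions,
    untemplated end bases, total end offset), in that priority order;
    ties are broken by the more abundant canonical when ``abundance`` is
    supplied, then by id.  Tags whose best interpretation exceeds
    ``bounds`` are labelled ``variant-novel``.
    """
    if len(tag) < 18:
        raise ValueError("tags shorter than 18 nt are not classifiable")
    tag = normalize_seq(tag)
    best: IsomiRCall | None = None
    best_key = None
    for record in reference:
        L = len(record.mature_seq)
        for offset5 in range(-bounds.max_offset5, bounds.max_offset5 + 1):
            offset3 = len(tag) - L + offset5
            if abs(offset3) > bounds.max_offset3:
                continue
            call = _align_tag(tag, record, offset5)
            if call is None or len(call.substitutions) > bounds.max_substitutions:
                continue
            ab = -(abundance or {}).get(record.mirna_id, 0.0)
            key = (*call.edit_cost, ab, record.mirna_id)
            if best_key is None or key < best_key:
                best, best_key = call, key
    if best is None:
        return IsomiRCall(tag_seq=tag, canonical_id=None, variant_class=VARIANT_NOVEL)
    return best


@dataclass
class MatchResult:
    """Per-library assignment of unique tags to canonical groups/isomiRs."""

    canonical_counts: Counter = field(default_factory=Counter)
    isomir_calls: list[tuple[IsomiRCall, int]] = field(default_factory=list)
    unassigned: Counter = field(default_factory=Counter)
    total_tags: int = 0


def match_tags(
    tags: Mapping[str, int],
    reference: MiRNAReference,
    bounds: EditBounds = EditBounds(),
    classify: bool = True,
) -> MatchResult:
    """Assign unique tags to canonical miRNA groups and isomiR classes.

    Exact matches are counted under the merged group id of their mature
    sequence; non-exact tags are forwarded to :func:`classify_isomir`.
    IsomiR counts are reported separately and never added to the
    canonical counts.
    """
    result = MatchResult(total_tags=sum(tags.values()))
    for seq, count in tags.items():
        seq = normalize_seq(seq)
        group = reference.group_of_seq.get(seq)
        if group is not None:
            result.canonical_counts[group] += count
            continue
        if not classify or len(seq) < 18:
            result.unassigned[seq] += count
            continue
        call = classify_isomir(seq, reference, bounds)
        if call.variant_class == VARIANT_NOVEL:
            result.unassigned[seq] += count
        else:
            result.isomir_calls.append((call, count))
    return result


def quantify_libraries(
    tag_tables: Mapping[str, Mapping[str, int]],
    reference: MiRNAReference,
    bounds: EditBounds = EditBounds(),
    classify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify several libraries at once.

    Returns ``(counts, isomirs)``: a canonical-group x library raw count
    matrix (all reference groups, zero-filled), and a long-format isomiR
    table with one row per (library, tag).
    """
    counts = pd.DataFrame(
        0, index=reference.group_ids, columns=list(tag_tables), dtype=int
    )
    iso_rows = []
    for lib, tags in tag_tables.items():
        res = match_tags(tags, reference, bounds, classify=classify)
        for gid, c in res.canonical_counts.items():
            counts.loc[gid, lib] = c
        for call, c in res.isomir_calls:
            iso_rows.append(
                {
                    "library_id": lib,
                    "tag_seq": call.tag_seq,
                    "canonical_id": call.canonical_id,
                    "variant_class": call.variant_class,
                    "offset5": call.offset5,
                    "offset3": call.offset3,
                    "templated3": call.templated3,
                    "n_substitutions": len(call.substitutions),
                    "count": c,
                }
            )
    isomirs = pd.DataFrame(
        iso_rows,
        columns=[
            "library_id",
            "tag_seq",
            "canonical_id",
            "variant_class",
            "offset5",
            "offset3",
            "templated3",
            "n_substitutions",
            "count",
        ],
    )
    counts.index.name = "mirna_id"
    return counts, isomirs


def rptm_normalize(
    counts: pd.DataFrame, totals: pd.Series | None = None
) -> pd.DataFrame:
    """Reads-per-ten-million normalisation: 1e7 x count / library total.

    ``totals`` are the per-library mapped-tag totals; when omitted the
    column sums of ``counts`` are used.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = pd.Series(totals).reindex(counts.columns)
    if (totals <= 0).any() or totals.isna().any():
        bad = totals.index[(totals <= 0) | totals.isna()].tolist()
        raise ValueError(f"non-positive or missing library totals: {bad}")
    return counts * 1e7 / totals


def retention_filter(
    rptm: pd.DataFrame,
    groups: Mapping[str, str],
    min_rptm: float = 1.0,
    min_libs: int = 3,
) -> list[str]:
    """Ids with >= ``min_rptm`` in at least ``min_libs`` libraries of some
    treatment group."""
    group_labels = pd.Series({lib: groups[lib] for lib in rptm.columns})
    if not (group_labels.value_counts() >= min_libs).any():
        raise ValueError(f"no treatment group has >= {min_libs} libraries")
    keep = pd.Series(False, index=rptm.index)
    for g in group_labels.unique():
        libs = group_labels.index[group_labels == g]
        keep |= (rptm[libs] >= min_rptm).sum(axis=1) >= min_libs
    return rptm.index[keep].tolist()
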