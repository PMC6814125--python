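"""Ground-truth synthetic data for every stage of the pipeline.

The generator emulates the statistical structure the analysis assumes:
small-RNA libraries of 21–25-nt tags drawn from canonical miRNAs plus
isomiR variants, degradome 5'-end pileups peaked at the base paired to
miRNA position 10, negative-binomially dispersed count matrices over
three watering treatments (well-watered, mild and severe deficit; four
replicates each) with a spiked differentially abundant subset,
transcripts carrying planted complementary binding sites, one
cleavage-resistant target-mimic locus, and ddCt-style Ct tables.

Every sub-generator draws from its own named pseudorandom stream
derived from the single configuration seed, so adding one generator
does not perturb the others and seeded runs are bit-reproducible.
Synthetic miRNAs use invented high family numbers (zma-miR9xxx) so no
fabricated sequence is attributed to a real miRBase entry.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .degradome_targets import revcomp
from .mirna_quantify import MiRNARecord, MiRNAReference

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_reference",
    "simulate_srna_library",
    "simulate_degradome",
    "simulate_counts",
    "simulate_qpcr",
    "simulate_study",
    "write_fastq",
]

BASES = "ACGT"
DEFAULT_ADAPTER = "CTGGAGTTCAGACGTGTGCTCTTCCGATCT"
PHRED_OFFSET = 33


def stream(seed: int, name: str) -> np.random.Generator:
    """A named, independent pseudorandom stream derived from one seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Study design and noise parameters of the synthetic experiment.

    Defaults mirror the analysed design: three watering treatments
    (well-watered, −0.3 MPa mild, −1.6 MPa severe) with four biological
    replicates each, 21–25-nt miRNAs, and negative-binomial counts
    (dispersion ``phi``, i.e. BCV^2 = 0.2 -> BCV ~ 0.45, typical of
    biological replicates).
    """

    n_families: int = 20
    members_per_family: int = 2
    mirna_length_range: tuple[int, int] = (21, 24)
    n_libraries_per_group: int = 4
    groups: tuple[str, ...] = ("WW", "mild", "severe")
    isomir_rate: float = 0.15
    de_fraction: float = 0.2
    fold_changes: tuple[float, ...] = (2.0, 4.0, 8.0)
    dispersion: float = 0.2
    library_depth: int = 500_000
    depth_jitter: float = 0.2  # uniform +/- fraction around library_depth
    read_depth: int = 100_000
    seed: int = 0
    # read-level nuisance structure
    lowq_rate: float = 0.01
    short_rate: float = 0.01
    read_length: int = 40
    adapter: str = DEFAULT_ADAPTER
    # transcript/target design
    n_transcripts: int = 30
    transcript_length: int = 1500
    n_target_sites: int = 8
    target_mismatches: tuple[int, ...] = (0, 1, 2)
    mimic_insert_len: int = 3
    n_identical_families: int = 1
    n_reference_mirnas: int = 2

    def __post_init__(self):
        for name in ("isomir_rate", "de_fraction", "lowq_rate", "short_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.library_depth <= 0 or self.read_depth <= 0:
            raise ValueError("library depth must be positive")
        if not 0.0 <= self.depth_jitter < 1.0:
            raise ValueError("depth_jitter must lie in [0, 1)")
        lo, hi = self.mirna_length_range
        if not (18 <= lo <= hi <= 30):
            raise ValueError("miRNA lengths must lie within 18–30 nt")
        if self.dispersion < 0:
            raise ValueError("NB dispersion must be >= 0")
        if any(f <= 0 for f in self.fold_changes):
            raise ValueError("fold changes must be positive")
        if max(self.target_mismatches) >= lo:
            raise ValueError("site mismatches must be fewer than the miRNA length")
        if self.n_families < 2 or self.members_per_family < 1:
            raise ValueError("need >= 2 families with >= 1 member")


@dataclass
class GroundTruth:
    """Planted truth labels accompanying every emitted artifact."""

    abundances: pd.Series | None = None  # relative abundance per miRNA id
    target_sites: pd.DataFrame | None = None
    mimic: dict | None = None
    reference_mirnas: list[str] = field(default_factory=list)
    true_de: pd.DataFrame | None = None
    read_labels: dict[str, pd.DataFrame] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: Sequence[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


def make_reference(
    config: SimulationConfig,
) -> tuple[MiRNAReference, dict[str, str], GroundTruth]:
    """Build the miRNA reference, transcript set and planted truth.

    Mature miRNAs are random sequences embedded in random-flank
    hairpins; the first ``n_identical_families`` families carry an
    identical mature sequence in every member (exercising merged-ID
    counting).  Target transcripts receive the reverse complement of a
    chosen miRNA with 0–2 planted mismatches; one dedicated transcript
    carries a target-mimic region: full complementarity interrupted by a
    ``mimic_insert_len``-nt insertion opposite miRNA positions 10–11.
    """
    rng = stream(config.seed, "reference")
    records: list[MiRNARecord] = []
    letters = string.ascii_lowercase
    seen: set[str] = set()
    for fam_i in range(config.n_families):
        fam_num = 9001 + fam_i
        length = int(rng.integers(*config.mirna_length_range, endpoint=True))
        identical = fam_i < config.n_identical_families
        shared = None
        shared_arm = None
        for m in range(config.members_per_family):
            arm = rng.choice(["5p", "3p"]) if shared_arm is None else shared_arm
            if identical:
                shared_arm = arm
            if identical and shared is not None:
                mature = shared
            else:
                mature = _random_seq(rng, length)
                while mature in seen:
                    mature = _random_seq(rng, length)
            seen.add(mature)
            if identical and shared is None:
                shared = mature
            hairpin = _random_seq(rng, 15) + mature + _random_seq(rng, 50)
            records.append(
                MiRNARecord(
                    mirna_id=f"zma-miR{fam_num}{letters[m]}-{arm}",
                    mature_seq=mature,
                    hairpin_seq=hairpin,
                    family=f"miR{fam_num}",
                    arm=arm,
                )
            )
    reference = MiRNAReference(records)

    # relative abundances: log-uniform across ~3 decades
    ab = 10.0 ** rng.uniform(1.0, 4.0, size=len(records))
    abundances = pd.Series(
        ab / ab.sum(), index=[r.mirna_id for r in records], name="rel_abundance"
    )

    transcripts = {
        f"synTx{i + 1:03d}": _random_seq(rng, config.transcript_length)
        for i in range(config.n_transcripts)
    }
    tx_ids = list(transcripts)
    mimic_tx = tx_ids[-1]
    target_txs = rng.choice(
        tx_ids[:-1], size=min(config.n_target_sites, len(tx_ids) - 1), replace=False
    )
    site_mirnas = rng.choice(
        [r.mirna_id for r in records], size=len(target_txs), replace=False
    )
    site_rows = []
    for tid, mid in zip(target_txs, site_mirnas):
        mature = reference[mid].mature_seq
        L = len(mature)
        m = int(rng.choice(config.target_mismatches))
        site_seq = revcomp(mature)
        if m > 0:
            # mismatch positions in transcript frame, away from the ends
            pos = rng.choice(np.arange(1, L - 1), size=m, replace=False)
            site_seq = _mutate(rng, site_seq, pos)
        tx = transcripts[tid]
        # keep the cleavage product 5' end >= 20 nt from the 3' end
        start0 = int(rng.integers(50, len(tx) - L - 60))
        transcripts[tid] = tx[:start0] + site_seq + tx[start0 + L:]
        start, end = start0 + 1, start0 + L
        site_rows.append(
            {
                "mirna_id": mid,
                "transcript_id": tid,
                "start": start,
                "end": end,
                "mismatches": m,
                "cleavage_pos": end - 9,  # base paired to miRNA position 10
            }
        )
    target_sites = pd.DataFrame(site_rows)

    # the mimic: complementarity broken only by an insertion opposite
    # the slicing register (between the bases pairing positions 11, 10)
    mimic_mirna = str(site_mirnas[0])
    mature = reference[mimic_mirna].mature_seq
    L = len(mature)
    rc = revcomp(mature)
    while True:
        insert = _random_seq(rng, config.mimic_insert_len)
        region = rc[: L - 10] + insert + rc[L - 10:]
        # the insert must not recreate an ungapped cleavable window
        if rc not in region:
            break
    tx = transcripts[mimic_tx]
    start0 = int(rng.integers(50, len(tx) - len(region) - 60))
    transcripts[mimic_tx] = tx[:start0] + region + tx[start0 + len(region):]
    mimic = {
        "transcript_id": mimic_tx,
        "mirna_id": mimic_mirna,
        "start": start0 + 1,
        "end": start0 + len(region),
        "bulge_after": 10,
        "insert_len": config.mimic_insert_len,
    }

    ref_mirnas = [
        r.mirna_id
        for r in records[config.n_identical_families * config.members_per_family:][
            : config.n_reference_mirnas
        ]
    ]
    truth = GroundTruth(
        abundances=abundances,
        target_sites=target_sites,
        mimic=mimic,
        reference_mirnas=ref_mirnas,
    )
    return reference, transcripts, truth


def _quality_string(rng: np.random.Generator, length: int) -> list[int]:
    return list(rng.integers(30, 41, size=length))


def simulate_srna_library(
    reference: MiRNAReference,
    abundances: pd.Series,
    isomir_rate: float,
    seed: int,
    depth: int = 100_000,
    adapter: str = DEFAULT_ADAPTER,
    read_length: int = 40,
    lowq_rate: float = 0.01,
    short_rate: float = 0.01,
    library_id: str = "lib1",
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one small-RNA library with per-read truth labels.

    Reads are canonical miRNAs or isomiRs (5'/3' trims and extensions —
    templated from the hairpin or untemplated — and internal
    substitutions) followed by the 3' adapter, truncated to
    ``read_length``.  A ``lowq_rate`` fraction carries one sub-25 Phred
    score inside the first 25 bases and a ``short_rate`` fraction has a
    sub-18-nt insert; both are labelled so filters can be checked read
    by read.  Returns (records, labels): records as (id, sequence,
    quality string) FASTQ tuples.
    """
    if (abundances < 0).any():
        raise ValueError("abundances must be non-negative")
    if abundances.sum() <= 0:
        raise ValueError("abundances sum to zero")
    if len(reference) == 0:
        raise ValueError("empty reference")
    rng = stream(seed, f"srna:{library_id}")
    probs = (abundances / abundances.sum()).reindex(
        [r.mirna_id for r in reference]
    ).fillna(0.0)
    n_per_mirna = rng.multinomial(depth, probs.to_numpy())
    canonical_seqs = {r.mirna_id for r in reference}

    records, labels = [], []
    read_i = 0
    for record, n_reads in zip(reference, n_per_mirna):
        for _ in range(n_reads):
            read_i += 1
            rid = f"{library_id}:read{read_i}"
            fate = "ok"
            u = rng.random()
            if u < short_rate:
                fate = "short"
            elif u < short_rate + lowq_rate:
                fate = "lowq"
            insert, variant_class, off5, off3 = _draw_insert(
                rng, record, reference, isomir_rate, canonical_seqs
            )
            if fate == "short":
                insert = insert[: int(rng.integers(12, 18))]
                variant_class, off5, off3 = "short", 0, 0
            seq = (insert + adapter)[:read_length]
            qual = _quality_string(rng, len(seq))
            if fate == "lowq":
                qual[int(rng.integers(0, min(25, len(seq))))] = 24
            records.append(
                (rid, seq, "".join(chr(q + PHRED_OFFSET) for q in qual))
            )
            labels.append(
                {
                    "read_id": rid,
                    "canonical_id": record.mirna_id,
                    "variant_class": variant_class,
                    "offset5": off5,
                    "offset3": off3,
                    "insert_seq": insert,
                    "fate": fate,
                }
            )
    return records, pd.DataFrame(labels)


def _draw_insert(
    rng: np.random.Generator,
    record: MiRNARecord,
    reference: MiRNAReference,
    isomir_rate: float,
    canonical_seqs,
) -> tuple[str, str, int, int]:
    """One insert: the canonical mature sequence or a planted isomiR."""
    mature = record.mature_seq
    if rng.random() >= isomir_rate:
        return mature, "canonical", 0, 0
    hairpin = record.hairpin_seq
    h = record.hairpin_offset
    L = len(mature)
    for _ in range(20):  # retry until the variant is clean
        kind = rng.choice(["5p-variant", "3p-variant", "5p3p-variant",
                           "internal-variant"])
        off5 = off3 = 0
        if kind in ("5p-variant", "5p3p-variant"):
            off5 = int(rng.choice([-2, -1, 1, 2]))
        if kind in ("3p-variant", "5p3p-variant"):
            off3 = int(rng.choice([-3, -2, -1, 1, 2, 3]))
        if L - off5 + off3 < 18:
            continue
        seq = list(mature)
        if kind == "internal-variant":
            n_subs = int(rng.integers(1, 3))
            pos = rng.choice(np.arange(3, L - 3), size=n_subs, replace=False)
            seq = list(_mutate(rng, mature, pos))
        else:
            if off5 > 0:
                seq = seq[off5:]
            elif off5 < 0:
                ext = []
                for k in range(1, -off5 + 1):
                    c = h - k
                    templated = rng.random() < 0.5 and c >= 0
                    if templated:
                        ext.append(hairpin[c])
                    else:
                        base = hairpin[c] if c >= 0 else None
                        ext.append(
                            rng.choice([b for b in BASES if b != base])
                        )
                seq = ext[::-1] + seq
            if off3 < 0:
                seq = seq[:off3]
            elif off3 > 0:
                for k in range(off3):
                    c = h + L + k
                    templated = rng.random() < 0.5 and c < len(hairpin)
                    if templated:
                        seq.append(hairpin[c])
                    else:
                        base = hairpin[c] if c < len(hairpin) else None
                        seq.append(rng.choice([b for b in BASES if b != base]))
        out = "".join(seq)
        # an isomiR colliding with a canonical sequence would be
        # (correctly) counted as canonical; avoid planting those
        if out in canonical_seqs or out == mature:
            continue
        return out, kind, off5, off3
    return mature, "canonical", 0, 0


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_degradome(
    transcripts: Mapping[str, str],
    truth: GroundTruth,
    peak_fraction: float = 0.8,
    noise_rate: float = 0.01,
    seed: int = 0,
    reads_per_site: int = 50,
    read_length: int = 36,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Degradome tag table and FASTQ with truth-linked cleavage peaks.

    For each planted site, each of ``reads_per_site`` tag 5' ends falls
    on the transcript base paired to miRNA position 10 with probability
    ``peak_fraction``, otherwise uniformly along the transcript; every
    transcript additionally receives Poisson(``noise_rate`` x
    ``reads_per_site``) uniform background tags.  Returns the pre-mapped
    tag table (transcript_id, position, count) and 4-line FASTQ records
    whose first 20 nt are the tag.
    """
    if not 0.0 <= peak_fraction <= 1.0:
        raise ValueError("peak_fraction outside [0, 1]")
    rng = stream(seed, "degradome")
    counts: dict[tuple[str, int], int] = {}

    def add(tid: str, pos: int, n: int = 1) -> None:
        counts[(tid, pos)] = counts.get((tid, pos), 0) + n

    sites = truth.target_sites if truth.target_sites is not None else pd.DataFrame()
    for row in sites.itertuples(index=False):
        tx_len = len(transcripts[row.transcript_id])
        max_pos = tx_len - 19  # need a 20-nt tag downstream
        n_peak = rng.binomial(reads_per_site, peak_fraction)
        if n_peak:
            add(row.transcript_id, int(row.cleavage_pos), int(n_peak))
        for _ in range(reads_per_site - n_peak):
            add(row.transcript_id, int(rng.integers(1, max_pos + 1)))
    for tid, seq in transcripts.items():
        n_bg = rng.poisson(noise_rate * reads_per_site)
        max_pos = len(seq) - 19
        for _ in range(n_bg):
            add(tid, int(rng.integers(1, max_pos + 1)))

    table = pd.DataFrame(
        [
            {"transcript_id": tid, "position": pos, "count": n}
            for (tid, pos), n in sorted(counts.items())
        ],
        columns=["transcript_id", "position", "count"],
    )
    records = []
    i = 0
    for row in table.itertuples(index=False):
        seq = transcripts[row.transcript_id][
            row.position - 1: row.position - 1 + read_length
        ]
        for _ in range(row.count):
            i += 1
            qual = "".join(
                chr(q + PHRED_OFFSET) for q in _quality_string(rng, len(seq))
            )
            records.append((f"deg:read{i}", seq, qual))
    return table, records


def simulate_counts(
    config: SimulationConfig,
    reference: MiRNAReference | None = None,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """NB-dispersed miRNA count matrix with a spiked DE subset.

    Counts are drawn per library as NB(mean = depth x relative
    abundance x group effect, dispersion phi) via the gamma–Poisson
    mixture (phi = 0 gives Poisson).  A ``de_fraction`` subset of
    miRNAs receives a fold change from ``fold_changes`` with random
    sign under severe stress only, both stresses, or mild only
    (probability 0.6/0.3/0.1, echoing the predominance of severe-stress
    responses); designated qPCR reference miRNAs always have zero group
    effect.  Returns (counts, library->group mapping, truth table with
    per-contrast log2 effects).
    """
    rng = stream(config.seed, "counts")
    if reference is not None:
        ids = reference.group_ids
        if truth is not None and truth.abundances is not None:
            grouped = truth.abundances.copy()
            grouped.index = [reference.group_for(i) for i in grouped.index]
            base = grouped.groupby(level=0).max().reindex(ids).fillna(0.0)
        else:
            ab = 10.0 ** rng.uniform(1.0, 4.0, size=len(ids))
            base = pd.Series(ab, index=ids)
        ref_groups = (
            [reference.group_for(i) for i in truth.reference_mirnas]
            if truth is not None
            else []
        )
    else:
        ids = [f"zma-miR{9001 + i}-5p" for i in range(config.n_families * 4)]
        ab = 10.0 ** rng.uniform(1.0, 4.0, size=len(ids))
        base = pd.Series(ab, index=ids)
        ref_groups = ids[: config.n_reference_mirnas]
    base = base / base.sum()

    eligible = [i for i in ids if i not in ref_groups]
    n_de = int(round(config.de_fraction * len(eligible)))
    de_ids = list(rng.choice(eligible, size=n_de, replace=False))
    effects = pd.DataFrame(0.0, index=ids, columns=["mild", "severe"])
    patterns = {}
    for i in de_ids:
        fold = float(rng.choice(config.fold_changes))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        pattern = rng.choice(["severe_only", "both", "mild_only"], p=[0.6, 0.3, 0.1])
        patterns[i] = pattern
        lfc = sign * np.log2(fold)
        if pattern in ("both", "mild_only"):
            effects.loc[i, "mild"] = lfc
        if pattern in ("both", "severe_only"):
            effects.loc[i, "severe"] = lfc

    libs, groups = [], {}
    counts = {}
    for g in config.groups:
        eff = 2.0 ** effects[g] if g in effects.columns else pd.Series(1.0, index=ids)
        for r in range(config.n_libraries_per_group):
            lib = f"{g}R{r + 1}"
            libs.append(lib)
            groups[lib] = g
            depth = config.library_depth * rng.uniform(
                1.0 - config.depth_jitter, 1.0 + config.depth_jitter
            )
            mu = depth * base * eff
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                lam = rng.gamma(shape, mu * config.dispersion)
            else:
                lam = mu
            counts[lib] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=ids)[libs]
    counts_df.index.name = "mirna_id"
    true_de = pd.DataFrame(
        {
            "mirna_id": ids,
            "is_de": [i in patterns for i in ids],
            "pattern": [patterns.get(i, "none") for i in ids],
            "log2_effect_mild": effects["mild"].to_numpy(),
            "log2_effect_severe": effects["severe"].to_numpy(),
            "is_reference": [i in ref_groups for i in ids],
        }
    ).set_index("mirna_id")
    return counts_df, groups, true_de


def simulate_spike_benchmark(
    seed: int,
    n_features: int = 2000,
    n_de: int = 100,
    fold: float = 8.0,
    de_mean: float = 200.0,
    dispersion: float = 0.2,
    n_per_group: int = 4,
) -> tuple[pd.DataFrame, dict[str, str], np.ndarray, np.ndarray]:
    """Two-group NB benchmark with spiked fold changes at a fixed mean.

    Background features draw means log-uniformly over 10..1000; the
    ``n_de`` spiked features sit at ``de_mean`` in the control group and
    ``de_mean`` x ``fold``^(+/-1) in the treatment group (random sign).
    With ``n_de=0`` this is a pure null for error-rate calibration.
    Returns (counts, groups, is_de mask, true sign of the log2 effect).
    """
    rng = stream(seed, "spike-benchmark")
    mu = 10.0 ** rng.uniform(1.0, 3.0, n_features)
    is_de = np.zeros(n_features, dtype=bool)
    sign = np.zeros(n_features)
    mu_a, mu_b = mu.copy(), mu.copy()
    if n_de > 0:
        de_idx = rng.choice(n_features, n_de, replace=False)
        is_de[de_idx] = True
        up = rng.random(n_de) < 0.5
        sign[de_idx] = np.where(up, 1.0, -1.0)
        mu_a[de_idx] = de_mean
        mu_b[de_idx] = de_mean * np.where(up, fold, 1.0 / fold)

    def draw(mus: np.ndarray) -> np.ndarray:
        m = np.outer(mus, np.ones(n_per_group))
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, m * dispersion)
        else:
            lam = m
        return rng.poisson(lam)

    libs = [f"A{r + 1}" for r in range(n_per_group)] + [
        f"B{r + 1}" for r in range(n_per_group)
    ]
    counts = pd.DataFrame(
        np.hstack([draw(mu_a), draw(mu_b)]),
        index=[f"feat{i}" for i in range(n_features)],
        columns=libs,
    )
    groups = {lib: lib[0] for lib in libs}
    return counts, groups, is_de, sign


def simulate_qpcr(
    true_de: pd.DataFrame,
    abundances: pd.Series,
    seed: int = 0,
    targets: Sequence[str] | None = None,
    treatments: Sequence[str] = ("WW", "mild", "severe"),
    n_bio: int = 4,
    n_tech: int = 3,
    sigma_bio: float = 0.15,
    sigma_tech: float = 0.1,
    intercept: float = 35.0,
) -> pd.DataFrame:
    """Stem-loop RT-qPCR Ct table consistent with the planted effects.

    Ct = intercept − log2(10^6 x relative abundance x group effect) +
    biological + technical Gaussian noise, so a doubling of abundance
    lowers Ct by one cycle.
    """
    rng = stream(seed, "qpcr")
    if targets is None:
        targets = true_de.index.tolist()
    rows = []
    for target in targets:
        base = np.log2(max(abundances.get(target, 1e-6), 1e-12) * 1e6)
        for treatment in treatments:
            lfc = 0.0
            if treatment != treatments[0] and target in true_de.index:
                col = f"log2_effect_{treatment}"
                if col in true_de.columns:
                    lfc = float(true_de.loc[target, col])
            for b in range(1, n_bio + 1):
                bio_noise = rng.normal(0.0, sigma_bio)
                for t in range(1, n_tech + 1):
                    ct = (
                        intercept
                        - (base + lfc)
                        + bio_noise
                        + rng.normal(0.0, sigma_tech)
                    )
                    rows.append(
                        {
                            "target_id": target,
                            "treatment": treatment,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct": float(ct),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_study(
    config: SimulationConfig, outdir: str | Path | None = None
) -> dict:
    """Generate every input the pipeline consumes, optionally on disk.

    Returns a dict with the reference, transcripts, one read-level
    small-RNA library ("WWR1"), the degradome tag table and reads, the
    count matrix with group labels, the qPCR Ct table, and the combined
    ground truth.  With ``outdir`` set, the artifacts are written as
    FASTA/FASTQ/TSV files.
    """
    reference, transcripts, truth = make_reference(config)
    srna_records, read_labels = simulate_srna_library(
        reference,
        truth.abundances,
        config.isomir_rate,
        seed=config.seed,
        depth=config.read_depth,
        adapter=config.adapter,
        read_length=config.read_length,
        lowq_rate=config.lowq_rate,
        short_rate=config.short_rate,
        library_id="WWR1",
    )
    truth.read_labels["WWR1"] = read_labels
    deg_table, deg_records = simulate_degradome(
        transcripts, truth, seed=config.seed
    )
    counts, groups, true_de = simulate_counts(config, reference, truth)
    truth.true_de = true_de
    group_abund = truth.abundances.copy()
    group_abund.index = [reference.group_for(i) for i in group_abund.index]
    group_abund = group_abund.groupby(level=0).max()
    ct_table = simulate_qpcr(true_de, group_abund, seed=config.seed)
    result = {
        "reference": reference,
        "transcripts": transcripts,
        "srna_records": srna_records,
        "degradome_table": deg_table,
        "degradome_records": deg_records,
        "counts": counts,
        "groups": groups,
        "ct_table": ct_table,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        reference.to_fasta(outdir / "mature.fa", outdir / "hairpin.fa")
        SeqIO.write(
            [SeqRecord(Seq(s), id=t, description="") for t, s in transcripts.items()],
            str(outdir / "transcripts.fa"),
            "fasta",
        )
        write_fastq(srna_records, outdir / "srna_WWR1.fastq")
        write_fastq(deg_records, outdir / "degradome.fastq")
        deg_table.to_csv(outdir / "degradome_tags.tsv", sep="\t", index=False)
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        pd.Series(groups, name="group").rename_axis("library_id").to_csv(
            outdir / "groups.tsv", sep="\t"
        )
        ct_table.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
        read_labels.to_csv(outdir / "truth_reads_WWR1.tsv", sep="\t", index=False)
        truth.target_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
        true_de.to_csv(outdir / "truth_de.tsv", sep="\t")
        pd.DataFrame([truth.mimic]).to_csv(
            outdir / "truth_mimic.tsv", sep="\t", index=False
        )
    return result
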