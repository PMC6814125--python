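"""Generator contracts: seeded determinism, truth/file consistency and
the negative-binomial moment structure of simulated counts."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO

from rootmir import (
    MiRNAReference,
    SimulationConfig,
    find_sites,
    make_reference,
    simulate_counts,
    simulate_study,
)
from rootmir.degradome_targets import revcomp
from rootmir.synthetic_data import simulate_spike_benchmark, stream


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(isomir_rate=1.5)

    def test_depth_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(library_depth=0)

    def test_length_window(self):
        with pytest.raises(ValueError):
            SimulationConfig(mirna_length_range=(15, 24))

    def test_impossible_mismatches_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_mismatches=(25,), mirna_length_range=(21, 24))

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(dispersion=-0.1)


class TestDeterminism:
    def test_study_outputs_byte_identical(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_families=4, n_transcripts=8,
                               transcript_length=600, n_target_sites=3,
                               read_depth=2000)
        simulate_study(cfg, outdir=tmp_path / "a")
        simulate_study(cfg, outdir=tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            assert filecmp.cmp(
                tmp_path / "a" / name, tmp_path / "b" / name, shallow=False
            ), name

    def test_named_streams_independent(self):
        a1 = stream(3, "alpha").random(5)
        b = stream(3, "beta").random(5)
        a2 = stream(3, "alpha").random(5)
        assert np.allclose(a1, a2)
        assert not np.allclose(a1, b)


class TestReferenceConstruction:
    def test_mature_within_hairpin(self, reference_bundle):
        reference, _, _ = reference_bundle
        for rec in reference:
            assert rec.mature_seq in rec.hairpin_seq

    def test_planted_sites_found_by_bruteforce(self, reference_bundle):
        reference, transcripts, truth = reference_bundle
        for row in truth.target_sites.itertuples():
            mature = reference[row.mirna_id].mature_seq
            sites = find_sites(mature, transcripts[row.transcript_id])
            match = [s for s in sites if s.start == row.start]
            assert match and match[0].mismatch_count == row.mismatches

    def test_mimic_region_structure(self, reference_bundle):
        reference, transcripts, truth = reference_bundle
        m = truth.mimic
        mature = reference[m["mirna_id"]].mature_seq
        region = transcripts[m["transcript_id"]][m["start"] - 1: m["end"]]
        rc = revcomp(mature)
        L = len(mature)
        assert len(region) == L + m["insert_len"]
        assert region[: L - 10] == rc[: L - 10]
        assert region[L - 10 + m["insert_len"]:] == rc[L - 10:]

    def test_mismatch_budget_respected(self, reference_bundle):
        _, _, truth = reference_bundle
        assert (truth.target_sites.mismatches < 4).all()


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory):
    cfg = SimulationConfig(seed=11, n_families=5, n_transcripts=8,
                           transcript_length=600, n_target_sites=3,
                           read_depth=3000)
    out = tmp_path_factory.mktemp("study")
    simulate_study(cfg, outdir=out)
    return out


class TestEmittedFilesConsistent:
    def test_truth_reads_exist_in_fastq(self, study_dir):
        labels = pd.read_csv(study_dir / "truth_reads_WWR1.tsv", sep="\t")
        ids = set()
        with open(study_dir / "srna_WWR1.fastq") as fh:
            for i, line in enumerate(fh):
                if i % 4 == 0:
                    ids.add(line[1:].strip())
        assert set(labels.read_id) == ids

    def test_truth_sites_exist_in_transcripts(self, study_dir):
        sites = pd.read_csv(study_dir / "truth_sites.tsv", sep="\t")
        mature = {r.id: str(r.seq) for r in SeqIO.parse(str(study_dir / "mature.fa"), "fasta")}
        txs = {r.id: str(r.seq) for r in SeqIO.parse(str(study_dir / "transcripts.fa"), "fasta")}
        for row in sites.itertuples():
            window = txs[row.transcript_id][row.start - 1: row.end]
            rc = revcomp(mature[row.mirna_id])
            diffs = sum(a != b for a, b in zip(window, rc))
            assert diffs == row.mismatches

    def test_counts_match_truth_universe(self, study_dir):
        counts = pd.read_csv(study_dir / "counts.tsv", sep="\t", index_col=0)
        truth_de = pd.read_csv(study_dir / "truth_de.tsv", sep="\t", index_col=0)
        assert list(counts.index) == list(truth_de.index)
        groups = pd.read_csv(study_dir / "groups.tsv", sep="\t", index_col=0)
        assert set(groups["group"]) == {"WW", "mild", "severe"}
        assert (groups.groupby("group").size() == 4).all()


class TestCountMoments:
    def test_nb_moments_match(self):
        """Across 1000 simulated replicate libraries the empirical
        mean/variance of a feature follow var = mu + phi mu^2."""
        rng = stream(123, "moments")
        phi, mu = 0.2, 400.0
        draws = rng.poisson(rng.gamma(1 / phi, mu * phi, size=1000))
        assert np.mean(draws) == pytest.approx(mu, rel=0.05)
        assert np.var(draws) == pytest.approx(mu + phi * mu ** 2, rel=0.2)

    def test_poisson_limit(self):
        cfg = SimulationConfig(seed=5, dispersion=0.0, library_depth=50_000,
                               depth_jitter=0.0)
        counts, groups, _ = simulate_counts(cfg)
        libs = [c for c in counts.columns if groups[c] == "WW"]
        sub = counts[libs]
        means = sub.mean(axis=1)
        ratio = (sub.var(axis=1) / means)[means > 100]
        # variance/mean ~ 1 under Poisson sampling
        assert 0.5 < ratio.median() < 2.0

    def test_reference_mirnas_have_zero_effect(self):
        cfg = SimulationConfig(seed=5)
        _, _, truth_de = simulate_counts(cfg)
        refs = truth_de[truth_de.is_reference]
        assert len(refs) == cfg.n_reference_mirnas
        assert (refs.log2_effect_mild == 0).all()
        assert (refs.log2_effect_severe == 0).all()

    def test_zero_de_fraction_plants_nothing(self):
        cfg = SimulationConfig(seed=5, de_fraction=0.0)
        _, _, truth_de = simulate_counts(cfg)
        assert not truth_de.is_de.any()

    def test_spike_benchmark_null_has_no_de(self):
        counts, groups, is_de, sign = simulate_spike_benchmark(1, n_de=0)
        assert not is_de.any() and (sign == 0).all()
        assert counts.shape == (2000, 8)


def test_isomir_rate_zero_gives_only_canonical(reference_bundle):
    from rootmir import simulate_srna_library

    reference, _, truth = reference_bundle
    canon = {r.mature_seq for r in reference}
    _, labels = simulate_srna_library(
        reference, truth.abundances, isomir_rate=0.0, seed=9, depth=3000,
        lowq_rate=0.0, short_rate=0.0,
    )
    assert (labels.variant_class == "canonical").all()
    assert set(labels.insert_seq) <= canon


def test_expected_rptm_of_rare_mirna(reference_bundle):
    """A miRNA at relative abundance 5e-4 in a 100k-read library has
    expected RPTM 5000 within binomial sampling error."""
    from collections import Counter

    from rootmir import simulate_srna_library
    from rootmir.mirna_quantify import rptm_normalize
    import pandas as pd

    reference, _, _ = reference_bundle
    ids = [r.mirna_id for r in reference]
    abund = pd.Series(0.0, index=ids)
    abund.iloc[0] = 5e-4
    abund.iloc[1:] = (1 - 5e-4) / (len(ids) - 1)
    _, labels = simulate_srna_library(
        reference, abund, isomir_rate=0.0, seed=21, depth=100_000,
        lowq_rate=0.0, short_rate=0.0,
    )
    n = (labels.canonical_id == ids[0]).sum()
    counts = pd.DataFrame({"L1": [n]}, index=[ids[0]])
    rptm = rptm_normalize(counts, pd.Series({"L1": 100_000}))
    # binomial sd ~ sqrt(50) reads -> ~700 RPTM at this depth
    assert abs(rptm.iloc[0, 0] - 5000) < 2500


def test_peak_fraction_one_concentrates_tags(reference_bundle):
    from rootmir import simulate_degradome

    reference, transcripts, truth = reference_bundle
    table, _ = simulate_degradome(
        transcripts, truth, peak_fraction=1.0, noise_rate=0.0, seed=4
    )
    expected = {
        (r.transcript_id, r.cleavage_pos)
        for r in truth.target_sites.itertuples()
    }
    assert set(zip(table.transcript_id, table.position)) == expected
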