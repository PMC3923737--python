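import numpy as np
import pytest
from scipy import stats

from seedmir._seq import gc_percent, revcomp
from seedmir.synthetic import (SynthConfig, build_world, generate_hairpin,
                               generate_mrna_libraries, generate_srna_library,
                               simulate)


class TestGenerateHairpin:
    def test_mature_spans_inside_arms(self, rng):
        for _ in range(50):
            seq, m5, m3, loop = generate_hairpin(rng, 100, 0.5, 21)
            arm = loop[0]
            assert 0 <= m5[0] < m5[1] <= arm        # inside the 5p arm
            assert loop[1] <= m3[0] < m3[1] <= 100  # inside the 3p arm
            assert m5[1] - m5[0] == 21

    def test_zero_mismatch_gives_palindrome(self, rng):
        seq, m5, m3, loop = generate_hairpin(rng, 120, 0.45, 21,
                                             mismatch_rate=0.0)
        arm = loop[0]
        assert seq[loop[1]:] == revcomp(seq[:arm])

    def test_gc_law_of_large_numbers(self, rng):
        gcs = [gc_percent(generate_hairpin(rng, 150, 0.45, 21)[0]) / 100
               for _ in range(1000)]
        assert abs(np.mean(gcs) - 0.45) <= 0.01

    def test_requested_gc_within_tolerance(self, rng):
        for _ in range(30):
            seq, *_ = generate_hairpin(rng, 200, 0.42, 22)
            assert abs(gc_percent(seq) / 100 - 0.42) <= 0.05

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_hairpin(rng, 49, 0.5, 21)


class TestConfigValidation:
    def test_rate_sum_above_one_rejected(self):
        cfg = SynthConfig(degradation_rate=0.5,
                          ncrna_class_rates={"rRNA": 0.6})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_unordered_range_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(precursor_len_range=(250, 70)).validate()

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(low_quality_rate=1.5).validate()


class TestSrnaLibrary:
    def test_read_count_equals_label_count(self, study):
        assert len(study.reads) == len(study.truth.read_labels)
        assert sum(study.truth.class_counts.values()) == len(study.reads)

    def test_pure_precursor_library(self):
        cfg = SynthConfig(seed=3, n_precursors=5, n_sirna_loci=0,
                          degradation_rate=0.0,
                          ncrna_class_rates={c: 0.0 for c in
                                             ("rRNA", "tRNA", "snRNA",
                                              "snoRNA", "cpRNA", "mtRNA")})
        world = build_world(cfg)
        _, truth = generate_srna_library(world)
        assert all(lab.startswith("mirna:") for _, lab, _ in truth.read_labels)

    def test_rrna_fraction_within_3sd(self):
        # ~100k reads so the binomial check is sharp
        cfg = SynthConfig(seed=0, n_precursors=40,
                          reads_per_precursor_range=(500, 5000))
        world = build_world(cfg)
        reads, truth = generate_srna_library(world)
        n = len(reads)
        rate = cfg.ncrna_class_rates["rRNA"]
        sd = np.sqrt(rate * (1 - rate) / n)
        assert n >= 80_000
        assert abs(truth.class_counts.get("rRNA", 0) / n - rate) <= 3 * sd

    def test_isomir_reads_stay_inside_precursor(self, study):
        label = {rid: lab for rid, lab, _ in study.truth.read_labels}
        pre = {p.id: p for p in study.truth.precursors}
        adapter = study.cfg.adapter_3p.replace("T", "U")
        for r in study.reads[:400]:
            lab = label[r.id]
            if not lab.startswith("mirna:"):
                continue
            insert = r.sequence[:-len(adapter)].replace("N", "")
            p = pre[lab.split(":")[1]]
            if "N" not in r.sequence:
                assert insert in p.sequence


class TestReproducibility:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg1 = SynthConfig(seed=77, n_precursors=6, n_targets=3, n_sirna_loci=1)
        cfg2 = SynthConfig(seed=77, n_precursors=6, n_targets=3, n_sirna_loci=1)
        simulate(cfg1, tmp_path / "a")
        simulate(cfg2, tmp_path / "b")
        for name in ("srna_reads.fastq", "contigs.fasta", "mature_ref.fasta",
                     "mrna_L2.fasta", "truth_precursors.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_different_seed_differs(self, tmp_path):
        simulate(SynthConfig(seed=1, n_precursors=6, n_targets=3,
                             n_sirna_loci=1), tmp_path / "a")
        simulate(SynthConfig(seed=2, n_precursors=6, n_targets=3,
                             n_sirna_loci=1), tmp_path / "b")
        assert (tmp_path / "a" / "srna_reads.fastq").read_bytes() != \
               (tmp_path / "b" / "srna_reads.fastq").read_bytes()


class TestMrnaLibraries:
    def test_flat_fold_gives_scaled_depths(self):
        cfg = SynthConfig(seed=9, n_precursors=4, n_targets=2,
                          differential_fraction=0.0)
        world = build_world(cfg)
        ab = world.abundance
        for fid in ab.index:
            base = ab.loc[fid, "L1"] / cfg.mrna_depth_factors[0]
            expected = [base * f for f in cfg.mrna_depth_factors]
            assert np.allclose(ab.loc[fid].values, expected)

    def test_depth_linearity(self):
        cfg1 = SynthConfig(seed=9, n_precursors=4, n_targets=2,
                           differential_fraction=0.0)
        cfg2 = SynthConfig(seed=9, n_precursors=4, n_targets=2,
                           differential_fraction=0.0,
                           mrna_depth_factors=(2.0, 1.7, 1.4))
        ab1 = build_world(cfg1).abundance
        ab2 = build_world(cfg2).abundance
        assert np.allclose(ab2.values, 2 * ab1.values)

    def test_poisson_goodness_of_fit(self):
        """Simulated per-feature counts are consistent with their Poisson
        expectations (chi-square over 200 features, alpha = 0.01)."""
        from collections import Counter

        cfg = SynthConfig(seed=13, n_precursors=100, n_targets=100,
                          mrna_base_abundance=80.0)
        world = build_world(cfg)
        libs = generate_mrna_libraries(world)
        chi2, df = 0.0, 0
        for stage, lib in libs.items():
            got = Counter(rid.split("|")[1] for rid, _ in lib)
            for fid, expected in world.abundance[stage].items():
                if expected >= 10 and df < 200:
                    chi2 += (got.get(fid, 0) - expected) ** 2 / expected
                    df += 1
        p = stats.chi2.sf(chi2, df)
        assert p > 0.01
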