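import numpy as np
import pytest
from scipy import stats as sps

from exsmallrna.profiles import (
    BiofluidProfile,
    get_profile,
    plasma_profile,
    saliva_profile,
    urine_profile,
)
from exsmallrna.simulate import (
    CohortConfig,
    build_synthetic_references,
    build_synthetic_species,
    simulate_cohort,
    simulate_cohort_counts,
    simulate_sample,
)


class TestReferences:
    def test_fixed_seed_byte_identical(self, tmp_path):
        from exsmallrna.references import write_reference_bundle

        a, b = tmp_path / "a", tmp_path / "b"
        write_reference_bundle(build_synthetic_references(seed=3).bundle, a)
        write_reference_bundle(build_synthetic_references(seed=3).bundle, b)
        for name in ("references.fasta", "annotation.tsv", "genome.fasta"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_all_mature_trnas_end_cca(self, refs):
        for rec in refs.bundle.by_biotype("tRNA"):
            assert rec.sequence.endswith("CCA")

    def test_planted_pirna_is_gly_trna_prefix(self, refs):
        gly = [r for r in refs.bundle.by_biotype("tRNA") if r.family == "GlyGCC"]
        planted = refs.bundle["piR-syn-1"]
        assert any(r.sequence.startswith(planted.sequence) for r in gly)

    def test_records_embedded_in_genome(self, refs):
        chrom = refs.bundle.genome["chr1"]
        for rec in refs.bundle.records:
            assert rec.sequence in chrom

    def test_isodecoders_share_five_prime_end(self, refs):
        fams = refs.trna_families()
        for fam, recs in fams.items():
            if len(recs) > 1:
                prefixes = {r.sequence[:40] for r in recs}
                assert len(prefixes) == 1, fam

    def test_zero_trna_with_fragments_rejected(self):
        with pytest.raises(ValueError, match="fragment simulation"):
            build_synthetic_references(n_per_biotype={"tRNA": 0})


class TestProfiles:
    @pytest.mark.parametrize("fluid", ["plasma", "urine", "saliva"])
    def test_defaults_validate(self, fluid):
        get_profile(fluid).validate()

    def test_unknown_fluid(self):
        with pytest.raises(ValueError):
            get_profile("sweat")

    def test_yaml_round_trip(self, tmp_path):
        p = urine_profile()
        p.to_yaml(tmp_path / "p.yaml")
        q = BiofluidProfile.from_yaml(tmp_path / "p.yaml")
        assert q == p

    def test_bad_proportions_rejected(self):
        p = urine_profile()
        p.biotype_proportions["tRNA"] += 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            p.validate()

    def test_urine_rny4_5p_joint_share_is_97_percent(self):
        p = urine_profile()
        joint = p.parent_weights["RNY4"] * p.end_class_proportions["YRNA"]["F5"]
        assert joint == pytest.approx(0.97, abs=1e-9)


class TestSimulateSample:
    def test_fixed_seed_byte_identical(self, refs, tmp_path):
        a = simulate_sample(urine_profile(), refs, 500, seed=11, sample_id="x")
        b = simulate_sample(urine_profile(), refs, 500, seed=11, sample_id="x")
        fa, ta = a.write(tmp_path / "a")
        fb, tb = b.write(tmp_path / "b")
        import gzip

        assert gzip.open(fa).read() == gzip.open(fb).read()
        assert ta.read_bytes() == tb.read_bytes()

    def test_truth_conservation(self, refs):
        sample = simulate_sample(plasma_profile(), refs, 777, seed=2)
        assert len(sample.truth) == len(sample.reads) == 777

    def test_degenerate_all_too_short(self, refs):
        p = urine_profile()
        p.too_short_fraction = 1.0
        p.rrna_fraction = 0.0
        p.exogenous_fraction = 0.0
        sample = simulate_sample(p, refs, 200, seed=1)
        assert (sample.truth["category"] == "too_short").all()

    def test_all_f5_trfs_are_mature_prefixes(self, refs):
        p = urine_profile()
        p.end_class_proportions["tRNA"] = {"F5": 1.0, "F3": 0.0, "FM": 0.0}
        sample = simulate_sample(p, refs, 2000, seed=4)
        trna = sample.truth[sample.truth["category"] == "tRNA"]
        for row in trna.itertuples():
            parent = refs.bundle[row.record_id].sequence
            insert = sample.reads[int(row.read_id.split(":")[1])].sequence[: row.insert_length]
            assert parent.startswith(insert)

    def test_trna_fraction_within_3sd_of_binomial(self, refs):
        p = urine_profile()
        n = 30_000
        sample = simulate_sample(p, refs, n, seed=7)
        expected = (
            1 - p.too_short_fraction - p.rrna_fraction - p.exogenous_fraction
        ) * p.biotype_proportions["tRNA"]
        observed = (sample.truth["category"] == "tRNA").sum()
        sd = np.sqrt(n * expected * (1 - expected))
        assert abs(observed - n * expected) < 3 * sd

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_category_proportions_multinomial_consistent(self, refs, seed):
        """Chi-square goodness of fit of truth categories vs the profile."""
        p = saliva_profile()
        species, _, _ = build_synthetic_species(seed=5)
        n = 20_000
        sample = simulate_sample(p, refs, n, seed=seed, species=species)
        genome_mass = 1 - p.too_short_fraction - p.rrna_fraction - p.exogenous_fraction
        expected = {
            "too_short": p.too_short_fraction,
            "rRNA": p.rrna_fraction,
            "exogenous": p.exogenous_fraction,
        }
        expected.update(
            {bt: genome_mass * w for bt, w in p.biotype_proportions.items() if w > 0}
        )
        observed = sample.truth["category"].value_counts()
        cats = sorted(expected)
        chi2 = sps.chisquare(
            [observed.get(c, 0) for c in cats], [n * expected[c] for c in cats]
        )
        assert chi2.pvalue > 0.001

    def test_insert_longer_than_read_rejected(self, refs):
        p = urine_profile()
        p.length_distribution["tRNA"] = {45: 1.0}
        with pytest.raises(ValueError, match="exceeds read length"):
            simulate_sample(p, refs, 50, seed=1, read_length=40)

    def test_unknown_family_rejected(self, refs):
        p = urine_profile()
        p.family_weights = {"NoSuchFam": 1.0}
        with pytest.raises(ValueError, match="not present"):
            simulate_sample(p, refs, 10, seed=1)

    def test_low_quality_tail_exercises_trimming(self, refs):
        from exsmallrna.preprocess import quality_trim_3prime

        sample = simulate_sample(urine_profile(), refs, 20, seed=1, low_quality_tail=5)
        trimmed = quality_trim_3prime(sample.reads[0])
        assert len(trimmed) == len(sample.reads[0]) - 5


class TestCohort:
    def _cfg(self, **kw):
        base = dict(
            n_subjects=5, samples_per_subject=6, fluid="plasma",
            inter_subject_sd=0.5, intra_subject_sd=0.05,
            reads_per_sample=500, seed=13,
        )
        base.update(kw)
        return CohortConfig(**base)

    def test_sample_sheet_shape(self, refs):
        cohort = simulate_cohort(self._cfg(), plasma_profile(), refs)
        assert len(cohort.sample_sheet) == 30
        assert cohort.sample_sheet["subject_id"].nunique() == 5
        assert len(cohort.samples) == 30

    def test_zero_intra_sd_fixes_subject_weights(self, refs):
        cohort = simulate_cohort(self._cfg(intra_subject_sd=0.0, n_subjects=2,
                                           samples_per_subject=3), plasma_profile(), refs)
        w = cohort.expected_weights
        sheet = cohort.sample_sheet
        for subject, group in sheet.groupby("subject_id"):
            cols = list(group["sample_id"])
            for col in cols[1:]:
                assert np.allclose(w[col], w[cols[0]])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            self._cfg(samples_per_subject=0).validate()
        with pytest.raises(ValueError):
            self._cfg(inter_subject_sd=-1).validate()

    def test_counts_fast_path_deterministic(self):
        m1, sheet1 = simulate_cohort_counts(self._cfg(reads_per_sample=10_000))
        m2, _ = simulate_cohort_counts(self._cfg(reads_per_sample=10_000))
        assert m1.equals(m2)
        assert (m1.sum(axis=0) == 10_000).all()
        assert len(sheet1) == m1.shape[1] == 30

    def test_lognormal_cv_structure(self):
        """inter_sd >> intra_sd shows up as larger between-subject spread."""
        cfg = self._cfg(reads_per_sample=50_000, inter_subject_sd=0.5,
                        intra_subject_sd=0.05, n_subjects=6)
        matrix, sheet = simulate_cohort_counts(cfg, n_mirna=50)
        sheet = sheet.set_index("sample_id")
        # per-miRNA CV across one subject's samples vs across subjects
        subj = sheet["subject_id"]
        first_per_subject = [
            matrix.columns[subj.loc[matrix.columns] == s][0] for s in subj.unique()
        ]
        within_cols = matrix.columns[subj.loc[matrix.columns] == subj.unique()[0]]
        cv = lambda df: (df.std(axis=1, ddof=1) / df.mean(axis=1)).median()
        assert cv(matrix[within_cols]) < cv(matrix[first_per_subject])
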