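import numpy as np
import pandas as pd
import pytest

from circprio import ValidationError
from circprio import synthetic_data as sd


class TestGenerateAnnotation:
    def test_seeded_determinism(self):
        a = sd.generate_annotation(3, exons_per_gene=(3, 3), seed=7)
        b = sd.generate_annotation(3, exons_per_gene=(3, 3), seed=7)
        assert a.genome == b.genome
        assert a.genes == b.genes

    def test_exon_structure_invariants(self, toy_annotation):
        for gene in toy_annotation.genes:
            assert 2 <= gene.n_exons <= 8
            starts = [s for s, _ in gene.exons]
            ends = [e for _, e in gene.exons]
            assert starts == sorted(starts)
            assert all(s < e for s, e in gene.exons)
            # non-overlapping
            assert all(ends[i] <= starts[i + 1] for i in range(len(starts) - 1))
            assert ends[-1] <= len(toy_annotation.genome[gene.chrom])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"n_genes": 5, "exon_len": (0, 10)},
            {"n_genes": 5, "intron_len": (10, 5)},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            sd.generate_annotation(**kwargs)

    def test_gtf_fasta_roundtrip(self, toy_annotation, tmp_path):
        toy_annotation.write_fasta(tmp_path / "g.fa")
        toy_annotation.write_gtf(tmp_path / "a.gtf")
        back = sd.Annotation.from_files(tmp_path / "a.gtf", tmp_path / "g.fa")
        assert back.genome == toy_annotation.genome
        assert {g.gene_id: g for g in back.genes} == {
            g.gene_id: g for g in toy_annotation.genes
        }


class TestSimulateTranscriptome:
    def test_no_effects_means_zero_fold_changes(self, toy_annotation, two_group_design):
        _, truth = sd.simulate_transcriptome(
            toy_annotation, two_group_design, seed=3
        )
        assert (truth.features["log2fc"] == 0).all()

    def test_planted_effect_halves_treatment_expectation(
        self, toy_annotation, two_group_design
    ):
        _, truth = sd.simulate_transcriptome(
            toy_annotation,
            two_group_design,
            effect_model=[sd.Effect("G0001", sd.CIRCLE, -1.0)],
            seed=3,
        )
        ab = truth.abundance.loc["G0001|circ"]
        ctrl = [s for s, i in two_group_design.items() if i.group == "control"]
        trt = [s for s, i in two_group_design.items() if i.group == "treatment"]
        assert ab[trt].mean() == pytest.approx(0.5 * ab[ctrl].mean())

    def test_realized_circle_count_matches_truth(self, two_group_design):
        ann = sd.generate_annotation(100, seed=5)
        pool, truth = sd.simulate_transcriptome(
            ann, two_group_design, circ_rate=0.3, seed=3
        )
        pool_circles = [m for m in pool.molecules if m.topology == sd.CIRCLE]
        truth_circles = truth.features[truth.features["topology"] == sd.CIRCLE]
        assert len(pool_circles) == len(truth_circles) == 30

    def test_molecule_invariants(self, experiment):
        for mol in experiment["pool"].molecules:
            mol.validate()  # raises on violation
            if mol.topology == sd.LINEAR_BACKSPLICED:
                assert len(set(mol.exon_indices)) < len(mol.exon_indices)

    def test_effect_on_unknown_gene_rejected(self, toy_annotation, two_group_design):
        with pytest.raises(ValidationError):
            sd.simulate_transcriptome(
                toy_annotation,
                two_group_design,
                effect_model=[sd.Effect("NOPE", sd.CIRCLE, -1.0)],
                seed=0,
            )


def _single_molecule_pool(topology, copies, n_exons=3, exon_len=100, polya=None):
    """One gene, one molecule, one sample."""
    ann = sd.generate_annotation(
        1, exons_per_gene=(n_exons, n_exons), exon_len=(exon_len, exon_len), seed=1
    )
    design = {"s1": sd.SampleInfo("ctx", "control", 1)}
    mol = sd.Molecule(
        "m1",
        "G0000",
        topology,
        tuple(range(n_exons)),
        polyadenylated=(topology != sd.CIRCLE) if polya is None else polya,
        copy_number={"s1": copies},
    )
    return ann, sd.MoleculePool([mol], design)


class TestPrepareFractions:
    def test_zero_linear_survival_removes_all_linear(self, experiment):
        _, rnaser = sd.prepare_fractions(
            experiment["pool"], rnaser_linear_survival=0.0, seed=1
        )
        for mol in rnaser.molecules:
            if mol.topology != sd.CIRCLE:
                assert all(c == 0 for c in mol.copy_number.values())

    def test_polya_fraction_excludes_circles_without_leak(self, experiment):
        polya, _ = sd.prepare_fractions(
            experiment["pool"], polya_capture=1.0, polya_circle_leak=0.0, seed=1
        )
        originals = {m.molecule_id: m.copy_number for m in experiment["pool"].molecules}
        for mol in polya.molecules:
            if mol.topology == sd.CIRCLE:
                assert all(c == 0 for c in mol.copy_number.values())
            else:  # capture probability 1 keeps every poly(A) copy
                assert mol.copy_number == originals[mol.molecule_id]

    def test_binomial_survival_expectations(self):
        _, pool_lin = _single_molecule_pool(sd.LINEAR_MRNA, 10_000)
        _, pool_circ = _single_molecule_pool(sd.CIRCLE, 10_000)
        pool = sd.MoleculePool(
            pool_lin.molecules + [pool_circ.molecules[0]], pool_lin.sample_design
        )
        _, rnaser = sd.prepare_fractions(
            pool, rnaser_linear_survival=0.02, rnaser_circle_survival=0.95, seed=0
        )
        lin = next(m for m in rnaser.molecules if m.topology == sd.LINEAR_MRNA)
        circ = next(m for m in rnaser.molecules if m.topology == sd.CIRCLE)
        sd_lin = np.sqrt(10_000 * 0.02 * 0.98)
        sd_circ = np.sqrt(10_000 * 0.95 * 0.05)
        assert abs(lin.copy_number["s1"] - 200) <= 3 * sd_lin
        assert abs(circ.copy_number["s1"] - 9_500) <= 3 * sd_circ

    def test_survival_ordering_enforced(self, experiment):
        with pytest.raises(ValidationError):
            sd.prepare_fractions(
                experiment["pool"],
                rnaser_linear_survival=0.5,
                rnaser_circle_survival=0.2,
            )


class TestSampleReads:
    def test_error_free_reads_are_source_substrings(self, experiment):
        ann = experiment["annotation"]
        pool = experiment["rnaser_pool"]
        rs = experiment["reads_rnaser"]
        genes = {g.gene_id: g for g in ann.genes}
        mols = {m.molecule_id: m for m in pool.molecules}
        for row in rs.reads.sample(200, random_state=0).itertuples(index=False):
            mol = mols[row.molecule_id]
            mature = ann.mature_sequence(genes[mol.gene_id], mol.exon_indices)
            if mol.topology == sd.CIRCLE:
                mature = mature * (len(row.sequence) // len(mature) + 2)
            assert row.sequence in mature

    def test_short_circle_reads_always_cross_the_junction(self):
        ann, pool = _single_molecule_pool(sd.CIRCLE, 100, n_exons=1, exon_len=60)
        rs = sd.sample_reads(pool, ann, 300, read_len=75, seed=4)
        assert (rs.truth["bsj_overhang"] >= 1).all()

    def test_read_counts_follow_copy_length_weights(self):
        # two linear molecules with copy x length weights 1:3
        ann = sd.generate_annotation(
            2, exons_per_gene=(1, 1), exon_len=(200, 200), seed=2
        )
        design = {"s1": sd.SampleInfo("ctx", "control", 1)}
        mols = [
            sd.Molecule("m1", "G0000", sd.LINEAR_MRNA, (0,), True, {"s1": 1}),
            sd.Molecule("m2", "G0001", sd.LINEAR_MRNA, (0,), True, {"s1": 3}),
        ]
        pool = sd.MoleculePool(mols, design)
        rs = sd.sample_reads(pool, ann, 10_000, seed=5)
        n1 = (rs.reads["molecule_id"] == "m1").sum()
        sd3 = 3 * np.sqrt(10_000 * 0.25 * 0.75)
        assert abs(n1 - 2_500) <= sd3

    def test_multinomial_goodness_of_fit(self):
        from scipy import stats

        ann = sd.generate_annotation(
            5, exons_per_gene=(1, 1), exon_len=(150, 150), seed=3
        )
        design = {"s1": sd.SampleInfo("ctx", "control", 1)}
        copies = [1, 2, 3, 4, 10]
        mols = [
            sd.Molecule(f"m{i}", f"G{i:04d}", sd.LINEAR_MRNA, (0,), True, {"s1": c})
            for i, c in enumerate(copies)
        ]
        pool = sd.MoleculePool(mols, design)
        rs = sd.sample_reads(pool, ann, 100_000, seed=6)
        observed = rs.reads["molecule_id"].value_counts()
        obs = [observed.get(f"m{i}", 0) for i in range(5)]
        expected = [100_000 * c / sum(copies) for c in copies]
        assert stats.chisquare(obs, expected).pvalue > 0.001

    def test_empty_pool_rejected(self):
        ann, pool = _single_molecule_pool(sd.LINEAR_MRNA, 0)
        with pytest.raises(ValidationError):
            sd.sample_reads(pool, ann, 10, seed=0)

    def test_fastq_truth_deterministic_roundtrip(self, experiment, tmp_path):
        ann = experiment["annotation"]
        pool = experiment["polya_pool"]
        r1 = sd.sample_reads(pool, ann, 100, seed=9)
        r2 = sd.sample_reads(pool, ann, 100, seed=9)
        sd.write_fastq(r1, tmp_path / "a.fastq")
        sd.write_fastq(r2, tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
        sd.write_truth(r1, tmp_path / "a.tsv")
        sd.write_truth(r2, tmp_path / "b.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
        back = sd.read_fastq(tmp_path / "a.fastq")
        assert list(back["sequence"]) == list(r1.reads["sequence"])
        assert list(back["read_id"]) == list(r1.reads["read_id"])


class TestSimulateCtTable:
    def test_planted_fold_change_shifts_ct(self):
        targets = pd.DataFrame(
            {"target": ["circA"], "base_dct": [5.0], "log2fc": [-2.0]}
        )
        table = sd.simulate_ct_table(
            targets, biological_sd=0.0, technical_sd=0.0, seed=0
        )
        hk = table[table["is_housekeeping"]]
        t = table[~table["is_housekeeping"]]
        dct = (
            t.groupby("group")["ct"].mean() - hk.groupby("group")["ct"].mean()
        )
        assert dct["cerebellum"] == pytest.approx(5.0)
        assert dct["medulloblastoma"] == pytest.approx(7.0)
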