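"""Parsing, hypermutator QC, and strand-aware classification."""

import numpy as np
import pandas as pd
import pytest

from mutdet.genes import GeneModel, IntervalSet
from mutdet.mutations import (classify_mutations, count_by_gene,
                              filter_hypermutators, parse_mutations)

from conftest import random_reference

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def records(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "sample_id", "dataset"])


class TestParse:
    def test_maf_row_maps_directly(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tpos\tref\talt\tsample\tdataset\n"
                     "chr1\t100\tA\tG\tS1\tBRCA\n")
        df, counters = parse_mutations(p)
        assert df.iloc[0].tolist() == ["chr1", 100, "A", "G", "S1", "BRCA"]
        assert counters["n_snv"] == 1

    def test_non_snv_rows_skipped_and_counted(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tpos\tref\talt\tsample\tdataset\n"
                     "chr1\t100\tAT\tG\tS1\td\n"
                     "chr1\t101\tA\tG\tS1\td\n"
                     "chr1\t102\tA\tA\tS1\td\n")
        df, counters = parse_mutations(p)
        assert len(df) == 1
        assert counters["n_skipped_non_snv"] == 1
        assert counters["n_skipped_bad_allele"] == 1

    def test_missing_column_is_an_error(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("chrom\tpos\tref\tsample\tdataset\nchr1\t1\tA\tS1\td\n")
        with pytest.raises(ValueError, match="alt"):
            parse_mutations(p)

    def test_minimal_vcf(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text("##fileformat=VCFv4.2\n"
                     "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
                     "chr1\t5\t.\tA\tG\t.\t.\t.\tGT\t0/1\t0/0\n")
        df, _ = parse_mutations(p, format="vcf_min", dataset="d")
        assert len(df) == 1
        assert df.iloc[0]["sample_id"] == "S1"


class TestHypermutatorFilter:
    def test_single_extreme_sample_removed(self):
        rows = [("chr1", i + 1, "A", "G", s, "d")
                for s, k in [("S1", 10), ("S2", 10), ("S3", 10), ("S4", 10), ("S5", 100)]
                for i in range(k)]
        kept, qc = filter_hypermutators(records(rows))
        assert qc.set_index("sample_id")["removed"].to_dict() == {
            "S1": False, "S2": False, "S3": False, "S4": False, "S5": True}
        assert qc["fence_value"].iloc[0] == 10.0  # Q3 = 10, IQR = 0
        assert set(kept["sample_id"]) == {"S1", "S2", "S3", "S4"}

    def test_equal_counts_remove_nothing(self):
        rows = [("chr1", i + 1, "A", "G", f"S{j}", "d")
                for j in range(6) for i in range(7)]
        _, qc = filter_hypermutators(records(rows))
        assert not qc["removed"].any()

    def test_fewer_than_four_samples_warns_and_keeps_all(self):
        rows = [("chr1", 1, "A", "G", "S1", "d"), ("chr1", 2, "A", "G", "S2", "d")]
        with pytest.warns(UserWarning, match="fewer than 4"):
            kept, qc = filter_hypermutators(records(rows))
        assert len(kept) == 2 and not qc["removed"].any()

    def test_esd_variant_flags_planted_outlier(self):
        rng = np.random.default_rng(0)
        rows = []
        for j in range(20):
            k = 200 if j == 0 else int(rng.poisson(20))
            rows += [("chr1", i + 1, "A", "G", f"S{j:02d}", "d") for i in range(k)]
        _, qc = filter_hypermutators(records(rows), method="esd")
        assert qc.set_index("sample_id").loc["S00", "removed"]


def brute_classify(rec, gene, seq, islands):
    """Single-mutation oracle: explicit strings and complement tables."""
    p = rec["pos"] - 1
    in_exon = any(s <= p < e for s, e in gene.exons)
    if not in_exon or seq[p] != rec["ref"]:
        return None
    if gene.strand == "+":
        nts_ref, nts_alt = rec["ref"], rec["alt"]
    else:
        nts_ref, nts_alt = _COMP[rec["ref"]], _COMP[rec["alt"]]
    if nts_ref in "AG":
        collapsed, strand = f"{nts_ref}>{nts_alt}", "NTS"
    else:
        collapsed, strand = f"{_COMP[nts_ref]}>{_COMP[nts_alt]}", "TS"
    ctx = (rec["ref"] == "C" and p + 1 < len(seq) and seq[p + 1] == "G") or \
          (rec["ref"] == "G" and p - 1 >= 0 and seq[p - 1] == "C")
    in_isl = bool(islands.contains(gene.chrom, [p])[0])
    cpg_ti = collapsed == "G>A" and ctx and not in_isl
    return collapsed, strand, cpg_ti


class TestClassification:
    def test_plus_strand_a_to_g_is_nts(self, tiny_genome):
        genes = [GeneModel("g", "chr1", "+", [(0, 12)])]
        df = records([("chr1", 3, "A", "G", "s", "d")])
        cl, _ = classify_mutations(df, genes, tiny_genome)
        assert cl.iloc[0][["collapsed_type", "strand_class"]].tolist() == ["A>G", "NTS"]

    def test_minus_strand_a_to_g_is_ts(self, tiny_genome):
        genes = [GeneModel("g", "chr1", "-", [(0, 12)])]
        df = records([("chr1", 3, "A", "G", "s", "d")])
        cl, _ = classify_mutations(df, genes, tiny_genome)
        assert cl.iloc[0][["collapsed_type", "strand_class"]].tolist() == ["A>G", "TS"]

    def test_cpg_transition_flagged_outside_islands(self, tiny_genome):
        genes = [GeneModel("g", "chr1", "+", [(0, 12)])]
        df = records([("chr1", 4, "C", "T", "s", "d")])
        cl, _ = classify_mutations(df, genes, tiny_genome)
        row = cl.iloc[0]
        assert row["collapsed_type"] == "G>A" and row["cpg_ti"]
        islands = IntervalSet({"chr1": [(3, 5)]})
        cl2, _ = classify_mutations(df, genes, tiny_genome, islands)
        assert not cl2.iloc[0]["cpg_ti"] and cl2.iloc[0]["in_island"]

    def test_dual_strand_genes_excluded(self, tiny_genome):
        genes = [GeneModel("g", "chr1", "+", [(0, 12)], dual_strand_flag=True)]
        df = records([("chr1", 3, "A", "G", "s", "d")])
        cl, rep = classify_mutations(df, genes, tiny_genome)
        assert cl.empty and rep.n_no_gene == 1 and rep.n_genes_dual_strand == 1

    def test_reference_mismatch_dropped(self, tiny_genome):
        genes = [GeneModel("g", "chr1", "+", [(0, 12)])]
        df = records([("chr1", 1, "A", "G", "s", "d")])  # genome has T there
        cl, rep = classify_mutations(df, genes, tiny_genome)
        assert cl.empty and rep.n_ref_mismatch == 1 and rep.conserved()

    def test_overlapping_genes_both_receive_mutation(self, tiny_genome):
        genes = [GeneModel("a", "chr1", "+", [(0, 12)]),
                 GeneModel("b", "chr1", "-", [(0, 8)])]
        df = records([("chr1", 3, "A", "G", "s", "d")])
        cl, rep = classify_mutations(df, genes, tiny_genome)
        assert sorted(cl["gene_id"]) == ["a", "b"]
        assert rep.n_assignments == 2 and rep.n_assigned == 1

    def test_matches_bruteforce_oracle_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq, gene, islands = random_reference(rng, 300)
            rows = []
            for _ in range(40):
                p = int(rng.integers(0, 300))
                ref = seq[p]
                if ref not in "ACGT":
                    continue
                alt = rng.choice([b for b in "ACGT" if b != ref])
                rows.append(("chr1", p + 1, ref, alt, "s", "d"))
            if not rows:
                continue
            df = records(rows)
            cl, rep = classify_mutations(df, [gene], {"chr1": seq}, islands)
            assert rep.conserved()
            expected = [brute_classify(r, gene, seq, islands)
                        for _, r in df.iterrows()]
            expected = [e for e in expected if e is not None]
            got = list(map(tuple, cl[["collapsed_type", "strand_class", "cpg_ti"]]
                           .itertuples(index=False)))
            assert sorted(got) == sorted(expected)

    def test_complement_symmetry(self):
        """Reverse-complementing the genome and flipping strands leaves
        every (collapsed_type, strand_class) pair unchanged."""
        rng = np.random.default_rng(5)
        seq, gene, islands = random_reference(rng, 200, n_islands=0)
        L = len(seq)
        rows = []
        for _ in range(60):
            p = int(rng.integers(0, L))
            if seq[p] not in "ACGT":
                continue
            alt = rng.choice([b for b in "ACGT" if b != seq[p]])
            rows.append(("chr1", p + 1, seq[p], alt, "s", "d"))
        df = records(rows)
        cl, _ = classify_mutations(df, [gene], {"chr1": seq})

        rc = "".join(_COMP.get(b, "N") for b in reversed(seq))
        gene_rc = GeneModel(gene.gene_id, "chr1",
                            "-" if gene.strand == "+" else "+",
                            [(L - e, L - s) for s, e in reversed(gene.exons)])
        df_rc = df.copy()
        df_rc["pos"] = L - df["pos"] + 1
        df_rc["ref"] = df["ref"].map(_COMP)
        df_rc["alt"] = df["alt"].map(_COMP)
        cl_rc, _ = classify_mutations(df_rc, [gene_rc], {"chr1": rc})

        key = ["collapsed_type", "strand_class"]
        a = cl[key].value_counts().sort_index()
        b = cl_rc[key].value_counts().sort_index()
        assert a.equals(b)


class TestCountByGene:
    def test_class_partitions(self, tiny_genome):
        genes = [GeneModel("g", "chr1", "+", [(0, 12)])]
        df = records([("chr1", 3, "A", "G", "s", "d"),
                      ("chr1", 4, "C", "T", "s", "d"),
                      ("chr1", 7, "A", "T", "s", "d")])
        cl, _ = classify_mutations(df, genes, tiny_genome)
        n_cpg = count_by_gene(cl, ["g"], "cpg_ti")["g"]
        n_other = count_by_gene(cl, ["g"], "other")["g"]
        n_all = count_by_gene(cl, ["g"], "all")["g"]
        assert (n_cpg, n_other, n_all) == (1, 2, 3)
        assert count_by_gene(cl, ["g"], collapsed_type="A>G",
                             strand_class="NTS")["g"] == 1
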