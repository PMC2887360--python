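import pytest

from phosphatome import families as fam
from phosphatome.families import (
    FamilySchema,
    assign_family,
    classify_genome,
    detect_fusions,
    family_counts,
)
from phosphatome.genome_io import DomainCall, Gene
from phosphatome.simulate import classification_metrics


def _gene(protein="M" + "A" * 60, locus="g1"):
    return Gene(locus, 1, 3 * len(protein), "+", 0, protein)


def _calls(locus, *accessions):
    out = []
    for acc in accessions:
        pfam = acc if acc.startswith(("PF", "SM")) else ""
        cog = acc if acc.startswith("COG") else ""
        out.append(DomainCall(locus, pfam, cog, 1, 10))
    return out


class TestAssignFamily:
    @pytest.mark.parametrize(
        "accessions,family",
        [
            (("PF00481", "COG0631"), fam.PP2C),
            (("PF07228", "COG2208"), fam.SPOIIE),
            (("COG2453",), fam.PTP),
            (("COG0394",), fam.LOW_MW_PTP),
            (("COG2365",), fam.DSP_PTP),
            (("COG4551",), fam.PTP_OTHER),
            (("COG5350",), fam.PTP_OTHER),
            (("COG4464",), fam.PTPZ),
            (("COG0515",), fam.ELK),
            (("COG2172",), fam.NON_ELK_KINASE),
            (("COG1366",), fam.ANTI_ANTI_SIGMA),
            (("COG0607",), fam.RHODANESE),
        ],
    )
    def test_schema_rows(self, accessions, family):
        a = assign_family(_gene(), _calls("g1", *accessions))
        assert a.family == family

    def test_calcineurin_fold_without_ppp_cog_is_not_a_phosphatase(self):
        a = assign_family(_gene(), _calls("g1", "PF00149", "COG3568"))
        assert a.family == fam.OTHER
        assert a.note == "calcineurin-like non-phosphatase"

    def test_ppp_with_idstg_motif_is_confirmed(self):
        gene = _gene("M" + "A" * 20 + "IDSG" + "A" * 20)
        a = assign_family(gene, _calls("g1", "PF00149", "COG0639"))
        assert a.family == fam.PPP_CANDIDATE
        assert a.subtype_flags == {fam.PPP_CONFIRMED}

    def test_ppp_without_idstg_motif_is_apah_candidate(self):
        a = assign_family(_gene(), _calls("g1", "PF00149", "COG0639"))
        assert a.subtype_flags == {fam.APAH_CANDIDATE}

    def test_ppp_with_all_motifs_is_consensus_complete(self):
        seq = "M" + "GDAHG" + "AA" + "GDQQDRG" + "AA" + "GNHE" + "AA" + "IDSG" + "A" * 10
        a = assign_family(_gene(seq), _calls("g1", "PF00149", "COG0639"))
        assert a.subtype_flags == {fam.CONSENSUS_COMPLETE}
        assert a.motif_flags.consensus_complete

    def test_rhodanese_without_cdc25_motif_flagged_negative(self):
        a = assign_family(_gene(), _calls("g1", "COG0607"))
        assert a.family == fam.RHODANESE
        assert a.subtype_flags == {fam.CDC25_NEGATIVE}

    def test_rhodanese_with_cdc25_motif_not_flagged(self):
        gene = _gene("M" + "A" * 10 + "CEYSKLR" + "A" * 10)
        a = assign_family(gene, _calls("g1", "COG0607"))
        assert a.subtype_flags == frozenset()

    def test_no_calls_is_other(self):
        a = assign_family(_gene(), [])
        assert a.family == fam.OTHER and a.evidence == []

    def test_foreign_locus_calls_rejected(self):
        with pytest.raises(ValueError, match="passed with gene"):
            assign_family(_gene(locus="g1"), _calls("g2", "COG0515"))

    def test_classification_ignores_call_row_order(self):
        calls = _calls("g1", "PF00481", "COG0631", "PF00027")
        a1 = assign_family(_gene(), calls)
        a2 = assign_family(_gene(), list(reversed(calls)))
        assert (a1.family, a1.fusion_flags) == (a2.family, a2.fusion_flags)


class TestDetectFusions:
    @pytest.mark.parametrize(
        "accessions,flags",
        [
            (("PF00481", "COG0631", "PF00027"), {"cNMP"}),
            (("PF00481", "COG0631", "SM00100"), {"cNMP"}),
            (("PF07228", "COG2208", "PF00672"), {"HAMP"}),
            (("PF07228", "COG2208", "PF00498"), {"FHA"}),
            (("PF07228", "COG2208", "PF01590"), {"GAF"}),
            (("PF07228", "COG2208", "PF00532"), {"PBD"}),
            (("PF00481", "COG0631"), set()),
            (("PF00672",), set()),  # accessory alone is not a fusion
        ],
    )
    def test_flags(self, accessions, flags):
        assert detect_fusions(_calls("g1", *accessions)) == frozenset(flags)


class TestClassifyGenome:
    def test_genes_without_calls_become_other(self, default_sim):
        genome = default_sim.genomes["G0"]
        assignments = classify_genome(genome, [])
        assert all(a.family == fam.OTHER for a in assignments)
        assert len(assignments) == len(genome)

    def test_recovers_planted_ground_truth_exactly(self, default_sim):
        assignments = {
            g: classify_genome(default_sim.genomes[g], default_sim.calls[g])
            for g in default_sim.genomes
        }
        metrics = classification_metrics(default_sim.truth, assignments)
        assert metrics  # at least one family present
        for family, (precision, recall) in metrics.items():
            assert precision == 1.0 and recall == 1.0, family

    def test_subtype_and_fusion_truth_recovered(self, default_sim):
        for g, genome in default_sim.genomes.items():
            assignments = classify_genome(genome, default_sim.calls[g])
            for a in assignments:
                expected_subtype = default_sim.truth.subtypes[g][a.locus_tag]
                if expected_subtype:
                    assert expected_subtype in a.subtype_flags, a.locus_tag
                expected_fusions = set(default_sim.truth.fusions[g][a.locus_tag])
                assert set(a.fusion_flags) == expected_fusions, a.locus_tag

    def test_counts_match_summary_conservation(self, default_sim):
        g = "G0"
        assignments = classify_genome(default_sim.genomes[g], default_sim.calls[g])
        counts = family_counts(assignments)
        assert sum(counts.values()) == len(default_sim.genomes[g])


class TestSchemaIO:
    def test_shipped_schema_equals_default(self):
        from phosphatome.motifs import default_motif_library_path

        shipped = default_motif_library_path().parent / "family_schema.tsv"
        assert FamilySchema.from_tsv(shipped).rows == FamilySchema.default().rows

    def test_tsv_round_trip(self, tmp_path):
        schema = FamilySchema.default()
        p = tmp_path / "schema.tsv"
        schema.to_tsv(p)
        assert FamilySchema.from_tsv(p).rows == schema.rows
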