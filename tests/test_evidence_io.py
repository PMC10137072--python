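"""Evidence reading, deduplication and annotation-based filtering."""

import dataclasses
import io
import json

import pytest

from levelmap.evidence_io import (
    CRITERIA,
    AnnotationRecord,
    EvidenceFragment,
    FilterCriteria,
    deduplicate,
    failed_criteria,
    filter_annotations,
    join_candidates,
    read_annotations_jsonl,
    read_annotations_tsv,
    read_evidence,
    read_pairs,
    write_pairs,
)

from conftest import make_fragment


def jsonl_line(i, **overrides):
    obj = {
        "id": f"f{i}",
        "targetId": f"ENSG{i:011d}",
        "targetFromSource": f"GENE{i}",
        "diseaseId": "EFO_0000001",
        "pmid": str(30000000 + i),
        "text": f"fragment number {i}",
    }
    obj.update(overrides)
    return json.dumps(obj)


class TestReadEvidence:
    def test_well_formed_lines_parse_in_order(self):
        stream = io.StringIO("\n".join(jsonl_line(i) for i in range(3)) + "\n")
        result = read_evidence(stream)
        assert [f.fragment_id for f in result.fragments] == ["f0", "f1", "f2"]
        assert result.n_skipped == 0

    def test_missing_text_field_is_skipped_with_count(self):
        lines = [jsonl_line(0)]
        broken = json.loads(jsonl_line(1))
        del broken["text"]
        lines.append(json.dumps(broken))
        result = read_evidence(lines)
        assert len(result.fragments) == 1
        assert result.n_skipped == 1
        assert result.skipped[0][0] == 2  # 1-based line number

    def test_mixed_stream_keeps_only_valid_lines(self):
        # 10 lines, 2 malformed (broken JSON; empty text) -> 8 fragments
        lines = [jsonl_line(i) for i in range(8)]
        lines.insert(3, "{not json")
        lines.insert(7, jsonl_line(99, text="   "))
        result = read_evidence(lines)
        assert len(lines) == 10
        assert len(result.fragments) == 8
        assert result.n_skipped == 2

    def test_custom_key_names(self):
        line = json.dumps(
            {
                "frag": "a",
                "gene": "ENSG00000000042",
                "name": "ABC",
                "disease": "MONDO_1",
                "pubmed": "123",
                "sentence": "some text",
            }
        )
        result = read_evidence(
            [line],
            keys={
                "fragment_id": "frag",
                "target_ensembl_id": "gene",
                "target_name": "name",
                "disease_id": "disease",
                "pmid": "pubmed",
                "text": "sentence",
            },
        )
        assert result.fragments[0].target_name == "ABC"

    def test_non_numeric_pmid_is_skipped(self):
        result = read_evidence([jsonl_line(0, pmid="PMC123")])
        assert result.fragments == [] and result.n_skipped == 1


class TestDeduplicate:
    def test_same_key_keeps_first(self):
        a = make_fragment("The SAME   text", fragment_id="a")
        b = make_fragment("the same text", fragment_id="b")
        kept = deduplicate([a, b])
        assert kept == [a]

    def test_same_text_different_target_both_kept(self):
        a = make_fragment("shared sentence", fragment_id="a")
        b = make_fragment(
            "shared sentence", fragment_id="b", target_ensembl_id="ENSG00000000002"
        )
        assert len(deduplicate([a, b])) == 2

    def test_idempotent(self):
        frags = [
            make_fragment("one", fragment_id="a"),
            make_fragment("one", fragment_id="b"),
            make_fragment("two", fragment_id="c"),
        ]
        once = deduplicate(frags)
        assert deduplicate(once) == once


def passing_record(accession="NX_P1", gene="ENSG00000000001", pmid="11111"):
    return AnnotationRecord(
        protein_accession=accession,
        ensembl_gene_ids=frozenset({gene}),
        protein_existence_level="protein_level",
        annotation_group="general-annotation; generic-function",
        annotation_category="function",
        annotation_quality="GOLD",
        has_negative_evidence=False,
        evidence_quality="GOLD",
        evidence_type="publication",
        eco_terms=frozenset({"experimental evidence"}),
        pmid=pmid,
    )


class TestFilterAnnotations:
    def test_all_criteria_met_emits_pair(self):
        result = filter_annotations([passing_record()])
        assert result.pairs == {("ENSG00000000001", "11111")}
        assert result.n_excluded == 0

    def test_silver_annotation_quality_excluded(self):
        record = dataclasses.replace(passing_record(), annotation_quality="SILVER")
        result = filter_annotations([record])
        assert result.pairs == set()
        assert result.exclusions["annotation_quality"] == 1

    def test_multiple_ensembl_ids_excluded_not_expanded(self):
        record = dataclasses.replace(
            passing_record(),
            ensembl_gene_ids=frozenset({"ENSG00000000001", "ENSG00000000002"}),
        )
        result = filter_annotations([record])
        assert result.pairs == set()
        assert result.exclusions["ensembl_one_to_one"] == 1

    def test_failed_criteria_names_every_violation(self):
        record = dataclasses.replace(
            passing_record(),
            annotation_quality="BRONZE",
            has_negative_evidence=True,
        )
        assert failed_criteria(record, FilterCriteria()) == (
            "annotation_quality",
            "negative_evidence",
        )

    @pytest.mark.parametrize(
        "relaxed",
        [
            dict(allowed_groups=frozenset({"sequence; topology"})),
            dict(forbidden_categories=frozenset()),
            dict(allowed_eco_terms=frozenset({"sequence similarity evidence"})),
        ],
        ids=["extra-group", "no-forbidden-category", "extra-eco-term"],
    )
    def test_relaxing_a_criterion_never_shrinks_output(self, relaxed):
        base = FilterCriteria()
        records = [passing_record(f"NX_{i}", f"ENSG{i:011d}", str(i)) for i in range(5)]
        records.append(
            dataclasses.replace(
                passing_record("NX_X", "ENSG00000000099", "99"),
                annotation_group="sequence; topology",
                annotation_category="caution",
                eco_terms=frozenset({"sequence similarity evidence"}),
            )
        )
        strict = filter_annotations(records, base).pairs
        wide = dataclasses.replace(
            base,
            **{
                key: getattr(base, key) | value
                for key, value in relaxed.items()
                if key != "forbidden_categories"
            },
            **(
                {"forbidden_categories": relaxed["forbidden_categories"]}
                if "forbidden_categories" in relaxed
                else {}
            ),
        )
        assert strict <= filter_annotations(records, wide).pairs


class TestJoinCandidates:
    def test_empty_pairs_gives_empty_output(self):
        assert join_candidates([make_fragment("x")], set()) == []

    def test_gene_match_without_pmid_match_is_excluded(self):
        frag = make_fragment("x")
        pairs = {(frag.target_ensembl_id, "999")}
        assert join_candidates([frag], pairs) == []

    def test_known_overlap_is_recovered(self):
        frags = [
            make_fragment(f"t{i}", fragment_id=f"f{i}", pmid=str(100 + i))
            for i in range(10)
        ]
        pairs = {(f.target_ensembl_id, f.pmid) for f in frags[:7]}
        joined = join_candidates(frags, pairs)
        assert joined == frags[:7]
        assert len(set(joined)) == len(joined)


class TestInterchange:
    def test_pairs_tsv_round_trip(self):
        pairs = {("ENSG1", "10"), ("ENSG2", "20")}
        buf = io.StringIO()
        write_pairs(pairs, buf)
        assert read_pairs(io.StringIO(buf.getvalue())) == pairs

    def test_annotation_jsonl_and_tsv_agree(self):
        record = passing_record()
        jsonl = json.dumps(
            {
                "protein_accession": record.protein_accession,
                "ensembl_gene_ids": sorted(record.ensembl_gene_ids),
                "protein_existence_level": record.protein_existence_level,
                "annotation_group": record.annotation_group,
                "annotation_category": record.annotation_category,
                "annotation_quality": record.annotation_quality,
                "has_negative_evidence": record.has_negative_evidence,
                "evidence_quality": record.evidence_quality,
                "evidence_type": record.evidence_type,
                "eco_terms": sorted(record.eco_terms),
                "pmid": record.pmid,
            }
        )
        header = (
            "protein_accession\tensembl_gene_ids\tprotein_existence_level\t"
            "annotation_group\tannotation_category\tannotation_quality\t"
            "has_negative_evidence\tevidence_quality\tevidence_type\t"
            "eco_terms\tpmid"
        )
        row = (
            f"{record.protein_accession}\t{'|'.join(record.ensembl_gene_ids)}\t"
            f"{record.protein_existence_level}\t{record.annotation_group}\t"
            f"{record.annotation_category}\t{record.annotation_quality}\t"
            f"false\t{record.evidence_quality}\t{record.evidence_type}\t"
            f"{'|'.join(record.eco_terms)}\t{record.pmid}"
        )
        from_jsonl = list(read_annotations_jsonl([jsonl]))
        from_tsv = list(read_annotations_tsv([header, row]))
        assert from_jsonl == from_tsv == [record]


def test_empty_text_fragment_rejected():
    with pytest.raises(ValueError):
        EvidenceFragment(
            fragment_id="x",
            target_ensembl_id="ENSG1",
            target_name="A",
            disease_id="D",
            pmid="1",
            text="   ",
        )
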