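"""Quality-filter annotation records and join them with evidence fragments.

Generates a synthetic corpus plus an annotation fixture containing nine
records that each violate exactly one selection criterion, filters the
records, and joins the accepted (gene, PubMed id) pairs back onto the
deduplicated fragments.
"""

from levelmap import (
    SyntheticConfig,
    deduplicate,
    filter_annotations,
    generate_annotation_fixture,
    generate_corpus,
    join_candidates,
)


def main() -> None:
    cfg = SyntheticConfig(seed=11, n_per_category=200)
    fragments, _ = generate_corpus(cfg)
    unique = deduplicate(fragments)
    print(f"corpus: {len(fragments)} records, {len(unique)} after deduplication "
          f"({100 * (1 - len(unique) / len(fragments)):.1f}% duplicates removed)")

    pairs = {(f.target_ensembl_id, f.pmid) for f in unique[:400]}
    fixture = generate_annotation_fixture(cfg, pairs=pairs)
    outcome = filter_annotations(fixture.records)
    print(f"annotation records: {outcome.n_records}, passing: {outcome.n_passed}")
    print("exclusions by criterion:")
    for criterion, count in sorted(outcome.exclusions.items()):
        print(f"  {criterion}: {count}")

    candidates = join_candidates(unique, outcome.pairs)
    print(f"candidate fragments after the join: {len(candidates)}")
    print("Only fragments backed by a GOLD, publication-supported annotation")
    print("with a one-to-one gene mapping survive to the screening stage.")


if __name__ == "__main__":
    main()
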