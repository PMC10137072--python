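"""Curated worked examples: validated fragments with known categories.

Fifteen published target-disease evidence fragments (five per level of
study) whose category membership was confirmed by manual review.  They
serve as a desk-scale reference set for the dictionary screen: the
packaged dictionary must recover each fragment's category.
"""

from __future__ import annotations

import csv
import importlib.resources
from functools import lru_cache

from .categories import Category
from .evidence_io import EvidenceFragment


@lru_cache(maxsize=1)
def validated_examples() -> tuple[tuple[EvidenceFragment, Category], ...]:
    """The packaged (fragment, reviewed category) reference pairs.

    Database identifiers are not part of the published excerpts, so the
    fragments carry placeholder gene/disease/PubMed ids; only the text,
    the target name and the reviewed category matter here.
    """
    ref = importlib.resources.files("levelmap.data") / "validated_fragments.tsv"
    pairs = []
    with ref.open(encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t")):
            fragment = EvidenceFragment(
                fragment_id=row["fragment_id"],
                target_ensembl_id=f"ENSGEXAMPLE{i:04d}",
                target_name=row["target_name"],
                disease_id=f"EFO_EX{i:05d}",
                pmid=str(10_000_000 + i),
                text=row["text"],
            )
            pairs.append((fragment, Category(row["category"])))
    return tuple(pairs)
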