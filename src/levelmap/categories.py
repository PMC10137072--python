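"""The three biological levels of study used throughout the pipeline."""

from __future__ import annotations

import enum


class Category(str, enum.Enum):
    """Level of study at which a target-disease association was established.

    ``DNA_RNA`` covers genomic and transcriptomic evidence, ``PROTEIN``
    covers protein-level evidence (immunoassays, blots, proteomics), and
    ``METABOLITE`` covers metabolite-level evidence (metabolomics,
    lipidomics, glycomics).
    """

    DNA_RNA = "DNA_RNA"
    PROTEIN = "PROTEIN"
    METABOLITE = "METABOLITE"

    def __str__(self) -> str:  # keeps TSV/report output compact
        return self.value


CATEGORIES: tuple[Category, ...] = (
    Category.DNA_RNA,
    Category.PROTEIN,
    Category.METABOLITE,
)
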