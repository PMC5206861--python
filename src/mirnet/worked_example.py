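"""Worked-example data: a published mouse cisplatin-AKI miRNome screen.

The study behind these lists profiled mouse kidney miRNAs on a 528-feature
miRNome qPCR array across three groups — saline, cisplatin, and
cisplatin + mesenchymal stromal cell (MSC) treatment — and reported the top
regulated miRNAs (fold change of at least fivefold) for the injury
comparison (cisplatin vs. saline) and the treatment comparison
(cisplatin + MSC vs. cisplatin).  Feeding those printed lists through this
package's set operations reproduces the study's headline set results: the
two inversely regulated miRNAs (miR-141, down in injury / up with
treatment; miR-377, the reverse) and the three-database consensus targets
of each (3 genes for miR-141, 8 for miR-377).

Fold-change magnitudes were not printed per miRNA; profiles built here use
a nominal magnitude of 6 (all listed miRNAs cleared the fivefold bar).
Per-database decoy genes in the prediction tables are synthetic and marked
as such — only the consensus genes are the published ones.
"""

from __future__ import annotations

import pandas as pd

from .enrich import GeneSetCollection
from .network import TargetEdgeTable
from .qpcr import ComparisonProfile

__all__ = [
    "INJURY_UP", "INJURY_DOWN", "TREATMENT_UP", "TREATMENT_DOWN",
    "CONSENSUS_TARGETS", "DATABASES",
    "injury_profile", "treatment_profile", "prediction_tables",
    "pathway_annotation",
]

#: Top upregulated miRNAs, cisplatin vs. saline (injury comparison).
INJURY_UP = ("miR-377", "miR-741", "miR-675-3p", "miR-21", "miR-463",
             "miR-293*")
#: Top downregulated miRNAs, cisplatin vs. saline.
INJURY_DOWN = ("miR-141", "miR-208a", "miR-92a*", "miR-292-3p",
               "miR-673-5p", "miR-1190")
#: Top upregulated miRNAs, cisplatin + MSC vs. cisplatin (treatment).
TREATMENT_UP = ("miR-141", "miR-880", "miR-433", "miR-92a", "miR-463",
                "miR-295")
#: Top downregulated miRNAs, cisplatin + MSC vs. cisplatin.
TREATMENT_DOWN = ("miR-30e", "miR-377", "miR-543", "miR-693-5p", "miR-201",
                  "miR-148a*")

#: Three-database consensus target genes (mouse symbols) for the two most
#: connected miRNAs of the MSC-modulated regulatory network.
CONSENSUS_TARGETS: dict[str, tuple[str, ...]] = {
    "miR-141": ("Yaf2", "Ulk2", "Ccne2"),
    "miR-377": ("Ncoa6", "Bend6", "Nts", "Cul1", "Pitx2", "Zfp36l1",
                "Ssfa2", "Rsbn1"),
}

#: The three prediction databases consulted by the study.
DATABASES = ("TargetScan", "miRanda", "miRDB")

NOMINAL_MAGNITUDE = 6.0


def injury_profile(threshold: float = 5.0) -> ComparisonProfile:
    """The injury comparison (cisplatin vs. saline) as a ComparisonProfile."""
    return ComparisonProfile.from_calls(
        comparison_id="Cis_vs_Saline",
        numerator="cisplatin",
        denominator="saline",
        up=list(INJURY_UP),
        down=list(INJURY_DOWN),
        threshold=threshold,
        magnitude=NOMINAL_MAGNITUDE,
    )


def treatment_profile(threshold: float = 5.0) -> ComparisonProfile:
    """The treatment comparison (cisplatin + MSC vs. cisplatin)."""
    return ComparisonProfile.from_calls(
        comparison_id="CisMSC_vs_Cis",
        numerator="cisplatin_MSC",
        denominator="cisplatin",
        up=list(TREATMENT_UP),
        down=list(TREATMENT_DOWN),
        threshold=threshold,
        magnitude=NOMINAL_MAGNITUDE,
    )


def prediction_tables(n_decoys_per_db: int = 5) -> list[TargetEdgeTable]:
    """Per-database prediction tables for miR-141 and miR-377.

    Each database predicts the published consensus genes for both miRNAs
    plus ``n_decoys_per_db`` synthetic database-unique decoy genes per
    miRNA, so the three-way intersection recovers exactly the published
    consensus sets.
    """
    tables = []
    for db in DATABASES:
        rows = []
        for mirna, genes in CONSENSUS_TARGETS.items():
            for gene in genes:
                rows.append((mirna, gene, db))
            for i in range(n_decoys_per_db):
                # synthetic decoys, unique to this database by name
                rows.append((mirna, f"Decoy_{db}_{mirna}_{i + 1}", db))
        tables.append(TargetEdgeTable(
            pd.DataFrame(rows, columns=["mirna", "gene", "db"])))
    return tables


def pathway_annotation() -> GeneSetCollection:
    """Pathway-membership flags used to annotate the worked-example network.

    Cul1 (ubiquitin/proteolysis, Wnt-linked via the SCF complex) is flagged
    in the TGF-beta/Wnt set and Zfp36l1 in the fibrosis/EMT set; this is a
    small curated stand-in collection for node-coloring demonstrations, not
    a pathway database.
    """
    return GeneSetCollection(
        sets={
            "tgfb_wnt": {"Cul1", "Pitx2"},
            "fibrosis_emt": {"Zfp36l1", "Ccne2"},
        },
        descriptions={
            "tgfb_wnt": "genes linked to TGF-beta or Wnt signaling",
            "fibrosis_emt": "genes linked to fibrosis or EMT",
        },
    )
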