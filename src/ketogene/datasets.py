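"""Bundled reference data.

The field study behind this package (977 analyzable Polish
Holstein-Friesian cows, osteopontin c.495C>T genotypes, subclinical-ketosis
status at blood BHB >= 1.0 mmol/L) never deposited its raw records; what it
published is the 2x3 genotype-by-ketosis contingency table and rounded
frequency estimates. That table is packaged here as the canonical,
randomness-free regression input for the analytic stages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import GENOTYPE_ORDER, GenotypeOutcomeTable

# Published 2x3 counts: rows ketosis status (0 healthy, 1 SCK),
# columns CT, CC, TT. Margins: 928/49; 485/410/82; grand total 977.
_STUDY_COUNTS = np.array(
    [
        [462, 385, 81],
        [23, 25, 1],
    ]
)

#: Frequencies as printed in the source study (rounded).
PUBLISHED_GENOTYPE_FREQUENCIES = {"CT": 0.50, "CC": 0.42, "TT": 0.08}

#: Allele frequencies as printed in the source study. Note: gene counting on
#: the published genotype counts gives freq(C) = 1305/1954 ~ 0.668, not 0.71;
#: the pipeline reports this inconsistency rather than reconciling it.
PUBLISHED_ALLELE_FREQUENCIES = {"C": 0.71, "T": 0.29}

#: Initial cohort size before the contamination exclusion (979 -> 977).
INITIAL_COHORT_SIZE = 979
CONTAMINATED_RECORDS = 2


def load_study_counts() -> GenotypeOutcomeTable:
    """The published genotype-by-ketosis contingency table (n = 977)."""
    return GenotypeOutcomeTable(_STUDY_COUNTS.copy())


def expand_counts_to_records(table: GenotypeOutcomeTable) -> pd.DataFrame:
    """Inflate a 2x3 table into one pseudo-record per animal.

    Genotype and status are all the analytic stages need, so a counts table
    expands losslessly into an analysis dataset (BHB values are unknown and
    left missing).
    """
    rows = []
    k = 0
    for i, status in enumerate((0, 1)):
        for j, genotype in enumerate(GENOTYPE_ORDER):
            for _ in range(int(table.counts[i, j])):
                k += 1
                rows.append(
                    {"animal_id": f"REC{k:06d}", "genotype": genotype, "sck_status": status}
                )
    return pd.DataFrame(rows, columns=["animal_id", "genotype", "sck_status"])
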