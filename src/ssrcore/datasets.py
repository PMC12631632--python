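"""Bundled reference tables from a published SSR survey.

These are the printed summary statistics of a germplasm survey of 175
Polygonati Rhizoma (medicinal *Polygonatum*) accessions from 35 Chinese
populations, genotyped at 18 fluorescent SSR loci and reduced to a core
collection by least-distance stepwise sampling.  The raw genotypes are not
distributed here; the tables serve as worked-example inputs for the
package's summarizing, gene-flow and core-selection routines and as
internal-consistency fixtures for the test suite.
"""

from __future__ import annotations

import io

import pandas as pd

from .core_collection import CoreLadder, CoreStep

__all__ = [
    "load_marker_diversity",
    "load_core_ladder_table",
    "reference_core_ladder",
    "SPECIES_FST_HJ_DH",
]

#: printed pairwise Fst between the P. sibiricum (HJ) and P. cyrtonema (DH)
#: species groups — the least-differentiated species pair in the survey
SPECIES_FST_HJ_DH = 0.197

# Per-marker diversity of the full 175-accession collection.  N is the mean
# number of scored accessions per species group; Na..He are group-averaged;
# PIC is computed on collection-pooled frequencies.
_MARKER_DIVERSITY = """\
marker	N	Na	Ne	I	Ho	He	PIC
S3	24.500	13	1.429	0.700	0.000	0.335	0.771
S4	24.000	12	2.405	0.971	0.054	0.496	0.825
S13	20.000	14	2.322	0.894	0.013	0.397	0.564
S15	24.750	10	1.583	0.657	0.000	0.351	0.745
S21	19.500	13	2.755	1.052	0.000	0.578	0.757
S27	24.500	17	2.026	0.920	0.000	0.443	0.808
S34	20.000	26	3.681	1.242	0.000	0.524	0.899
S52	26.500	30	6.040	1.534	0.006	0.589	0.889
S55	34.500	11	1.294	0.572	0.167	0.301	0.595
S69	35.750	8	2.191	0.931	0.007	0.486	0.669
S83	28.750	30	4.323	1.625	0.039	0.683	0.909
S96	14.750	8	0.974	0.320	0.000	0.153	0.641
S99	12.250	18	4.098	1.286	0.000	0.594	0.902
S101	16.500	13	1.911	0.766	0.000	0.363	0.770
S102	17.750	22	4.924	1.360	0.000	0.563	0.869
S105	16.000	10	2.623	1.088	0.000	0.589	0.764
S109	12.750	9	2.020	0.782	0.000	0.384	0.738
S113	28.000	22	4.097	1.253	0.000	0.551	0.826
"""

# Diversity of the original bank and the five LDSS cores (C103 .. C22).
_CORE_LADDER = """\
collection	size	ratio	N	Na	Ne	I	Ho	He	Ra
Original	175	1.00	22.264	5.139	2.817	0.997	0.016	0.465	100.00
C103	103	0.59	14.597	4.667	2.794	0.995	0.017	0.473	90.82
C78	78	0.45	11.222	4.347	2.878	1.004	0.016	0.487	84.59
C62	62	0.35	9.028	3.833	2.694	0.945	0.018	0.473	74.59
C42	42	0.24	6.181	3.222	2.500	0.851	0.021	0.441	62.70
C22	22	0.13	3.472	2.375	2.119	0.699	0.019	0.399	46.22
"""


def load_marker_diversity() -> pd.DataFrame:
    """Per-locus diversity table of the reference survey (18 markers)."""
    return pd.read_csv(io.StringIO(_MARKER_DIVERSITY), sep="\t", index_col="marker")


def load_core_ladder_table() -> pd.DataFrame:
    """Published core-ladder summary (original bank plus five cores)."""
    return pd.read_csv(io.StringIO(_CORE_LADDER), sep="\t", index_col="collection")


def reference_core_ladder() -> CoreLadder:
    """The published ladder wrapped as a :class:`CoreLadder` (member lists
    are unknown and left empty), usable with
    :func:`ssrcore.core_collection.select_core`."""
    table = load_core_ladder_table()
    stats = ["N", "Na", "Ne", "I", "Ho", "He"]

    def step(name: str) -> CoreStep:
        row = table.loc[name]
        return CoreStep(
            ratio=float(row["ratio"]),
            size=int(row["size"]),
            members=[],
            summary=row[stats],
            ra=float(row["Ra"]),
        )

    original = step("Original")
    steps = [step(n) for n in table.index if n != "Original"]
    return CoreLadder(original=original, steps=steps)
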