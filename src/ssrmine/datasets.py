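"""Published reference values for a 20-marker *Aquilaria sinensis* panel.

Printed summary statistics from a genome-wide SSR marker development
effort in *A. sinensis*: per-class SSR counts from mining 60 resequenced
accessions, per-locus diversity statistics for the 20 selected markers
genotyped on 149 accessions, and the per-cluster diversity / AMOVA
summaries.  They serve as fixed numeric inputs for consistency checks
(e.g. recomputing a fixation index from its printed Ho/He, or column means
from printed columns); the underlying raw sequence and genotype data are
not public, so the full pipeline is exercised on synthetic data instead.
"""

from __future__ import annotations

import pandas as pd

#: genome-wide SSR class counts (motif-length class -> number of SSR sequences)
SSR_CLASS_COUNTS: dict[int, int] = {
    1: 4747,    # mononucleotide
    2: 41695,   # dinucleotide
    3: 9550,    # trinucleotide
    4: 644,     # tetranucleotide
    5: 13,      # pentanucleotide
    6: 8,       # hexanucleotide
}

#: mononucleotide canonical-label counts
MONO_MOTIF_COUNTS: dict[str, int] = {"A/T": 3013, "C/G": 1731}

#: leading dinucleotide canonical-label counts
DI_MOTIF_COUNTS: dict[str, int] = {"AT/AT": 15194, "TA/TA": 12840}

_PANEL_ROWS = [
    # locus, N, Na, Ne, I, Ho, He, F, PIC
    ("AquSSR07", 149, 3, 2.014, 0.820, 0.423, 0.503, 0.160, 0.422),
    ("AquSSR10", 149, 6, 3.751, 1.403, 0.725, 0.733, 0.012, 0.688),
    ("AquSSR14", 149, 6, 1.256, 0.478, 0.195, 0.204, 0.047, 0.196),
    ("AquSSR17", 149, 4, 1.410, 0.578, 0.282, 0.291, 0.031, 0.268),
    ("AquSSR18", 149, 10, 2.049, 1.168, 0.389, 0.512, 0.240, 0.489),
    ("AquSSR22", 149, 4, 3.048, 1.193, 0.181, 0.672, 0.730, 0.608),
    ("AquSSR27", 149, 7, 3.599, 1.456, 0.497, 0.722, 0.312, 0.676),
    ("AquSSR28", 149, 6, 1.891, 0.963, 0.389, 0.471, 0.174, 0.443),
    ("AquSSR29", 149, 12, 2.496, 1.282, 0.671, 0.599, -0.120, 0.564),
    ("AquSSR30", 149, 7, 3.148, 1.236, 0.564, 0.682, 0.174, 0.617),
    ("AquSSR34", 148, 3, 1.344, 0.493, 0.250, 0.256, 0.023, 0.236),
    ("AquSSR40", 148, 7, 3.308, 1.457, 0.615, 0.698, 0.119, 0.660),
    ("AquSSR42", 148, 5, 2.904, 1.192, 0.581, 0.656, 0.114, 0.595),
    ("AquSSR54", 149, 9, 2.680, 1.221, 0.631, 0.627, -0.006, 0.564),
    ("AquSSR58", 149, 5, 2.074, 0.864, 0.477, 0.518, 0.080, 0.434),
    ("AquSSR59", 148, 5, 3.706, 1.365, 0.716, 0.730, 0.019, 0.680),
    ("AquSSR62", 149, 6, 2.627, 1.098, 0.550, 0.619, 0.112, 0.554),
    ("AquSSR71", 148, 5, 1.939, 0.832, 0.405, 0.484, 0.163, 0.410),
    ("AquSSR89", 145, 3, 1.964, 0.781, 0.428, 0.491, 0.129, 0.402),
    ("AquSSR94", 147, 8, 3.009, 1.389, 0.932, 0.668, -0.396, 0.627),
]


def marker_panel_stats() -> pd.DataFrame:
    """Printed per-locus diversity statistics of the 20-marker panel
    (149 accessions), indexed by marker id."""
    df = pd.DataFrame(
        _PANEL_ROWS,
        columns=["locus_id", "N", "Na", "Ne", "I", "Ho", "He", "F", "PIC"],
    )
    return df.set_index("locus_id")


#: loci whose printed F is exactly consistent with its own printed Ho/He at
#: 3 dp (the remaining rows were evidently computed from unrounded inputs)
F_CONSISTENT_LOCI = ["AquSSR29", "AquSSR34", "AquSSR54", "AquSSR59"]

#: per-cluster diversity means for the three subpopulations
CLUSTER_DIVERSITY = pd.DataFrame(
    {
        "N": [70.750, 29.750, 47.950],
        "Na": [4.600, 4.800, 3.850],
        "Ne": [2.280, 2.816, 2.141],
        "I": [0.934, 1.141, 0.851],
        "Ho": [0.484, 0.561, 0.471],
        "He": [0.505, 0.603, 0.470],
        "F": [0.050, 0.063, -0.002],
    },
    index=["I", "II", "III"],
)

#: three-level AMOVA variance-component estimates for the 149-accession panel
AMOVA_COMPONENTS = {
    "among_populations": 0.636,
    "among_individuals": 0.290,
    "within_individuals": 4.930,
}

#: fingerprinting outcome: panel size and sizes of indistinguishable groups
FINGERPRINT_PANEL_SIZE = 149
FINGERPRINT_DUPLICATE_GROUPS = [2, 2, 2]
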