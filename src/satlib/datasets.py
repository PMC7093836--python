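"""Published reference data for the Schistocerca SG1-SG3 satDNA survey.

Ten species — the African desert locust (SGRE, the outgroup) and nine
American congeners — were profiled for three homologous satDNA families
(SG1, SG2, SG3) by read masking against consensus dimers. Per species the
survey reports the monomer size, A+T content, genomic abundance (% of
library nucleotides), implied copy number and nucleotide-weighted
intraspecific K2P divergence. FISH locus counts are available for SG1.
These values serve as worked-example inputs and as fixtures for the
desk-reproducible statistics (summary stats, z-scores, Spearman).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "schistocerca_satdna",
    "sg1_fish_loci",
    "clade_assignments",
    "RADIATION_TIME_MYR",
    "SPECIES_ORDER",
    "OUTGROUP",
]

RADIATION_TIME_MYR = 7.9
OUTGROUP = "SGRE"
SPECIES_ORDER = ("SGRE", "SFLA", "SCAR", "SPAL", "SCAN",
                 "SSEC", "SAME", "SDAM", "SCER", "SRUB")

_ROWS = [
    # family, species, monomer_size, at_percent, abundance_pct, copy_number, intra_k2p_pct
    ("SG1", "SGRE", 171, 55.0, 6.70, 161077, 8.97),
    ("SG1", "SFLA", 178, 56.7, 1.50, 72503, 13.25),
    ("SG1", "SCAR", 175, 56.6, 1.60, 78458, 14.57),
    ("SG1", "SPAL", 173, 61.3, 2.84, 133314, 17.47),
    ("SG1", "SCAN", 170, 51.2, 1.74, 96748, 23.55),
    ("SG1", "SSEC", 170, 58.8, 0.47, 21338, 14.96),
    ("SG1", "SAME", 170, 60.0, 0.55, 2540, 10.66),
    ("SG1", "SDAM", 170, 56.3, 0.47, 29448, 27.29),
    ("SG1", "SCER", 170, 60.0, 0.07, 3624, 27.93),
    ("SG1", "SRUB", 171, 60.2, 0.10, 7761, 19.54),
    ("SG2", "SGRE", 350, 57.0, 4.17, 94563, 6.66),
    ("SG2", "SFLA", 352, 55.7, 0.38, 17282, 6.19),
    ("SG2", "SCAR", 352, 55.5, 0.27, 12210, 8.92),
    ("SG2", "SPAL", 352, 57.1, 0.09, 4093, 24.10),
    ("SG2", "SCAN", 352, 57.1, 0.30, 13667, 20.82),
    ("SG2", "SSEC", 342, 59.6, 0.07, 3219, 10.70),
    ("SG2", "SAME", 336, 62.2, 0.01, 62, 21.92),
    ("SG2", "SDAM", 341, 59.8, 0.01, 248, 12.65),
    ("SG2", "SCER", 353, 56.4, 0.03, 748, 13.61),
    ("SG2", "SRUB", 343, 58.6, 1.35, 59827, 5.49),
    ("SG3", "SGRE", 170, 52.9, 0.29, 7243, 7.52),
    ("SG3", "SFLA", 169, 56.8, 0.57, 27828, 12.17),
    ("SG3", "SCAR", 169, 56.8, 0.61, 29558, 12.56),
    ("SG3", "SPAL", 168, 57.6, 1.41, 66005, 13.58),
    ("SG3", "SCAN", 170, 57.6, 1.08, 51109, 13.02),
    ("SG3", "SSEC", 172, 58.8, 0.98, 61898, 21.81),
    ("SG3", "SAME", 170, 59.4, 0.77, 4335, 24.60),
    ("SG3", "SDAM", 171, 58.5, 0.18, 9111, 13.83),
    ("SG3", "SCER", 170, 58.6, 0.35, 10323, 13.67),
    ("SG3", "SRUB", 170, 57.6, 0.47, 22606, 15.41),
]

# SG1 hybridizes at 12 chromosomal loci per haploid genome in eight
# species; the family is nearly lost in SCER (1 locus) and SRUB (3 loci).
_SG1_LOCI = {"SGRE": 12, "SFLA": 12, "SCAR": 12, "SPAL": 12, "SCAN": 12,
             "SSEC": 12, "SAME": 12, "SDAM": 12, "SCER": 1, "SRUB": 3}

_CLADES = {"SGRE": "outgroup",
           "SFLA": "1", "SCAR": "1",
           "SPAL": "2", "SCAN": "2",
           "SSEC": "3", "SAME": "3",
           "SDAM": "4", "SCER": "4", "SRUB": "4"}


def schistocerca_satdna() -> pd.DataFrame:
    """The published per-species survey of SG1-SG3 as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["family", "species", "monomer_size", "at_percent",
                 "abundance_pct", "copy_number", "intra_k2p_pct"],
    )


def sg1_fish_loci() -> dict[str, int]:
    """FISH locus counts for SG1 per haploid genome."""
    return dict(_SG1_LOCI)


def clade_assignments() -> dict[str, str]:
    """Clade membership of the ten species ('outgroup' for SGRE)."""
    return dict(_CLADES)
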