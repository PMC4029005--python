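"""Worked-example inputs: published summary values from a medicinal-leech
(Hirudo verbana) digestive-tract microbiome survey.

These are printed summary tables (relative abundances of 16S rRNA gene
tags and COG category hits/percents), included so that examples and checks
can run without any external download.  They are inputs, not package
results.
"""

from __future__ import annotations

#: Relative abundance (%) of 16S rRNA gene tags in crop intraluminal fluid
#: after a single blood meal; the nine named taxa dominate the community.
CROP_ILF_PERCENT: dict[str, int] = {
    "Rikenella": 35,
    "Aeromonas": 36,
    "Erysipelothrix": 5,
    "Bacteroides": 5,
    "Proteus": 4,
    "Fusobacterium": 4,
    "Clostridium": 3,
    "Peptostreptococcaceae": 2,
    "Granulicatella": 1,
}

#: Relative abundance (%) of 16S rRNA gene tags in the intestinum after a
#: single blood meal (five dominant taxa).
INTESTINUM_PERCENT: dict[str, int] = {
    "Rikenella": 36,
    "Aeromonas": 30,
    "Peptostreptococcaceae": 21,
    "Desulfovibrio": 6,
    "Pelagibius": 3,
}

#: COG metabolic categories of the Rikenella-like bin: BLASTX hit counts
#: and the printed percent column, alongside the percent column of
#: Bacteroides thetaiotaomicron for comparison.
RIKENELLA_COG_HITS: dict[str, int] = {
    "Energy production and conversion": 96,
    "Carbohydrate transport and metabolism": 112,
    "Amino acid transport and metabolism": 149,
    "Nucleotide transport and metabolism": 46,
    "Coenzyme transport and metabolism": 92,
    "Lipid transport and metabolism": 44,
    "Inorganic ion transport and metabolism": 87,
    "Secondary metabolites biosynthesis, transport and catabolism": 17,
}

RIKENELLA_COG_PERCENT: dict[str, float] = {
    "Energy production and conversion": 5.1,
    "Carbohydrate transport and metabolism": 6.0,
    "Amino acid transport and metabolism": 7.9,
    "Nucleotide transport and metabolism": 2.5,
    "Coenzyme transport and metabolism": 4.9,
    "Lipid transport and metabolism": 2.3,
    "Inorganic ion transport and metabolism": 4.6,
    "Secondary metabolites biosynthesis, transport and catabolism": 0.9,
}

BTHETA_COG_PERCENT: dict[str, float] = {
    "Energy production and conversion": 4.8,
    "Carbohydrate transport and metabolism": 9.8,
    "Amino acid transport and metabolism": 6.5,
    "Nucleotide transport and metabolism": 2.2,
    "Coenzyme transport and metabolism": 3.3,
    "Lipid transport and metabolism": 2.2,
    "Inorganic ion transport and metabolism": 6.2,
    "Secondary metabolites biosynthesis, transport and catabolism": 0.9,
}
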