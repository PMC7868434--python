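"""Genotype codes shared across the package.

A recombinant inbred line (RIL) panel descends from a biparental cross, so
every locus carries one of two parental alleles (here labelled after the
Lemont x TeQing cross: LM and TQ), a residual heterozygous state, or no call.
Codes are small ints so genotype matrices stay compact (int8).
"""

from __future__ import annotations

LM: int = 0
TQ: int = 1
HET: int = 2
MISSING: int = -1

#: single-character codes used in on-disk bin matrices
CODE_TO_CHAR = {LM: "A", TQ: "B", HET: "H", MISSING: "-"}
CHAR_TO_CODE = {v: k for k, v in CODE_TO_CHAR.items()}

#: the 16 elements of the rice grain/shoot/root ionome panel
ELEMENTS = [
    "As", "Ca", "Cd", "Co", "Cu", "Fe", "K", "Mg",
    "Mn", "Mo", "Ni", "P", "Rb", "S", "Sr", "Zn",
]

#: the 11 environment/tissue labels of the reference study design:
#: grain harvests from flooded (GF) and unflooded (GU) field plots,
#: a semi-flooded greenhouse (GGH), and hydroponic root/shoot tissue.
STUDY_ENVS = [
    "02GF", "03GF", "06GF", "07GF", "08GF2",
    "07GU", "08GU1", "08GU3", "11GGH", "15RTH", "15SHH",
]

#: across-environment PCA scopes: flooded, unflooded, all grain, and
#: grain+root+shoot
STUDY_ENV_SETS = {
    "F": ["02GF", "03GF", "06GF", "07GF", "08GF2"],
    "U": ["07GU", "08GU1", "08GU3"],
    "FUGG": ["02GF", "03GF", "06GF", "07GF", "08GF2",
             "07GU", "08GU1", "08GU3", "11GGH"],
    "GRS": ["02GF", "03GF", "06GF", "07GF", "08GF2",
            "07GU", "08GU1", "08GU3", "11GGH", "15RTH", "15SHH"],
}

#: least-squares-mean composite traits over environment groups
STUDY_LSMEAN_SETS = {
    "02-06_mean": ["02GF", "03GF", "06GF"],
    "F_mean": ["02GF", "03GF", "06GF", "07GF", "08GF2"],
    "U_mean": ["07GU", "08GU1", "08GU3"],
}


class ConfigError(ValueError):
    """Invalid simulator or pipeline configuration."""
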