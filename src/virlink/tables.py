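"""Published survey counts used as fixed inputs.

Contingency tables of virus / bacteriophage occurrence (TRUE, FALSE) by
protist taxon for single-cell genome surveys of the Gulf of Maine and the
Mediterranean Sea, and the flow-sorter drop parameters from the same
survey.  These are printed counts, used to exercise the association
statistics on real numbers.
"""

GOM_CONTAINS_VIRUS = {
    "Alveolata": (22, 75),
    "Stramenopile": (36, 55),
    "Chlorophyta/Prasinophyta": (32, 19),
    "Cercozoa": (14, 16),
    "Choanozoa": (13, 0),
    "Picozoa": (9, 0),
}

MED_CONTAINS_VIRUS = {
    "Stramenopile": (19, 22),
    "Chlorophyta/Prasinophyta": (15, 26),
    "Haptophyta": (2, 7),
}

MED_CONTAINS_BACTERIOPHAGE = {
    "Stramenopile": (8, 33),
    "Chlorophyta/Prasinophyta": (7, 34),
    "Haptophyta": (1, 8),
}

#: pL of sample per sorted drop, by instrument
DROP_SAMPLE_VOLUMES_PL = {"BD InFlux": 21.0, "Legacy MoFlo": 28.0}

#: typical surface seawater free-virus concentration bracket, viruses/pL
VIRUS_CONCENTRATION_RANGE_PER_PL = (0.01, 0.1)


def as_matrix(table: dict) -> list:
    """Row-ordered [[TRUE, FALSE], ...] matrix for the chi-square test."""
    return [list(v) for v in table.values()]
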