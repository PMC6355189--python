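"""CD160/HVEM study constants: sequence, peptide panel, binding annotations.

The mature CD160 extracellular domain is an IgV-like fold whose residues
1-133 are reconstructed here from the overlapping synthetic-fragment
sequences (the fragments tile the sequence with 8-residue overlaps, so every
position is fixed by at least one fragment and overlaps agree).  Positions
beyond 133 were not covered by any fragment; the default simulation protein
appends a synthetic Gly/Ser tail to reach the 141-residue scenario length
(see :mod:`hdxmap.synthetic_data`).
"""

from __future__ import annotations

from .peptide_chem import ModifiedPeptide, ProteinSequence, parse_peptide

# Residues 1-133 of mature CD160, reconstructed from the fragment panel.
CD160_SEQUENCE_133 = (
    "INITSSASQEGT"  # 1-12
    "RLNLICTVWHKK"  # 13-24
    "EEAEGFVVFLCK"  # 25-36
    "DRSGDCSPETSL"  # 37-48
    "KQLRLKRDPGID"  # 49-60
    "GVGEISSQLMFT"  # 61-72
    "ISQVTPLHSGTY"  # 73-84
    "QCCARSQKSGIR"  # 85-96
    "LQGHFFSILFTE"  # 97-108
    "TGNYTVTGLKQR"  # 109-120
    "QHLEFSHNEGTL"  # 121-132
    "S"             # 133
)

CD160 = ProteinSequence(id="CD160", residues=CD160_SEQUENCE_133)

# Synthetic fragment panel: name -> (start, end, bench notation).
# Cysteines are replaced by Abu throughout to prevent disulfide scrambling.
PEPTIDE_PANEL: dict[str, tuple[int, int, str]] = {
    "CD160(1-20)": (1, 20, "INITSSASQEGTRLNLIAbuTV-NH2"),
    "CD160(13-32)": (13, 32, "Ac-RLNLIAbuTVWHKKEEAEGFVV-NH2"),
    "CD160(25-44)": (25, 44, "Ac-EEAEGFVVFLAbuKDRSGDAbuSP-NH2"),
    "CD160(37-56)": (37, 56, "Ac-DRSGDAbuSPETSLKQLRLKRD-NH2"),
    "CD160(49-68)": (49, 68, "Ac-KQLRLKRDPGIDGVGEISSQ-NH2"),
    "CD160(61-80)": (61, 80, "Ac-GVGEISSQLMFTISQVTPLH-NH2"),
    "CD160(73-92)": (73, 92, "Ac-ISQVTPLHSGTYQAbuAbuARSQK-NH2"),
    "CD160(85-104)": (85, 104, "Ac-QAbuAbuARSQKSGIRLQGHFFSI-NH2"),
    "CD160(97-116)": (97, 116, "Ac-LQGHFFSILFTETGNYTVTG-NH2"),
    "CD160(97-110)": (97, 110, "Ac-LQGHFFSILFTETG-NH2"),
    "CD160(103-116)": (103, 116, "Ac-SILFTETGNYTVTG-NH2"),
    "CD160(109-133)": (109, 133, "Ac-TGNYTVTGLKQRQHLEFSHNEGTLS-NH2"),
}

# The intervals used as the fixed "panel map" in simulations (the affinity
# panel minus the insoluble 97-116 construct, which the two shorter
# fragments replace).
PANEL_MAP_INTERVALS: tuple[tuple[int, int], ...] = (
    (1, 20), (13, 32), (25, 44), (37, 56), (49, 68), (61, 80),
    (73, 92), (85, 104), (97, 110), (103, 116), (109, 133),
)

# Regions with significantly reduced exchange upon HVEM binding
# (HDX-resolved protected fragments).
PROTECTED_REGIONS: tuple[tuple[int, int], ...] = ((16, 21), (30, 34), (76, 87))

# Digest-style map: the panel intervals plus the short HDX-resolved
# fragments named in the study (the protease XIII + pepsin digest yields
# many short overlapping peptides; these are the ones with reported
# intervals).  Short fragments are what give region calling its residue
# resolution.
DIGEST_MAP_INTERVALS: tuple[tuple[int, int], ...] = PANEL_MAP_INTERVALS + (
    (16, 21), (30, 34), (70, 75), (76, 87), (88, 101),
)

# Disulfide topology of the extracellular domain.
DISULFIDE_PAIRS: tuple[tuple[int, int], ...] = ((18, 86), (35, 42))
FREE_CYSTEINES: tuple[int, ...] = (87,)

# Exchange time course, seconds: 10 s, 1 min, 5 min, 25 min, 2 h.
TIME_COURSE_S: tuple[float, ...] = (10.0, 60.0, 300.0, 1500.0, 7200.0)


def panel_peptides() -> list[tuple[str, ModifiedPeptide]]:
    """Parse the full fragment panel against the CD160 parent sequence."""
    return [
        (name, parse_peptide(spec, parent=CD160, start=start, end=end))
        for name, (start, end, spec) in PEPTIDE_PANEL.items()
    ]
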