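"""A PubChem-style 881-bit structural-key provider.

The 881-bit PubChem (CACTVS) substructure keys are not natively available in
RDKit, so this module ships a documented reimplementation of the key *layout*:
hierarchic element counts, ring descriptors, bonded atom pairs, and a curated
set of SMARTS substructure patterns, each mapped to a fixed index in the
881-bit space.  Bits whose CACTVS definition is not reproduced here are simply
never set.

This provider is versioned (``PUBCHEM_PROVIDER_VERSION``) and is **not**
bit-compatible with PubChem's own fingerprints; Tanimoto values computed with
it are comparable within this package only.  The region layout mirrors the
published key document:

* bits 0–114    element count thresholds
* bits 115–262  ring-size/aromaticity counts
* bits 263–326  bonded element pairs
* bits 327–880  substructure SMARTS (subset populated)
"""

from __future__ import annotations

from rdkit import Chem

PUBCHEM_PROVIDER_VERSION = "cliffscape-pubchem-1"
N_BITS = 881

# -- Section 1: hierarchic element counts (bits 0-114, subset) ---------------
# (bit, atomic number, minimum count)
_ELEMENT_COUNTS: list[tuple[int, int, int]] = [
    (0, 1, 4), (1, 1, 8), (2, 1, 16), (3, 1, 32),      # H
    (4, 3, 1), (5, 3, 2),                               # Li
    (6, 5, 1), (7, 5, 2),                               # B
    (8, 6, 2), (9, 6, 4), (10, 6, 8), (11, 6, 16), (12, 6, 32),  # C
    (13, 7, 1), (14, 7, 2), (15, 7, 4), (16, 7, 8),     # N
    (17, 8, 1), (18, 8, 2), (19, 8, 4), (20, 8, 8), (21, 8, 16),  # O
    (22, 9, 1), (23, 9, 2), (24, 9, 4),                 # F
    (25, 11, 1), (26, 11, 2),                           # Na
    (27, 14, 1), (28, 14, 2),                           # Si
    (29, 15, 1), (30, 15, 2), (31, 15, 4),              # P
    (32, 16, 1), (33, 16, 2), (34, 16, 4), (35, 16, 8), # S
    (36, 17, 1), (37, 17, 2), (38, 17, 4), (39, 17, 8), # Cl
    (40, 19, 1), (41, 19, 2),                           # K
    (42, 35, 1), (43, 35, 2), (44, 35, 4),              # Br
    (45, 53, 1), (46, 53, 2), (47, 53, 4),              # I
    (48, 4, 1),   # Be
    (49, 12, 1),  # Mg
    (50, 13, 1),  # Al
    (51, 20, 1),  # Ca
    (52, 26, 1),  # Fe
    (53, 29, 1),  # Cu
    (54, 30, 1),  # Zn
]

# -- Section 2: ring descriptors (bits 115-262, subset) ----------------------
# Per ring size 3..10 we expose: >=1 ring, >=2 rings, >=1 aromatic ring of
# that size, >=1 heteroatom-containing ring of that size.
_RING_SECTION_START = 115
_RING_SIZES = list(range(3, 11))
_BITS_PER_RING_SIZE = 4

# -- Section 3: bonded element pairs (bits 263-326, subset) ------------------
# (bit, SMARTS for a single bond-connected pair, any bond order)
_ATOM_PAIRS: list[tuple[int, str]] = [
    (263, "[#3]~[#1]"), (264, "[#3]~[#3]"), (265, "[#3]~[#5]"),
    (266, "[#3]~[#6]"), (267, "[#3]~[#8]"), (268, "[#9]~[#3]"),
    (269, "[#5]~[#1]"), (270, "[#5]~[#5]"), (271, "[#5]~[#6]"),
    (272, "[#5]~[#7]"), (273, "[#5]~[#8]"), (274, "[#9]~[#5]"),
    (275, "[#6]~[#1]"), (276, "[#6]~[#6]"), (277, "[#6]~[#7]"),
    (278, "[#6]~[#8]"), (279, "[#6]~[#16]"), (280, "[#6]~[#17]"),
    (281, "[#6]~[#9]"), (282, "[#6]~[#35]"), (283, "[#6]~[#53]"),
    (284, "[#6]~[#15]"), (285, "[#6]~[#14]"), (286, "[#7]~[#1]"),
    (287, "[#7]~[#7]"), (288, "[#7]~[#8]"), (289, "[#7]~[#16]"),
    (290, "[#8]~[#1]"), (291, "[#8]~[#8]"), (292, "[#8]~[#15]"),
    (293, "[#8]~[#16]"), (294, "[#16]~[#1]"), (295, "[#16]~[#16]"),
    (296, "[#15]~[#1]"), (297, "[#15]~[#7]"), (298, "[#15]~[#15]"),
]

# -- Section 4: substructure patterns (bits 327+, curated subset) ------------
_SMARTS_PATTERNS: list[tuple[int, str]] = [
    (327, "[#6](~[#6])(~[#6])~[#6]"),            # C branching
    (328, "[#6](~[#6])(~[#6])(~[#6])~[#6]"),     # quaternary-like C
    (329, "[#6]=[#6]"),
    (330, "[#6]#[#6]"),
    (331, "[#6]=[#8]"),
    (332, "[#6]=[#7]"),
    (333, "[#6]#[#7]"),
    (334, "[#7]=[#8]"),
    (335, "[#7]~[#6]=[#8]"),                     # amide
    (336, "[#8]~[#6]=[#8]"),                     # carboxyl/ester
    (337, "[#7]~[#6](~[#7])~[#7]"),              # guanidine-like
    (338, "[#6]-[OX2H]"),                        # hydroxyl
    (339, "[#6]-[NX3;H2]"),                      # primary amine
    (340, "[#6]-[NX3;H1]-[#6]"),                 # secondary amine
    (341, "[#6]-[NX3](-[#6])-[#6]"),             # tertiary amine
    (342, "[#6]-[OX2]-[#6]"),                    # ether
    (343, "[#6]-[SX2]-[#6]"),                    # thioether
    (344, "[#6]-[F,Cl,Br,I]"),                   # halide
    (345, "c1ccccc1"),                           # benzene
    (346, "c1ccncc1"),                           # pyridine
    (347, "c1cc2ccccc2[nH0]1"),                  # fused azine edge
    (348, "c1ccc2ncccc2c1"),                     # quinoline
    (349, "c1ccc2[nH]ccc2c1"),                   # indole
    (350, "c1cscn1"),                            # thiazole
    (351, "c1cocn1"),                            # oxazole
    (352, "c1cnc[nH]1"),                         # imidazole
    (353, "C1CCCCC1"),                           # cyclohexane
    (354, "C1CCNCC1"),                           # piperidine
    (355, "C1CNCCN1"),                           # piperazine
    (356, "C1CCOC1"),                            # tetrahydrofuran
    (357, "C1CCNC1"),                            # pyrrolidine
    (358, "C1COCCN1"),                           # morpholine
    (359, "[#6]S(=O)(=O)[#6,#7,#8]"),            # sulfone/sulfonamide
    (360, "[#6]-[NX3]-[#6]=[#8]"),               # N-acyl
    (361, "[#7]-[#6]-[#6]-[#8]"),
    (362, "[#8]-[#6]-[#6]-[#8]"),
    (363, "[#7]-[#6]-[#6]-[#7]"),
    (364, "[CX4]([#6])([#6])[#7]"),
    (365, "[#6]=[#6]-[#6]=[#8]"),                # enone
    (366, "a-[NX3]"),                            # aryl amine
    (367, "a-[OX2]"),                            # aryl ether/phenol
    (368, "a-[F,Cl,Br,I]"),                      # aryl halide
    (369, "a-[CH3]"),                            # aryl methyl
    (370, "a-a"),                                # biaryl junction
    (371, "[R2]"),                               # fusion atom
    (372, "[#7;R]"),                             # ring nitrogen
    (373, "[#8;R]"),                             # ring oxygen
    (374, "[#16;R]"),                            # ring sulfur
    (375, "[CX3](=O)[OX2H1]"),                   # carboxylic acid
    (376, "[CX3](=O)[OX2][#6]"),                 # ester
    (377, "[NX3][CX3](=[OX1])[NX3]"),            # urea
    (378, "[#6]-[#7]=[#6]"),
    (379, "[#8]=[#6]-[#6]=[#8]"),                # 1,2-dicarbonyl
    (380, "[CH2]([!#1])[!#1]"),                  # methylene linker
    (381, "[CH3]-[#7]"),                         # N-methyl
    (382, "[CH3]-[#8]"),                         # O-methyl
    (383, "[#6](-[#9])(-[#9])-[#9]"),            # trifluoromethyl
]


def _build_patterns() -> list[tuple[int, Chem.Mol]]:
    compiled = []
    for bit, smarts in _ATOM_PAIRS + _SMARTS_PATTERNS:
        patt = Chem.MolFromSmarts(smarts)
        assert patt is not None, smarts
        compiled.append((bit, patt))
    return compiled


_COMPILED: list[tuple[int, Chem.Mol]] | None = None


def pubchem_like_on_bits(mol: Chem.Mol) -> set[int]:
    """Compute the on-bits of the PubChem-style key set for one molecule."""
    global _COMPILED
    if _COMPILED is None:
        _COMPILED = _build_patterns()

    bits: set[int] = set()

    counts: dict[int, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetAtomicNum()] = counts.get(atom.GetAtomicNum(), 0) + 1
        counts[1] = counts.get(1, 0) + atom.GetTotalNumHs()
    for bit, z, minimum in _ELEMENT_COUNTS:
        if counts.get(z, 0) >= minimum:
            bits.add(bit)

    ring_info = mol.GetRingInfo()
    for size_idx, size in enumerate(_RING_SIZES):
        base = _RING_SECTION_START + size_idx * _BITS_PER_RING_SIZE
        rings = [r for r in ring_info.AtomRings() if len(r) == size]
        if len(rings) >= 1:
            bits.add(base)
        if len(rings) >= 2:
            bits.add(base + 1)
        for ring in rings:
            atoms = [mol.GetAtomWithIdx(i) for i in ring]
            if all(a.GetIsAromatic() for a in atoms):
                bits.add(base + 2)
            if any(a.GetAtomicNum() != 6 for a in atoms):
                bits.add(base + 3)

    for bit, patt in _COMPILED:
        if mol.HasSubstructMatch(patt):
            bits.add(bit)
    return bits
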