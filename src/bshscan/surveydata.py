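"""Published genus-survey counts used as worked-example inputs.

A genus-wide survey of 170 *Lactobacillus* species reported, for each of
the 39 BSH-encoding species, the number of sequenced strains, the number
of BSH-positive strains, and how many positive strains carry exactly
one, two, or three BSH copies; at the species level it reported 82
PVA-encoding, 39 BSH-encoding, 8 both, and 57 neither, and lifestyle
distributions for the encoding species.  These printed counts are
first-class inputs for exercising the summary stage: the helpers below
expand them into per-strain call records and species-level lifestyle
metadata whose marginals match the published figures, so the repertoire
module can recompute every published percentage from raw counts.
"""

from __future__ import annotations

from .repertoire import StrainCallRecord
from .seqio import StrainMetadata

#: (species, total strains, strains with BSH, # with exactly 1 / 2 / 3 copies)
BSH_SPECIES_COUNTS: tuple[tuple[str, int, int, int, int, int], ...] = (
    ("Lactobacillus acidophilus", 16, 15, 0, 15, 0),
    ("Lactobacillus agilis", 2, 2, 1, 1, 0),
    ("Lactobacillus amylovorus", 6, 6, 5, 1, 0),
    ("Lactobacillus animalis", 3, 3, 3, 0, 0),
    ("Lactobacillus antri", 1, 1, 0, 1, 0),
    ("Lactobacillus apodemi", 1, 1, 0, 1, 0),
    ("Lactobacillus aviarius", 15, 15, 14, 1, 0),
    ("Lactobacillus coleohominis", 2, 2, 2, 0, 0),
    ("Lactobacillus crispatus", 26, 24, 23, 1, 0),
    ("Lactobacillus delbrueckii", 30, 4, 4, 0, 0),
    ("Lactobacillus equicursoris", 2, 2, 2, 0, 0),
    ("Lactobacillus frumenti", 1, 1, 1, 0, 0),
    ("Lactobacillus gallinarum", 2, 1, 1, 0, 0),
    ("Lactobacillus gasseri", 21, 21, 1, 13, 7),
    ("Lactobacillus gigeriorum", 1, 1, 1, 0, 0),
    ("Lactobacillus gorillae", 1, 1, 1, 0, 0),
    ("Lactobacillus hamsteri", 1, 1, 1, 0, 0),
    ("Lactobacillus helveticus", 23, 1, 1, 0, 0),
    ("Lactobacillus hominis", 1, 1, 0, 1, 0),
    ("Lactobacillus ingluviei", 3, 1, 1, 0, 0),
    ("Lactobacillus intestinalis", 1, 1, 0, 0, 1),
    ("Lactobacillus johnsonii", 9, 9, 1, 5, 3),
    ("Lactobacillus kalixensis", 1, 1, 0, 1, 0),
    ("Lactobacillus kefiranofaciens", 3, 1, 1, 0, 0),
    ("Lactobacillus kitasatonis", 1, 1, 1, 0, 0),
    ("Lactobacillus mucosae", 8, 8, 8, 0, 0),
    ("Lactobacillus murinus", 3, 3, 3, 0, 0),
    ("Lactobacillus oris", 4, 3, 3, 0, 0),
    ("Lactobacillus panis", 1, 1, 1, 0, 0),
    ("Lactobacillus plantarum", 182, 147, 147, 0, 0),
    ("Lactobacillus reuteri", 30, 28, 28, 0, 0),
    ("Lactobacillus rogosae", 1, 1, 0, 1, 0),
    ("Lactobacillus ruminis", 14, 12, 12, 0, 0),
    ("Lactobacillus saerimneri", 2, 1, 1, 0, 0),
    ("Lactobacillus salivarius", 14, 11, 8, 3, 0),
    ("Lactobacillus secaliphilus", 1, 1, 1, 0, 0),
    ("Lactobacillus taiwanensis", 1, 1, 1, 0, 0),
    ("Lactobacillus ultunensis", 1, 1, 1, 0, 0),
    ("Lactobacillus vaginalis", 1, 1, 1, 0, 0),
)

TOTAL_SPECIES = 170
N_SPECIES_BSH = 39
N_SPECIES_PVA = 82
N_SPECIES_BOTH = 8
N_SPECIES_NEITHER = 57

# Species-level lifestyle counts among encoding species.  The BSH split
# (33 vertebrate / 5 unknown / 1 nomadic over 39) and the PVA split
# (33 free-living / 33 unknown / 11 vertebrate / 5 nomadic over 82) are
# the unique integer solutions to the published percentages.
BSH_LIFESTYLE_COUNTS = {
    "vertebrate-adapted": 33,
    "unknown": 5,
    "nomadic": 1,
}
PVA_LIFESTYLE_COUNTS = {
    "free-living": 33,
    "unknown": 33,
    "vertebrate-adapted": 11,
    "nomadic": 5,
}


def strain_call_records() -> list[StrainCallRecord]:
    """Expand the survey counts into one record per strain.

    BSH-encoding species yield their published per-copy strain counts
    (positive strains first, then the BSH-negative remainder).  The
    other 131 species of the survey are represented by a single strain
    each: 74 PVA-only species, then 57 with neither enzyme.  The 8
    "both" species are modelled by giving the first eight BSH species
    one PVA copy as well — species-level marginals are all that the
    summary stage consumes.
    """
    records: list[StrainCallRecord] = []
    for idx, (species, total, _positive, n1, n2, n3) in enumerate(BSH_SPECIES_COUNTS):
        n_pva = 1 if idx < N_SPECIES_BOTH else 0
        strain_no = 0
        for copies, count in ((1, n1), (2, n2), (3, n3)):
            for _ in range(count):
                strain_no += 1
                records.append(
                    StrainCallRecord(species, f"s{strain_no:03d}", copies, n_pva)
                )
        for _ in range(total - n1 - n2 - n3):
            strain_no += 1
            records.append(StrainCallRecord(species, f"s{strain_no:03d}", 0, n_pva))
    n_pva_only = N_SPECIES_PVA - N_SPECIES_BOTH
    for i in range(n_pva_only):
        records.append(StrainCallRecord(f"Lactobacillus pvaonly{i:03d}", "s001", 0, 1))
    for i in range(N_SPECIES_NEITHER):
        records.append(StrainCallRecord(f"Lactobacillus neither{i:03d}", "s001", 0, 0))
    return records


def lifestyle_metadata() -> list[StrainMetadata]:
    """Species-level lifestyle labels consistent with the published marginals.

    The eight "both" species are assigned 7 vertebrate-adapted + 1
    unknown, which is compatible with both enzyme classes' published
    lifestyle counts; the remaining BSH-only and PVA-only species fill
    the rest of their class's distribution, and the 57 "neither" species
    take the insect-adapted/free-living remainder.
    """
    meta: list[StrainMetadata] = []
    # Both-species lifestyles: 7 vertebrate, 1 unknown.
    both_lifestyles = ["vertebrate-adapted"] * 7 + ["unknown"]
    # BSH-only (31 species): 26 vertebrate, 4 unknown, 1 nomadic.
    bsh_only_lifestyles = (
        ["vertebrate-adapted"] * 26 + ["unknown"] * 4 + ["nomadic"]
    )
    bsh_lifestyles = both_lifestyles + bsh_only_lifestyles
    for (species, *_), lifestyle in zip(BSH_SPECIES_COUNTS, bsh_lifestyles):
        meta.append(StrainMetadata(species, "rep", lifestyle))
    # PVA-only (74 species): class totals minus the both-species share.
    pva_only_lifestyles = (
        ["free-living"] * 33
        + ["unknown"] * (33 - 1)
        + ["vertebrate-adapted"] * (11 - 7)
        + ["nomadic"] * 5
    )
    for i, lifestyle in enumerate(pva_only_lifestyles):
        meta.append(StrainMetadata(f"Lactobacillus pvaonly{i:03d}", "s001", lifestyle))
    for i in range(N_SPECIES_NEITHER):
        lifestyle = "insect-adapted" if i < 15 else "free-living"
        meta.append(StrainMetadata(f"Lactobacillus neither{i:03d}", "s001", lifestyle))
    return meta
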